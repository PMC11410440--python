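"""File I/O: grayscale images and cohort tables."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import UnreadableImage, UnsupportedFormat
from .stats import MORPH_PARAMS, PatientRecord, VesselParams

_IMAGE_EXTS = {".bmp", ".png", ".tif", ".tiff"}

#: ITU-R BT.601 luma weights for colour-to-grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])


def read_grayscale_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale BMP/PNG/TIFF as a float array.

    Colour images are converted by BT.601 luminance; an alpha channel is
    dropped.
    """
    path = Path(path)
    if path.suffix.lower() not in _IMAGE_EXTS:
        raise UnsupportedFormat(f"unsupported image format {path.suffix!r}")
    if not path.exists():
        raise UnreadableImage(f"no such file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # decoder errors vary by backend
        raise UnreadableImage(f"cannot decode {path}: {exc}") from exc
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            arr = arr @ _LUMA
        else:
            arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise UnreadableImage(f"{path} is not a 2D image")
    return arr


def write_grayscale_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float image as 8-bit grayscale (clipped to 0..255)."""
    arr = np.clip(np.asarray(image, dtype=float), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


#: columns of a per-measurement audit table
MEASUREMENT_COLUMNS = (
    "patient_id",
    "vessel_type",
    "image_id",
    "repeat",
    "ld_um",
    "od_um",
    "accepted",
    "reason",
)


def write_measurements_csv(path: str | Path, rows: list[dict]) -> None:
    """Write a per-measurement audit table (one row per repeat).

    Rejected repeats carry ``accepted=False`` and the quality-control
    reason; their ``ld_um``/``od_um`` may be missing.
    """
    df = pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))
    df.to_csv(path, index=False)


def read_measurements_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement CSV missing columns: {sorted(missing)}")
    return df


# --------------------------------------------------------------------------
# cohort tables
# --------------------------------------------------------------------------


def cohort_to_frame(cohort: list[PatientRecord]) -> pd.DataFrame:
    """One row per patient, vessel morphometry in ``artery_*``/``vein_*``."""
    rows = []
    for p in cohort:
        row = {
            "id": p.id,
            "group": p.group,
            "sex": p.sex,
            "age": p.age,
            "bmi": p.bmi,
            "diabetes_duration": p.diabetes_duration,
            "dr_stage": p.dr_stage,
        }
        for vessel in ("artery", "vein"):
            v = getattr(p, vessel)
            for k in MORPH_PARAMS:
                row[f"{vessel}_{k}"] = getattr(v, k)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(path: str | Path, cohort: list[PatientRecord]) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[PatientRecord]:
    df = pd.read_csv(path)
    records = []
    for _, r in df.iterrows():
        vessels = {
            vessel: VesselParams(
                **{k: float(r[f"{vessel}_{k}"]) for k in MORPH_PARAMS}
            )
            for vessel in ("artery", "vein")
        }
        records.append(
            PatientRecord(
                id=str(r["id"]),
                group=str(r["group"]),
                sex=str(r["sex"]),
                age=float(r["age"]),
                bmi=float(r["bmi"]),
                diabetes_duration=float(r["diabetes_duration"]),
                dr_stage=int(r["dr_stage"]),
                artery=vessels["artery"],
                vein=vessels["vein"],
            )
        )
    return records
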