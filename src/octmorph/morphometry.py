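"""Per-vessel measurement protocol and morphometric parameters.

A vessel is measured on several cross-sectional images (at least five in the
strict protocol), each measured three times; per-image repeats are averaged
and images averaged with equal weight. From the aggregated lumen diameter
(LD) and outer diameter (OD):

    WT   = (OD − LD) / 2            wall thickness, µm
    WLR  = (OD − LD) / LD           wall-to-lumen ratio
    WCSA = π (OD² − LD²) / 4        wall cross-sectional area, µm²

``pi_mode='paper'`` substitutes the 2-decimal approximation 3.14 for π, for
literal reproduction of tabulated values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import (
    InsufficientMeasurements,
    InvalidGeometry,
    LineOutOfBounds,
    OctMorphError,
)
from .fwhm import (
    MeasureParams,
    TroughEdges,
    VesselBoundaries,
    detect_wall_troughs,
    trough_edges,
)
from .profile import IntensityProfile


@dataclass(frozen=True)
class ScanLine:
    """A straight scan segment in image pixel coordinates (x right, y down)."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    note: str = ""

    def __post_init__(self) -> None:
        if self.p0 == self.p1:
            raise ValueError("scan line endpoints must differ")

    @property
    def length_px(self) -> float:
        return math.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1])


def extract_profile(
    image: np.ndarray,
    line: ScanLine,
    step_px: float = 1.0,
    um_per_px: float = 1.0,
) -> IntensityProfile:
    """Sample an image along a scan line by bilinear interpolation.

    Samples run from ``p0`` towards ``p1`` at uniform ``step_px`` intervals;
    the profile spacing is ``step_px * um_per_px`` with origin at ``p0``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2D grayscale")
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    if not (um_per_px > 0):
        raise ValueError("um_per_px must be positive")
    if not (0 < step_px <= 2):
        raise ValueError("step_px must be in (0, 2]")
    (x0, y0), (x1, y1) = line.p0, line.p1
    h, w = img.shape
    for x, y in (line.p0, line.p1):
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise LineOutOfBounds(f"endpoint ({x}, {y}) outside {w}x{h} image")
    n = int(math.floor(line.length_px / step_px)) + 1
    t = np.arange(n) * step_px / line.length_px
    xs = x0 + t * (x1 - x0)
    ys = y0 + t * (y1 - y0)
    samples = map_coordinates(img, [ys, xs], order=1, mode="nearest")
    samples = np.clip(samples, 0.0, None)
    return IntensityProfile(
        samples=samples, spacing_um=step_px * um_per_px, origin_um=0.0
    )


# --------------------------------------------------------------------------
# measurement with quality control
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ProfileMeasurement:
    """Full outcome of one FWHM measurement on one profile."""

    boundaries: VesselBoundaries
    first_trough: TroughEdges
    second_trough: TroughEdges


def measure_profile_detailed(
    profile: IntensityProfile, params: MeasureParams = MeasureParams()
) -> ProfileMeasurement:
    """Like :func:`octmorph.fwhm.measure_profile` but keeps the per-trough
    FWHM intermediates for quality control."""
    t1, t2 = detect_wall_troughs(
        profile, params.min_contrast, params.min_separation_um
    )
    e1 = trough_edges(profile, t1, k=params.run_length, search_stop=t2.min_index)
    e2 = trough_edges(profile, t2, k=params.run_length, search_start=t1.min_index)
    boundaries = VesselBoundaries(
        outer_first_um=e1.left_edge_um,
        inner_first_um=e1.right_edge_um,
        inner_second_um=e2.left_edge_um,
        outer_second_um=e2.right_edge_um,
    )
    return ProfileMeasurement(boundaries, e1, e2)


def quality_check(
    outcome: ProfileMeasurement | Exception,
    min_contrast: float,
) -> tuple[bool, str]:
    """Accept or reject one measurement attempt.

    Rejects failed trough detection or edge extraction (the wall "cannot be
    distinguished"), any flank whose crest-to-minimum contrast falls below
    ``min_contrast``, and violated geometry invariants.
    """
    if isinstance(outcome, Exception):
        if not isinstance(outcome, OctMorphError):
            raise outcome
        return False, f"measurement failed: {type(outcome).__name__}: {outcome}"
    for name, e in (("first", outcome.first_trough), ("second", outcome.second_trough)):
        for side, crest in (("left", e.crest_left), ("right", e.crest_right)):
            if crest - e.trough_min < min_contrast:
                return False, (
                    f"insufficient wall contrast on {name} trough {side} flank "
                    f"({crest - e.trough_min:.1f} < {min_contrast})"
                )
    b = outcome.boundaries
    if not (b.od_um > b.ld_um > 0):
        return False, "invalid geometry"
    return True, "ok"


@dataclass(frozen=True)
class VesselMeasurement:
    """Aggregated diameters of one vessel over images and repeats.

    For an artery ``ld_um``/``od_um`` are the RALD/RAOD of the protocol; for
    a vein the RVLD/RVOD.
    """

    vessel_type: str  # "artery" | "vein"
    per_image: tuple  # tuple of tuples of VesselBoundaries
    ld_um: float
    od_um: float


def aggregate_measurements(
    per_image: list,
    vessel_type: str = "artery",
    strict: bool = True,
) -> VesselMeasurement:
    """Average repeats within each image, then images with equal weight.

    ``per_image`` is a list (one entry per image) of lists of accepted
    :class:`VesselBoundaries` repeats. The strict protocol requires at least
    five images with exactly three repeats each.
    """
    if vessel_type not in ("artery", "vein"):
        raise ValueError("vessel_type must be 'artery' or 'vein'")
    images = [list(reps) for reps in per_image if reps]
    if not images:
        raise InsufficientMeasurements("no accepted images")
    if strict:
        if len(images) < 5:
            raise InsufficientMeasurements(
                f"strict protocol needs >= 5 images, got {len(images)}"
            )
        if any(len(reps) != 3 for reps in images):
            raise InsufficientMeasurements(
                "strict protocol needs exactly 3 repeats per image"
            )
    image_ld = [float(np.mean([b.ld_um for b in reps])) for reps in images]
    image_od = [float(np.mean([b.od_um for b in reps])) for reps in images]
    ld = float(np.mean(image_ld))
    od = float(np.mean(image_od))
    if not (od > ld):
        raise InvalidGeometry("aggregated od must exceed ld")
    return VesselMeasurement(
        vessel_type=vessel_type,
        per_image=tuple(tuple(reps) for reps in images),
        ld_um=ld,
        od_um=od,
    )


# --------------------------------------------------------------------------
# morphometric parameters
# --------------------------------------------------------------------------


def _pi(pi_mode: str) -> float:
    if pi_mode == "exact":
        return math.pi
    if pi_mode == "paper":
        return 3.14
    raise ValueError("pi_mode must be 'exact' or 'paper'")


def _check_geometry(od_um: float, ld_um: float) -> None:
    if not (od_um > ld_um > 0):
        raise InvalidGeometry(f"need od > ld > 0, got od={od_um}, ld={ld_um}")


def wall_thickness(od_um: float, ld_um: float) -> float:
    """WT = (OD − LD) / 2, µm."""
    _check_geometry(od_um, ld_um)
    return (od_um - ld_um) / 2.0


def wall_to_lumen_ratio(od_um: float, ld_um: float) -> float:
    """WLR = (OD − LD) / LD, dimensionless."""
    _check_geometry(od_um, ld_um)
    return (od_um - ld_um) / ld_um


def wall_cross_sectional_area(
    od_um: float, ld_um: float, pi_mode: str = "exact"
) -> float:
    """WCSA = π (OD² − LD²) / 4, µm² (π → 3.14 under ``pi_mode='paper'``)."""
    _check_geometry(od_um, ld_um)
    return _pi(pi_mode) * (od_um**2 - ld_um**2) / 4.0


@dataclass(frozen=True)
class MorphometricParams:
    """WT / WLR / WCSA of one vessel."""

    wt_um: float
    wlr: float
    wcsa_um2: float
    pi_mode: str = "exact"

    @classmethod
    def from_diameters(
        cls, od_um: float, ld_um: float, pi_mode: str = "exact"
    ) -> "MorphometricParams":
        return cls(
            wt_um=wall_thickness(od_um, ld_um),
            wlr=wall_to_lumen_ratio(od_um, ld_um),
            wcsa_um2=wall_cross_sectional_area(od_um, ld_um, pi_mode),
            pi_mode=pi_mode,
        )
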