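"""Calibrated 1D densitometric line profiles.

An :class:`IntensityProfile` holds the grey values sampled along a scan line
through a vessel cross-section, together with the physical sample spacing in
micrometres. Sample *i* sits at ``origin_um + i * spacing_um``. All sub-pixel
edge positions produced by the FWHM machinery are continuous coordinates on
this axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ProfileTooShort

#: minimum number of samples required for an FWHM measurement
MIN_SAMPLES = 15


@dataclass(frozen=True)
class IntensityProfile:
    """Ordered intensity samples along a scan line.

    Parameters
    ----------
    samples
        Non-negative intensities on an 8-bit-like arbitrary scale.
    spacing_um
        Distance between consecutive samples, micrometres (> 0).
    origin_um
        Physical position of sample 0, micrometres.
    """

    samples: np.ndarray
    spacing_um: float
    origin_um: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", arr)
        if arr.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples must be finite")
        if arr.size and arr.min() < 0:
            raise ValueError("samples must be non-negative")
        if not (self.spacing_um > 0):
            raise ValueError("spacing_um must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def positions_um(self) -> np.ndarray:
        """Physical positions of every sample (µm)."""
        return self.origin_um + self.spacing_um * np.arange(self.samples.size)

    def position(self, index: float) -> float:
        """Physical position (µm) of a possibly fractional sample index."""
        return self.origin_um + self.spacing_um * float(index)

    def index(self, position_um: float) -> float:
        """Fractional sample index of a physical position (µm)."""
        return (float(position_um) - self.origin_um) / self.spacing_um

    def require_measurable(self) -> None:
        """Raise :class:`ProfileTooShort` if too short for the FWHM method."""
        if self.samples.size < MIN_SAMPLES:
            raise ProfileTooShort(
                f"profile has {self.samples.size} samples; "
                f"at least {MIN_SAMPLES} required"
            )

    # -- serialization -----------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the profile as two-column CSV (position_um, intensity)."""
        data = np.column_stack([self.positions_um, self.samples])
        np.savetxt(
            path, data, delimiter=",", header="position_um,intensity", comments=""
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "IntensityProfile":
        """Read a two-column CSV (position_um, intensity).

        Positions must be uniformly spaced; spacing and origin are inferred.
        """
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        pos, inten = data[:, 0], data[:, 1]
        if pos.size < 2:
            raise ProfileTooShort("profile CSV needs at least two samples")
        steps = np.diff(pos)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("profile CSV positions must be uniformly spaced")
        return cls(samples=inten, spacing_um=float(steps[0]), origin_um=float(pos[0]))
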