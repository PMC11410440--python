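"""Full-width-at-half-maximum (FWHM) sub-pixel wall segmentation.

A vessel cross-section seen along a densitometric line profile shows two
concave-upward troughs — the near and far vessel walls, darker than both the
surrounding tissue and the lumen between them. For each wall trough the
procedure is:

1. locate the trough as a local minimum of the 3-sample moving mean;
2. on each flank, take the crest and the trough minimum as the largest and
   smallest mean of three consecutive samples, and set the half level to
   their arithmetic midpoint (the "half maximum");
3. fit a least-squares line through the run of ``k`` consecutive samples with
   the steepest endpoint difference on that flank;
4. the wall edge is the continuous position where this line crosses the half
   level.

The inner edges of the two troughs delimit the lumen diameter (LD), the outer
edges the outer diameter (OD). All positions are continuous micrometre
coordinates; on a noiseless phantom with linear ramps each edge coincides with
the analytic half-maximum crossing (the ramp midpoint).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, peak_prominences

from .errors import (
    EdgeOutOfFlank,
    FlatFlank,
    InvalidGeometry,
    TwoTroughsNotFound,
    ZeroSlope,
)
from .profile import IntensityProfile

#: default run length for the steepest-segment line fit
DEFAULT_RUN_LENGTH = 3
#: default minimum crest-to-trough contrast (intensity units)
DEFAULT_MIN_CONTRAST = 10.0
#: default minimum separation between the two wall trough minima (µm)
DEFAULT_MIN_SEPARATION_UM = 5.0

_FLAT_TOL = 1e-9


@dataclass(frozen=True)
class TroughSegment:
    """One wall trough: inclusive sample-index extent and its minimum."""

    start_index: int
    end_index: int
    min_index: int

    def __post_init__(self) -> None:
        if not (self.start_index < self.min_index < self.end_index):
            raise InvalidGeometry(
                f"trough indices must satisfy start < min < end, got "
                f"{self.start_index}/{self.min_index}/{self.end_index}"
            )


@dataclass(frozen=True)
class TroughEdges:
    """Sub-pixel edges of one wall trough with the FWHM intermediates."""

    left_edge_um: float
    right_edge_um: float
    crest_left: float
    crest_right: float
    trough_min: float
    half_left: float
    half_right: float

    @property
    def width_um(self) -> float:
        return self.right_edge_um - self.left_edge_um


@dataclass(frozen=True)
class VesselBoundaries:
    """Four sub-pixel wall-edge positions and the derived diameters (µm)."""

    outer_first_um: float
    inner_first_um: float
    inner_second_um: float
    outer_second_um: float

    def __post_init__(self) -> None:
        o1, i1, i2, o2 = (
            self.outer_first_um,
            self.inner_first_um,
            self.inner_second_um,
            self.outer_second_um,
        )
        if not (o1 < i1 < i2 < o2):
            raise InvalidGeometry(
                f"boundary ordering violated: {o1:.3f}/{i1:.3f}/{i2:.3f}/{o2:.3f}"
            )

    @property
    def ld_um(self) -> float:
        """Lumen diameter: distance between the inner edges."""
        return self.inner_second_um - self.inner_first_um

    @property
    def od_um(self) -> float:
        """Outer diameter: distance between the outer edges."""
        return self.outer_second_um - self.outer_first_um


@dataclass(frozen=True)
class MeasureParams:
    """Tunable parameters of the FWHM measurement."""

    min_contrast: float = DEFAULT_MIN_CONTRAST
    min_separation_um: float = DEFAULT_MIN_SEPARATION_UM
    run_length: int = DEFAULT_RUN_LENGTH


def moving_mean3(samples: np.ndarray) -> np.ndarray:
    """3-sample moving mean, 'valid' mode (no edge padding).

    Output element ``j`` averages input samples ``j..j+2`` and is centred on
    input index ``j + 1``.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    return np.convolve(x, np.full(3, 1.0 / 3.0), mode="valid")


def detect_wall_troughs(
    profile: IntensityProfile,
    min_contrast: float = DEFAULT_MIN_CONTRAST,
    min_separation_um: float = DEFAULT_MIN_SEPARATION_UM,
) -> tuple[TroughSegment, TroughSegment]:
    """Locate the two wall troughs of a vessel profile.

    Candidate troughs are local minima of the 3-sample moving mean whose
    prominence (crest-to-minimum contrast on the shallower flank) reaches
    ``min_contrast``; the two most prominent candidates at least
    ``min_separation_um`` apart are returned in positional order, split at
    the lumen crest between them.

    Raises
    ------
    TwoTroughsNotFound
        If fewer than two qualifying minima exist.
    ProfileTooShort
        If the profile is too short to measure.
    """
    profile.require_measurable()
    if min_contrast <= 0:
        raise ValueError("min_contrast must be positive")
    s = moving_mean3(profile.samples)

    candidates, _ = find_peaks(-s)
    if candidates.size < 2:
        raise TwoTroughsNotFound(
            f"found {candidates.size} candidate trough(s); need 2"
        )
    prom = peak_prominences(-s, candidates)[0]
    qualified = candidates[prom >= min_contrast]
    qprom = prom[prom >= min_contrast]
    if qualified.size < 2:
        raise TwoTroughsNotFound(
            f"found {qualified.size} trough(s) with contrast >= {min_contrast}"
        )

    # two most prominent, respecting the minimum separation
    order = np.argsort(qprom)[::-1]
    first = qualified[order[0]]
    second = None
    min_sep_samples = min_separation_um / profile.spacing_um
    for idx in order[1:]:
        if abs(qualified[idx] - first) >= min_sep_samples:
            second = qualified[idx]
            break
    if second is None:
        raise TwoTroughsNotFound(
            f"no second trough at least {min_separation_um} um from the first"
        )
    m1, m2 = sorted((int(first), int(second)))

    # lumen crest between the minima; plateau split left/right for
    # non-overlapping segments
    between = s[m1 : m2 + 1]
    crest_left_rel = int(np.argmax(between))
    crest_right_rel = between.size - 1 - int(np.argmax(between[::-1]))
    lumen_left = m1 + crest_left_rel
    lumen_right = m1 + crest_right_rel

    outer_left = int(np.argmax(s[: m1 + 1]))
    tail = s[m2:]
    outer_right = m2 + (tail.size - 1 - int(np.argmax(tail[::-1])))

    # smoothed index j is centred on raw sample j + 1
    seg1 = TroughSegment(outer_left + 1, lumen_left + 1, m1 + 1)
    seg2 = TroughSegment(lumen_right + 1, outer_right + 1, m2 + 1)
    return seg1, seg2


@dataclass(frozen=True)
class _FlankInfo:
    crest: float
    crest_index: int  # raw-sample index of the crest window centre
    minimum: float
    min_index: int  # raw-sample index of the minimum window centre


def _windowed_means(samples: np.ndarray, lo: int, hi: int) -> tuple[np.ndarray, int]:
    """3-sample window means for windows fully inside [lo, hi] (inclusive)."""
    lo = max(0, lo)
    hi = min(samples.size - 1, hi)
    if hi - lo + 1 < 3:
        # degenerate window: fall back to the raw samples as 1-wide "means"
        return samples[lo : hi + 1].copy(), lo
    means = moving_mean3(samples[lo : hi + 1])
    return means, lo + 1  # centre index of the first window


def _flank_info(
    profile: IntensityProfile,
    trough: TroughSegment,
    side: str,
    search_start: int | None = None,
    search_stop: int | None = None,
) -> _FlankInfo:
    x = profile.samples
    n = x.size
    if trough.end_index >= n:
        raise InvalidGeometry("trough segment exceeds profile")

    seg_means, seg_c0 = _windowed_means(x, trough.start_index, trough.end_index)
    k_min = int(np.argmin(seg_means))
    minimum = float(seg_means[k_min])
    min_center = seg_c0 + k_min

    if side == "left":
        lo = 0 if search_start is None else search_start
        means, c0 = _windowed_means(x, lo, trough.min_index)
        if means.size == 0:
            raise FlatFlank("no crest window on the left flank")
        best = float(np.max(means))
        # nearest maximizing window to the trough: rightmost tie
        j = means.size - 1 - int(np.argmax(np.isclose(means[::-1], best)))
        crest_center = c0 + j
    elif side == "right":
        hi = n - 1 if search_stop is None else search_stop
        means, c0 = _windowed_means(x, trough.min_index, hi)
        if means.size == 0:
            raise FlatFlank("no crest window on the right flank")
        best = float(np.max(means))
        # nearest maximizing window to the trough: leftmost tie
        j = int(np.argmax(np.isclose(means, best)))
        crest_center = c0 + j
    else:
        raise ValueError("side must be 'left' or 'right'")

    crest = best
    scale = max(abs(crest), abs(minimum), 1.0)
    if crest - minimum < _FLAT_TOL * scale:
        raise FlatFlank(
            f"{side} flank contrast {crest - minimum:.3g} below machine tolerance"
        )
    return _FlankInfo(crest, crest_center, minimum, min_center)


def flank_extrema(
    profile: IntensityProfile,
    trough: TroughSegment,
    side: str,
    search_start: int | None = None,
    search_stop: int | None = None,
) -> tuple[float, float]:
    """Crest and minimum intensity of one flank of a wall trough.

    The minimum is the smallest mean of any three consecutive samples inside
    the trough segment; the crest is the largest such mean between the trough
    minimum and the flank's search bound (profile end or the neighbouring
    trough's minimum).
    """
    info = _flank_info(profile, trough, side, search_start, search_stop)
    return info.crest, info.minimum


def steepest_run_line(
    profile: IntensityProfile,
    flank_start: int,
    flank_end: int,
    k: int = DEFAULT_RUN_LENGTH,
) -> tuple[float, float]:
    """Least-squares line through the steepest run of ``k`` samples.

    Among all runs of ``k`` consecutive samples within the inclusive index
    window, the run maximising ``|I[last] - I[first]]`` is selected (ties go
    to the leftmost run). Returns ``(slope, intercept)`` of the fitted line in
    intensity-per-µm / intensity-at-origin units.
    """
    if k < 2:
        raise ValueError("run length k must be >= 2")
    if flank_end - flank_start + 1 < k:
        raise ValueError("flank window shorter than run length")
    x = profile.samples
    starts = np.arange(flank_start, flank_end - k + 2)
    diffs = np.abs(x[starts + k - 1] - x[starts])
    j = int(starts[np.argmax(diffs)])
    run_idx = np.arange(j, j + k)
    xs = profile.origin_um + profile.spacing_um * run_idx
    ys = x[run_idx]
    slope, intercept = np.polyfit(xs, ys, 1)
    if abs(slope) < 1e-12:
        raise ZeroSlope(f"steepest run at samples {j}..{j + k - 1} is flat")
    return float(slope), float(intercept)


def edge_position(
    slope: float,
    intercept: float,
    level: float,
    flank_start_um: float,
    flank_end_um: float,
) -> float:
    """Crossing of the fitted flank line with the horizontal half level.

    The crossing may extrapolate beyond the selected run but must stay inside
    the flank window.
    """
    if slope == 0:
        raise ZeroSlope("cannot intersect a horizontal line with the half level")
    x = (level - intercept) / slope
    tol = 1e-9 * max(1.0, abs(flank_end_um - flank_start_um))
    if not (flank_start_um - tol <= x <= flank_end_um + tol):
        raise EdgeOutOfFlank(
            f"half-level crossing {x:.3f} um outside flank "
            f"[{flank_start_um:.3f}, {flank_end_um:.3f}] um"
        )
    return float(x)


def trough_edges(
    profile: IntensityProfile,
    trough: TroughSegment,
    k: int = DEFAULT_RUN_LENGTH,
    search_start: int | None = None,
    search_stop: int | None = None,
) -> TroughEdges:
    """FWHM edges of a single wall trough.

    For each flank the half level is the arithmetic midpoint of that flank's
    crest and the trough minimum; the edge is where the steepest-run line
    crosses it. ``search_start``/``search_stop`` bound the crest search (use
    the neighbouring trough's minimum when measuring a two-wall profile).
    """
    left = _flank_info(profile, trough, "left", search_start=search_start)
    right = _flank_info(profile, trough, "right", search_stop=search_stop)
    half_left = 0.5 * (left.crest + left.minimum)
    half_right = 0.5 * (right.crest + right.minimum)

    def _edge(c_idx: int, m_idx: int, half: float) -> float:
        lo, hi = min(c_idx, m_idx), max(c_idx, m_idx)
        # widen a too-short window (sharp edge) to admit a k-run
        while hi - lo + 1 < k:
            if lo > 0:
                lo -= 1
            elif hi < len(profile) - 1:
                hi += 1
            else:
                raise ZeroSlope("flank too short for the run-line fit")
        slope, intercept = steepest_run_line(profile, lo, hi, k)
        return edge_position(
            slope, intercept, half, profile.position(lo), profile.position(hi)
        )

    left_edge = _edge(left.crest_index, left.min_index, half_left)
    right_edge = _edge(right.min_index, right.crest_index, half_right)
    if not (left_edge < right_edge):
        raise InvalidGeometry(
            f"left edge {left_edge:.3f} um not left of right edge {right_edge:.3f} um"
        )
    return TroughEdges(
        left_edge_um=left_edge,
        right_edge_um=right_edge,
        crest_left=left.crest,
        crest_right=right.crest,
        trough_min=min(left.minimum, right.minimum),
        half_left=half_left,
        half_right=half_right,
    )


def measure_profile(
    profile: IntensityProfile, params: MeasureParams = MeasureParams()
) -> VesselBoundaries:
    """Measure lumen and outer diameter of a two-wall vessel profile.

    Detects the two wall troughs, extracts FWHM edges for each (crest searches
    bounded by the neighbouring trough), and pairs them: the edges facing the
    lumen are the inner boundaries, the remaining two the outer boundaries.
    """
    t1, t2 = detect_wall_troughs(
        profile, params.min_contrast, params.min_separation_um
    )
    e1 = trough_edges(profile, t1, k=params.run_length, search_stop=t2.min_index)
    e2 = trough_edges(profile, t2, k=params.run_length, search_start=t1.min_index)
    return VesselBoundaries(
        outer_first_um=e1.left_edge_um,
        inner_first_um=e1.right_edge_um,
        inner_second_um=e2.left_edge_um,
        outer_second_um=e2.right_edge_um,
    )
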