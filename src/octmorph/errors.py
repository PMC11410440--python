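"""Typed errors raised by the measurement pipeline.

Degenerate or unmeasurable inputs raise rather than returning NaN so that the
quality-control layer can log an explicit rejection reason for every image.
"""


class OctMorphError(Exception):
    """Base class for all pipeline errors."""


class ProfileTooShort(OctMorphError):
    """Profile has too few samples for the FWHM procedure."""


class TwoTroughsNotFound(OctMorphError):
    """Fewer than two qualifying wall troughs in the intensity profile."""


class FlatFlank(OctMorphError):
    """Crest and trough minimum are indistinguishable on a flank."""


class ZeroSlope(OctMorphError):
    """The selected steepest run is flat; no half-level crossing exists."""


class EdgeOutOfFlank(OctMorphError):
    """The fitted line crosses the half level outside the flank window."""


class InvalidGeometry(OctMorphError):
    """Measured boundary ordering or diameter invariants are violated."""


class LineOutOfBounds(OctMorphError):
    """A scan line leaves the image."""


class InsufficientMeasurements(OctMorphError):
    """Strict protocol requires at least five images with three repeats each."""


class DegenerateInput(OctMorphError):
    """Statistical routine received constant or undersized data."""


class ZeroMarginal(OctMorphError):
    """A 2x2 contingency table has an empty row or column."""


class EmptyGroup(OctMorphError):
    """A cohort operation requires both NDR and DR groups to be non-empty."""


class GeometryDoesNotFit(OctMorphError):
    """Synthetic vessel does not fit in the requested window/image."""


class InvalidSpec(OctMorphError):
    """Cohort specification violates its invariants."""


class UnknownPreset(OctMorphError):
    """Unrecognised cohort preset name."""


class UnreadableImage(OctMorphError):
    """Image file missing or not decodable as 8-bit grayscale."""


class UnsupportedFormat(OctMorphError):
    """Image file extension/format outside BMP/PNG/TIFF."""


class ConfigError(OctMorphError):
    """Pipeline configuration contains unknown keys or out-of-range values."""
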