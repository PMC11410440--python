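import numpy as np
import pytest

from octmorph import IntensityProfile
from octmorph.synthetic import SyntheticVesselTruth, render_profile


@pytest.fixture
def hand_profile() -> IntensityProfile:
    """Symmetric single-trough profile used for hand-computed FWHM values."""
    samples = np.array(
        [100, 100, 100, 80, 60, 40, 20, 20, 20, 40, 60, 80, 100, 100, 100],
        dtype=float,
    )
    return IntensityProfile(samples=samples, spacing_um=1.0)


@pytest.fixture
def phantom_truth() -> SyntheticVesselTruth:
    """Noiseless two-wall phantom: LD 20 µm, OD 30 µm, boundaries 15/20/40/45."""
    return SyntheticVesselTruth(
        center_um=30.0, ld_true_um=20.0, od_true_um=30.0, ramp_halfwidth_um=1.0
    )


@pytest.fixture
def phantom_profile(phantom_truth):
    prof, boundaries = render_profile(phantom_truth, spacing_um=1.0)
    return prof, boundaries
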