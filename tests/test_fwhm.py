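"""FWHM edge detection: hand-computed oracles, phantom oracle, invariances."""

import numpy as np
import pytest

from octmorph import IntensityProfile, MeasureParams, measure_profile
from octmorph.errors import (
    EdgeOutOfFlank,
    FlatFlank,
    ProfileTooShort,
    TwoTroughsNotFound,
    ZeroSlope,
)
from octmorph.fwhm import (
    TroughSegment,
    detect_wall_troughs,
    edge_position,
    flank_extrema,
    steepest_run_line,
    trough_edges,
)
from octmorph.synthetic import SyntheticVesselTruth, render_profile


class TestDetectWallTroughs:
    def test_phantom_minima_near_wall_centres(self, phantom_profile):
        prof, _ = phantom_profile
        t1, t2 = detect_wall_troughs(prof)
        # wall bands are 15-20 and 40-45 um; smoothed minima near 17.5 / 42.5
        assert abs(prof.position(t1.min_index) - 17.5) <= 1.5
        assert abs(prof.position(t2.min_index) - 42.5) <= 1.5
        assert t1.end_index <= t2.start_index

    def test_constant_profile_has_no_troughs(self):
        prof = IntensityProfile(np.full(30, 100.0), 1.0)
        with pytest.raises(TwoTroughsNotFound):
            detect_wall_troughs(prof)

    def test_single_dip_is_rejected(self, hand_profile):
        with pytest.raises(TwoTroughsNotFound):
            detect_wall_troughs(hand_profile)

    def test_short_profile_rejected(self):
        prof = IntensityProfile(np.array([1.0, 2.0, 1.0] * 3), 1.0)
        with pytest.raises(ProfileTooShort):
            detect_wall_troughs(prof)


class TestFlankExtrema:
    def test_hand_profile_left_and_right(self, hand_profile):
        seg = TroughSegment(3, 11, 7)
        assert flank_extrema(hand_profile, seg, "left") == pytest.approx((100.0, 20.0))
        assert flank_extrema(hand_profile, seg, "right") == pytest.approx((100.0, 20.0))

    def test_flat_profile_raises(self):
        prof = IntensityProfile(np.full(15, 50.0), 1.0)
        with pytest.raises(FlatFlank):
            flank_extrema(prof, TroughSegment(3, 11, 7), "left")


class TestSteepestRunLine:
    def test_hand_profile_left_flank(self, hand_profile):
        slope, intercept = steepest_run_line(hand_profile, 2, 6, k=3)
        assert slope == pytest.approx(-20.0)
        # the fitted line passes through (4 um, 60)
        assert intercept + slope * 4.0 == pytest.approx(60.0)

    def test_exact_line_recovered(self):
        x = np.arange(20, dtype=float)
        prof = IntensityProfile(5 * x + 7, 1.0)
        slope, intercept = steepest_run_line(prof, 0, 19, k=3)
        assert (slope, intercept) == pytest.approx((5.0, 7.0))

    def test_flat_run_raises(self):
        prof = IntensityProfile(np.full(15, 50.0), 1.0)
        with pytest.raises(ZeroSlope):
            steepest_run_line(prof, 0, 3, k=3)


class TestEdgePosition:
    def test_hand_crossing(self):
        # line with slope -20 through (3 um, 80): I = -20x + 140
        assert edge_position(-20.0, 140.0, 60.0, 2.0, 6.0) == pytest.approx(4.0)

    def test_identity_line(self):
        assert edge_position(1.0, 0.0, 5.0, 0.0, 10.0) == pytest.approx(5.0)

    def test_crossing_outside_flank(self):
        with pytest.raises(EdgeOutOfFlank):
            edge_position(1.0, 0.0, 50.0, 0.0, 10.0)


class TestTroughEdges:
    def test_hand_profile(self, hand_profile):
        te = trough_edges(hand_profile, TroughSegment(3, 11, 7), k=3)
        assert te.left_edge_um == pytest.approx(4.0)
        assert te.right_edge_um == pytest.approx(10.0)
        assert te.half_left == pytest.approx(60.0)
        assert te.half_right == pytest.approx(60.0)
        assert te.width_um == pytest.approx(6.0)

    def test_translation_equivariance(self, hand_profile):
        shifted = IntensityProfile(hand_profile.samples, 1.0, origin_um=3.0)
        te = trough_edges(shifted, TroughSegment(3, 11, 7), k=3)
        assert te.left_edge_um == pytest.approx(7.0)
        assert te.right_edge_um == pytest.approx(13.0)

    def test_affine_intensity_invariance(self, hand_profile):
        mapped = IntensityProfile(2.0 * hand_profile.samples + 10.0, 1.0)
        te = trough_edges(mapped, TroughSegment(3, 11, 7), k=3)
        assert te.left_edge_um == pytest.approx(4.0)
        assert te.right_edge_um == pytest.approx(10.0)


class TestMeasureProfile:
    def test_noiseless_phantom_recovers_truth(self, phantom_profile):
        prof, (b1, b2, b3, b4) = phantom_profile
        m = measure_profile(prof)
        assert m.ld_um == pytest.approx(20.0, abs=0.1)
        assert m.od_um == pytest.approx(30.0, abs=0.1)
        for got, want in zip(
            (m.outer_first_um, m.inner_first_um, m.inner_second_um, m.outer_second_um),
            (b1, b2, b3, b4),
        ):
            assert got == pytest.approx(want, abs=0.1)

    def test_resolution_invariance(self, phantom_truth):
        prof, _ = render_profile(phantom_truth, spacing_um=0.5)
        m = measure_profile(prof)
        assert m.ld_um == pytest.approx(20.0, abs=0.1)
        assert m.od_um == pytest.approx(30.0, abs=0.1)

    def test_single_trough_profile_fails(self, hand_profile):
        with pytest.raises(TwoTroughsNotFound):
            measure_profile(hand_profile)


class TestProfileInvariances:
    """Exact symmetries of the measurement on a rendered phantom."""

    def _measure(self, prof):
        return measure_profile(prof)

    def test_translation_shifts_all_edges(self, phantom_truth):
        prof, _ = render_profile(phantom_truth, spacing_um=1.0)
        shifted = IntensityProfile(prof.samples, prof.spacing_um, origin_um=7.25)
        m0, m1 = self._measure(prof), self._measure(shifted)
        for a, b in zip(
            (m0.outer_first_um, m0.inner_first_um, m0.inner_second_um, m0.outer_second_um),
            (m1.outer_first_um, m1.inner_first_um, m1.inner_second_um, m1.outer_second_um),
        ):
            assert b - a == pytest.approx(7.25, abs=1e-9)

    def test_affine_intensity_leaves_edges(self, phantom_truth):
        prof, _ = render_profile(phantom_truth, spacing_um=1.0)
        mapped = IntensityProfile(1.7 * prof.samples + 13.0, prof.spacing_um)
        m0, m1 = self._measure(prof), self._measure(mapped)
        assert m1.ld_um == pytest.approx(m0.ld_um, abs=1e-9)
        assert m1.od_um == pytest.approx(m0.od_um, abs=1e-9)

    def test_reflection_mirrors_edges(self, phantom_truth):
        prof, _ = render_profile(phantom_truth, spacing_um=1.0)
        mirrored = IntensityProfile(prof.samples[::-1].copy(), prof.spacing_um)
        m0, m1 = self._measure(prof), self._measure(mirrored)
        end = prof.position(len(prof) - 1)
        assert m1.ld_um == pytest.approx(m0.ld_um, abs=1e-6)
        assert m1.od_um == pytest.approx(m0.od_um, abs=1e-6)
        assert m1.outer_first_um == pytest.approx(end - m0.outer_second_um, abs=1e-6)
        assert m1.inner_first_um == pytest.approx(end - m0.inner_second_um, abs=1e-6)

    def test_measured_ld_monotone_in_true_ld(self):
        measured = []
        for ld in (14.0, 18.0, 22.0, 26.0):
            truth = SyntheticVesselTruth(
                center_um=30.0, ld_true_um=ld, od_true_um=ld + 10.0
            )
            prof, _ = render_profile(truth, spacing_um=1.0)
            measured.append(measure_profile(prof).ld_um)
        assert all(a < b for a, b in zip(measured, measured[1:]))


class TestNoiseRobustness:
    def test_mean_ld_error_under_additive_noise(self):
        """Contrast 150, noise SD 5: mean |LD error| over 100 seeded
        replicates stays within half a micron."""
        errors = []
        for seed in range(100):
            truth = SyntheticVesselTruth(
                center_um=30.0, ld_true_um=20.0, od_true_um=30.0,
                noise_sd=5.0, seed=seed,
            )
            prof, _ = render_profile(truth, spacing_um=1.0)
            m = measure_profile(prof, MeasureParams(min_contrast=30.0))
            errors.append(abs(m.ld_um - 20.0))
        assert np.mean(errors) <= 0.5
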