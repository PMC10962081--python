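import numpy as np
import pytest
from helpers import welch_by_hand

from loopstate.exceptions import AnalysisError, InsufficientDataError, ValidationError
from loopstate.io_formats import IntensityProfile, PolylineROI
from loopstate.profile_analysis import (
    CrossCorrResult,
    cross_correlate,
    displacement_summary,
    extract_profile,
    find_peaks,
    spacing_stats,
)
from loopstate.synthetic_data import ProfileSimConfig, simulate_paired_profiles


class TestExtractProfile:
    PS = 20.0  # pixel size, nm

    def test_constant_grid_gives_constant_profile(self):
        grid = np.full((2, 10, 20), 7.0)
        roi = PolylineROI("r", [(50, 100), (350, 100)])
        prof = extract_profile(grid, self.PS, roi, step=20.0)
        assert prof.n == 16
        assert np.allclose(prof.channel_a, 7.0)
        assert np.allclose(prof.channel_b, 7.0)

    def test_bright_column_peaks_at_its_arc_position(self):
        """Horizontal ROI crossing a single bright pixel column: bilinear weights
        put the profile maximum exactly at the column's x position."""
        grid = np.zeros((2, 10, 30))
        grid[:, :, 10] = 1.0  # pixel centre at x = 210 nm
        roi = PolylineROI("r", [(10, 90), (590, 90)])  # starts at x=10, y on a centre row
        prof = extract_profile(grid, self.PS, roi, step=5.0)
        s_max = prof.positions[np.argmax(prof.channel_a)]
        assert s_max + 10 == pytest.approx(210, abs=2.5)
        # hand bilinear check at a sample between pixel centres 9 and 10
        s = 185.0  # x = 195 nm -> 25% of the way from centre 190 to 210
        i = int(s / 5.0)
        assert prof.channel_a[i] == pytest.approx(0.25)

    def test_sampling_at_pixel_pitch_reproduces_pixel_values(self):
        rng = np.random.default_rng(0)
        grid = rng.random((2, 8, 12))
        row = 3
        roi = PolylineROI("r", [(10, (row + 0.5) * self.PS), (230, (row + 0.5) * self.PS)])
        prof = extract_profile(grid, self.PS, roi, step=self.PS)
        assert prof.n == 12
        assert np.allclose(prof.channel_a, grid[0, row, :12])

    def test_roi_outside_grid_names_vertex(self):
        grid = np.zeros((2, 5, 5))
        roi = PolylineROI("r", [(10, 10), (1000, 10)])
        with pytest.raises(ValidationError, match="vertex 1"):
            extract_profile(grid, self.PS, roi, step=10.0)


class TestFindPeaks:
    def test_monotone_profile_has_no_peaks(self):
        prof = IntensityProfile("r", 20.0, np.arange(10.0), np.arange(10.0))
        assert len(find_peaks(prof, "a", 0.17)) == 0

    def test_two_peak_fixture_prominence_thresholding(self):
        values = np.array([0.0, 1.0, 0.0, 2.0, 0.0])
        prof = IntensityProfile("r", 20.0, values, values)
        peaks = find_peaks(prof, "b", tolerance_factor=0.5)
        assert peaks.positions.tolist() == [20.0, 60.0]
        assert len(find_peaks(prof, "b", tolerance_factor=3.0)) == 0

    def test_affine_intensity_rescaling_invariance(self, rng):
        values = np.abs(rng.normal(1, 0.5, 60)) + 0.1
        p1 = IntensityProfile("r", 20.0, values, values)
        p2 = IntensityProfile("r", 20.0, 5.0 * values + 3.0, 5.0 * values + 3.0)
        for tol in (0.17, 0.5, 1.0):
            assert np.array_equal(
                find_peaks(p1, "a", tol).positions, find_peaks(p2, "a", tol).positions
            )

    def test_plateau_reports_midpoint(self):
        values = np.array([0.0, 0.0, 3.0, 3.0, 3.0, 0.0, 0.0])
        prof = IntensityProfile("r", 10.0, values, values)
        assert find_peaks(prof, "a", 0.1).positions.tolist() == [30.0]

    def test_zero_variance_warns_and_returns_empty(self):
        prof = IntensityProfile("r", 20.0, np.ones(10), np.ones(10))
        with pytest.warns(UserWarning, match="zero-variance"):
            assert len(find_peaks(prof, "a", 0.17)) == 0

    def test_higher_tolerance_selects_subset_of_peaks(self, rng):
        cfg = ProfileSimConfig(n_profiles=3, spacing_mean=276, spacing_sd=164,
                               noise_sd=0.05, seed=33)
        profiles, _ = simulate_paired_profiles(cfg)
        for p in profiles:
            lo = set(find_peaks(p, "b", 0.17).positions)
            hi = set(find_peaks(p, "b", 1.0).positions)
            assert hi <= lo


class TestSpacingStats:
    def test_successive_differences_single_roi(self):
        from loopstate.profile_analysis import PeakSet

        ps = PeakSet("r", np.array([0.0, 100.0, 300.0]), 0.17, "b")
        stats = spacing_stats([ps])
        assert stats.spacings.tolist() == [100.0, 200.0]
        assert stats.mean == 150.0

    def test_pools_across_rois(self):
        from loopstate.profile_analysis import PeakSet

        sets = [
            PeakSet("r1", np.array([0.0, 100.0]), 0.17, "b"),
            PeakSet("r2", np.array([0.0, 250.0]), 0.17, "b"),
            PeakSet("r3", np.array([40.0]), 0.17, "b"),  # too few peaks, ignored
        ]
        stats = spacing_stats(sets)
        assert sorted(stats.spacings) == [100.0, 250.0]
        assert stats.n == 2

    def test_no_usable_peaksets_rejected(self):
        from loopstate.profile_analysis import PeakSet

        with pytest.raises(InsufficientDataError):
            spacing_stats([PeakSet("r", np.array([10.0]), 0.17, "b")])

    def test_recovered_mean_tracks_truth_at_high_snr(self):
        cfg = ProfileSimConfig(
            n_profiles=8, profile_length=10000, spacing_mean=400, spacing_sd=60,
            peak_fwhm=100, noise_sd=0.02, seed=3,
        )
        profiles, truth = simulate_paired_profiles(cfg)
        stats = spacing_stats([find_peaks(p, "b", 0.3) for p in profiles])
        se = truth.true_spacings.std(ddof=1) / np.sqrt(len(truth.true_spacings))
        assert abs(stats.mean - truth.true_spacings.mean()) < 3 * se + 1


class TestCrossCorrelate:
    def test_identical_channels_zero_lag_unit_corr(self, rng):
        v = np.abs(rng.normal(1, 0.3, 100))
        prof = IntensityProfile("r", 20.0, v, v)
        res = cross_correlate(prof, 400.0)
        assert res.best_lag == 0.0
        assert res.best_corr == pytest.approx(1.0)
        assert res.significant

    def test_integer_sample_shift_recovered_exactly(self, rng):
        v = np.abs(rng.normal(1, 0.3, 200))
        prof = IntensityProfile("r", 20.0, v, np.roll(v, 10))
        res = cross_correlate(prof, 400.0)
        assert abs(res.best_lag) == 200.0
        assert abs(res.best_corr) > 0.9

    def test_antisymmetry_under_channel_swap(self, rng):
        cfg = ProfileSimConfig(n_profiles=1, channel_shift=200, noise_sd=0.1, seed=5)
        (prof,), _ = simulate_paired_profiles(cfg)
        swapped = IntensityProfile(prof.roi_id, prof.step, prof.channel_b, prof.channel_a)
        assert cross_correlate(prof, 600.0).best_lag == -cross_correlate(swapped, 600.0).best_lag

    def test_white_noise_correlations_stay_small_and_flag_follows_cutoff(self, rng):
        """Independent white-noise channels: per-lag correlations behave like the
        1.96/sqrt(n) theory (about 5% exceedances at a fixed lag) and the
        significance flag applies exactly that cutoff to the best lag."""
        n_exceed_at_zero = 0
        for _ in range(40):
            a = rng.random(100)
            b = rng.random(100)
            res = cross_correlate(IntensityProfile("r", 20.0, a, b), 200.0)
            assert abs(res.best_corr) < 0.5  # far below any real-signal correlation
            assert res.significant == (abs(res.best_corr) > 1.96 / np.sqrt(res.n))
            zero_lag = res.corr[len(res.lags) // 2]
            n_exceed_at_zero += abs(zero_lag) > 1.96 / np.sqrt(100)
        assert n_exceed_at_zero <= 8  # ~5% expected at a single fixed lag

    def test_lag_recovery_within_one_step_at_high_snr(self):
        """Over many seeds at SNR >= 10, the recovered displacement never misses
        the true one by more than one sampling step."""
        for seed in range(25):
            cfg = ProfileSimConfig(
                n_profiles=1, channel_shift=200, noise_sd=0.1, seed=seed
            )
            (prof,), truth = simulate_paired_profiles(cfg)
            res = cross_correlate(prof, 1000.0)
            assert abs(abs(res.best_lag) - truth.true_shift) <= prof.step

    def test_zero_variance_channel_rejected(self):
        prof = IntensityProfile("r", 20.0, np.ones(50), np.arange(50.0))
        with pytest.raises(AnalysisError):
            cross_correlate(prof, 200.0)


class TestDisplacementSummary:
    @staticmethod
    def _result(lag, significant=True):
        return CrossCorrResult(
            "r", np.array([lag]), np.array([0.9]), lag, 0.9, 100, significant
        )

    def test_identical_conditions_are_indistinguishable(self):
        res = [self._result(l) for l in (40.0, 50.0, 60.0)]
        a, b = displacement_summary(res, list(res))
        assert a.median_abs_lag == b.median_abs_lag == 50.0
        assert a.p_value > 0.99

    def test_matches_hand_welch_computation(self):
        res_a = [self._result(l) for l in (40.0, 50.0, 60.0)]
        res_b = [self._result(l) for l in (180.0, 200.0, 220.0)]
        a, b = displacement_summary(res_a, res_b, "H3K27me3", "H3K4me3")
        t, _, p = welch_by_hand([40, 50, 60], [180, 200, 220])
        assert a.median_abs_lag == 50.0
        assert b.median_abs_lag == 200.0
        assert a.t_statistic == pytest.approx(t)
        assert a.p_value == pytest.approx(p)

    def test_nonsignificant_rois_are_discarded(self):
        res_a = [self._result(50.0), self._result(60.0), self._result(500.0, False)]
        res_b = [self._result(200.0), self._result(210.0)]
        a, _ = displacement_summary(res_a, res_b)
        assert a.n_discarded == 1
        assert len(a.abs_lags) == 2

    def test_too_few_significant_rois_rejected(self):
        res_a = [self._result(50.0), self._result(60.0, False)]
        res_b = [self._result(200.0), self._result(210.0)]
        with pytest.raises(InsufficientDataError):
            displacement_summary(res_a, res_b)

    def test_simulated_displacements_recovered_within_one_step(self):
        def run(shift, seed):
            cfg = ProfileSimConfig(n_profiles=8, channel_shift=shift, noise_sd=0.1, seed=seed)
            profiles, _ = simulate_paired_profiles(cfg)
            return [cross_correlate(p, 1000.0) for p in profiles]

        a, b = displacement_summary(run(50, 1), run(200, 2), "H3K27me3", "H3K4me3")
        assert abs(a.median_abs_lag - 50.0) <= 20.0
        assert abs(b.median_abs_lag - 200.0) <= 20.0
        assert a.p_value < 0.05
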