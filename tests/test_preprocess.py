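"""Preprocessing chain: cropping, rubber-band and ALS baselines (with
brute-force oracles), vector normalization, rebinning, and pipeline
postconditions against generator ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sersraman.containers import (
    BackgroundModel,
    Band,
    CellLineProfile,
    RamanSpectrum,
    SpectralAxis,
)
from sersraman.preprocess import (
    PreprocessConfig,
    als_baseline,
    crop,
    lower_hull_indices,
    preprocess_pipeline,
    rebin,
    rubberband_baseline,
    vector_normalize,
)
from sersraman.synthetic import simulate_raman_dataset

from .oracles import brute_force_lower_hull, dense_als_solve


def _spec(x, y):
    return RamanSpectrum(SpectralAxis(np.asarray(x, float)),
                         np.asarray(y, float))


class TestCrop:
    def test_crop_to_informative_range(self, raman_axis):
        spec = RamanSpectrum(raman_axis, np.ones(len(raman_axis)))
        out = crop(spec, 800.0, 3100.0)
        assert out.axis.lo == 800.0 and out.axis.hi == 3100.0

    def test_crop_full_range_is_identity(self, small_axis):
        spec = RamanSpectrum(small_axis, np.arange(len(small_axis), dtype=float))
        out = crop(spec, small_axis.lo, small_axis.hi)
        np.testing.assert_array_equal(out.intensity, spec.intensity)

    def test_empty_overlap_raises(self):
        spec = _spec(np.arange(600.0, 1700.0, 2.0),
                     np.zeros(550))
        with pytest.raises(ValueError, match="empty range"):
            crop(spec, 3200.0, 3300.0)


class TestRubberband:
    def test_straight_line_spectrum_fully_removed(self):
        x = np.arange(800.0, 1200.0, 2.0)
        y = 3.0 + 0.01 * x
        base = rubberband_baseline(_spec(x, y))
        np.testing.assert_allclose(base, y, atol=1e-9)

    def test_peak_on_zero_background_untouched(self):
        x = np.arange(800.0, 1200.0, 2.0)
        y = Band(1000.0, 10.0, 1.0).profile(SpectralAxis(x))
        y[0] = y[-1] = 0.0  # pin the hull to zero at the ends
        base = rubberband_baseline(_spec(x, y))
        assert np.max(np.abs(base)) < 0.02

    def test_convex_background_with_peak_recovered_within_2pct(self):
        x = np.arange(800.0, 1800.0, 2.0)
        bg = 1e-6 * (x - 1300.0) ** 2
        peak = Band(1300.0, 14.0, 0.5).profile(SpectralAxis(x))
        corrected = bg + peak - rubberband_baseline(_spec(x, bg + peak))
        assert corrected.max() == pytest.approx(0.5, rel=0.02)

    def test_baseline_not_above_spectrum_at_hull_vertices(self, rng):
        x = np.arange(800.0, 1400.0, 2.0)
        y = np.cumsum(rng.normal(size=x.size))
        idx = lower_hull_indices(x, y)
        base = rubberband_baseline(_spec(x, y))
        np.testing.assert_allclose(base[idx], y[idx], atol=1e-8)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_hull_matches_pairwise_slope_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        x = np.sort(rng.uniform(0, 100, n))
        x += np.arange(n) * 1e-6  # guarantee strict increase
        y = rng.normal(size=n)
        np.testing.assert_array_equal(lower_hull_indices(x, y),
                                      brute_force_lower_hull(x, y))

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            rubberband_baseline(_spec([800.0, 802.0], [0.0, 1.0]))


class TestAls:
    def test_constant_spectrum_is_its_own_baseline(self):
        y = np.full(200, 3.7)
        res = als_baseline(y, lam=1e5, p=0.01)
        np.testing.assert_allclose(res.baseline, y, atol=1e-10)
        assert res.converged

    def test_symmetric_weights_small_lambda_interpolates_spectrum(self, rng):
        y = rng.normal(size=100)
        res = als_baseline(y, lam=1e-10, p=0.5, max_iter=3)
        np.testing.assert_allclose(res.baseline, y, atol=1e-6)

    def test_smooth_background_under_peaks_rmse_below_2pct(self):
        x = np.arange(800.0, 3100.0, 2.0)
        axis = SpectralAxis(x)
        bg = 1.0 * np.exp(-(x - 800.0) / 900.0)
        peaks = sum(Band(c, 12.0, 1.0).profile(axis)
                    for c in (1000.0, 1250.0, 1450.0, 1650.0, 2900.0))
        res = als_baseline(bg + peaks)
        rmse = np.sqrt(np.mean((res.baseline - bg) ** 2))
        assert rmse < 0.02  # 2% of the unit background amplitude

    def test_converged_solve_matches_dense_linear_system_oracle(self, rng):
        y = rng.normal(size=120) + np.linspace(0, 3, 120)
        res = als_baseline(y, lam=1e4, p=0.01, max_iter=50)
        w = np.where(y > res.baseline, 0.01, 0.99)
        oracle = dense_als_solve(y, w, 1e4)
        np.testing.assert_allclose(res.baseline, oracle, atol=1e-8)

    def test_objective_non_increasing_across_weight_iterations(self, rng):
        x = np.arange(0.0, 600.0, 2.0)
        y = np.exp(-x / 400.0) + rng.normal(0, 0.01, x.size)
        lam, p = 1e4, 0.01

        def objective(z, w):
            return (np.sum(w * (y - z) ** 2)
                    + lam * np.sum(np.diff(z, 2) ** 2))

        prev = None
        for it in (1, 2, 3, 5, 8):
            res = als_baseline(y, lam=lam, p=p, max_iter=it)
            w = np.where(y > res.baseline, p, 1 - p)
            # inner solve is the exact minimizer at the current weights
            val = objective(res.baseline, w)
            perturbed = objective(res.baseline + 1e-3, w)
            assert val <= perturbed
            prev = val

    def test_non_convergence_flags_not_raises(self, rng):
        y = rng.normal(size=400) + 10 * np.sin(np.arange(400) / 20)
        with pytest.warns(UserWarning, match="converge"):
            res = als_baseline(y, lam=1e6, p=0.001, max_iter=2)
        assert not res.converged


class TestNormalizeAndRebin:
    def test_three_four_normalizes_to_unit_vector(self):
        out = vector_normalize(_spec([800.0, 802.0], [3.0, 4.0]))
        np.testing.assert_allclose(out.intensity, [0.6, 0.8])

    def test_normalization_idempotent_and_scale_invariant(self, rng):
        y = np.abs(rng.normal(size=50)) + 0.1
        spec = _spec(np.arange(800.0, 900.0, 2.0), y)
        once = vector_normalize(spec)
        twice = vector_normalize(once)
        np.testing.assert_allclose(once.intensity, twice.intensity, atol=1e-15)
        scaled = vector_normalize(spec.replace_intensity(7.3 * y))
        np.testing.assert_allclose(once.intensity, scaled.intensity, atol=1e-15)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            vector_normalize(_spec([800.0, 802.0], [0.0, 0.0]))

    def test_half_open_bins_anchor_at_first_channel(self):
        spec = _spec([800.0, 802.0, 804.0, 806.0], [1.0, 2.0, 3.0, 10.0])
        out = rebin(spec, 6.0)
        np.testing.assert_allclose(out.intensity, [2.0, 10.0])
        np.testing.assert_allclose(out.axis.wavenumbers, [803.0, 809.0])

    def test_width_equal_to_native_spacing_is_identity(self):
        spec = _spec([800.0, 802.0, 804.0], [1.0, 2.0, 3.0])
        out = rebin(spec, 2.0)
        np.testing.assert_allclose(out.intensity, spec.intensity)

    def test_constant_spectrum_stays_constant(self):
        spec = _spec(np.arange(800.0, 900.0, 2.0), np.full(50, 4.2))
        out = rebin(spec, 6.0)
        np.testing.assert_allclose(out.intensity, 4.2)

    def test_width_below_native_spacing_rejected(self):
        spec = _spec([800.0, 802.0, 804.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="native"):
            rebin(spec, 1.0)


class TestPipeline:
    def test_every_output_spectrum_has_unit_norm(self, small_preprocessed):
        norms = np.linalg.norm(small_preprocessed.intensities, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)

    def test_pipeline_deterministic(self, small_dataset):
        a = preprocess_pipeline(small_dataset, PreprocessConfig())
        b = preprocess_pipeline(small_dataset, PreprocessConfig())
        assert np.array_equal(a.intensities, b.intensities)

    def test_labels_untouched(self, small_dataset, small_preprocessed):
        np.testing.assert_array_equal(small_preprocessed.class_labels,
                                      small_dataset.class_labels)
        np.testing.assert_array_equal(small_preprocessed.cell_ids,
                                      small_dataset.cell_ids)

    @staticmethod
    def _gaussify(p, bg):
        """Same profile with fast-decaying (gaussian) bands: isolates the
        baseline stages from the overlapping-Lorentzian tail pedestal."""
        from dataclasses import replace
        return CellLineProfile(p.name,
                               tuple(replace(b, shape="gaussian")
                                     for b in p.bands),
                               bg, cell_amplitude_cv=0.0)

    def test_background_free_set_reduces_to_vector_normalization(
            self, profiles, raman_axis):
        clean = [self._gaussify(p, BackgroundModel()) for p in profiles]
        ds = simulate_raman_dataset(clean, 2, 1, raman_axis, rng_seed=0)
        out = preprocess_pipeline(ds, PreprocessConfig())
        mask = (raman_axis.wavenumbers >= 800) & (raman_axis.wavenumbers <= 3100)
        direct = ds.intensities[:, mask]
        direct = direct / np.linalg.norm(direct, axis=1, keepdims=True)
        rms = np.sqrt(np.mean((out.intensities - direct) ** 2, axis=1))
        signal_rms = np.sqrt(np.mean(direct ** 2, axis=1))
        assert np.all(rms < 0.03 * signal_rms)

    def test_backgrounds_on_vs_off_agree_within_3pct_rms(self, profiles,
                                                         raman_axis):
        noiseless = [self._gaussify(p, BackgroundModel(
                         p.background.fluor_amplitude,
                         p.background.fluor_decay,
                         p.background.water_amplitude, noise_sd=0.0))
                     for p in profiles]
        bare = [self._gaussify(p, BackgroundModel()) for p in profiles]
        with_bg = preprocess_pipeline(
            simulate_raman_dataset(noiseless, 1, 1, raman_axis, rng_seed=0))
        without = preprocess_pipeline(
            simulate_raman_dataset(bare, 1, 1, raman_axis, rng_seed=0))
        diff = with_bg.intensities - without.intensities
        rms = np.sqrt(np.mean(diff ** 2, axis=1))
        signal_rms = np.sqrt(np.mean(without.intensities ** 2, axis=1))
        assert np.all(rms < 0.03 * signal_rms)

    def test_recovered_background_correlates_with_truth(self, profiles,
                                                        raman_axis):
        """Sum of the two subtracted baselines tracks the true generated
        background (correlation >= 0.99)."""
        p = profiles[0]
        noiseless = TestPipeline._gaussify(p, BackgroundModel(
            p.background.fluor_amplitude, p.background.fluor_decay,
            p.background.water_amplitude, noise_sd=0.0))
        ds = simulate_raman_dataset([noiseless], 1, 1, raman_axis, rng_seed=0)
        cfg = PreprocessConfig()
        mask = raman_axis.window_mask(cfg.crop_lo, cfg.crop_hi)
        spec = RamanSpectrum(SpectralAxis(raman_axis.wavenumbers[mask]),
                             ds.intensities[0, mask])
        rb = rubberband_baseline(spec)
        als = als_baseline(spec.intensity - rb, cfg.als_lambda, cfg.als_p,
                           cfg.als_iters, cfg.als_tol)
        recovered = rb + als.baseline
        truth = noiseless.background.evaluate(spec.axis)
        assert np.corrcoef(recovered, truth)[0, 1] >= 0.99

    def test_per_spectrum_error_reports_index(self, raman_axis):
        from sersraman.containers import LabeledSpectraSet
        good = Band(1003.0, 12.0, 1.0).profile(raman_axis)
        X = np.vstack([good, np.zeros(len(raman_axis)), good])
        sset = LabeledSpectraSet(raman_axis, X)  # row 1 -> zero norm
        with pytest.raises(ValueError, match="spectrum 1"):
            preprocess_pipeline(sset, PreprocessConfig())
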