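"""Cohort generator: determinism, grade structure, spectral informativeness."""

import numpy as np
import pytest

import ovospec as o
from ovospec.preprocess import Preprocessor, SpectraMatrix
from _oracles import fisher_ratio


class TestModes:
    def test_nine_distinct_modes(self):
        modes = o.all_modes()
        assert len(modes) == 9
        assert len({m.label for m in modes}) == 9

    def test_angle_only_for_scatter(self):
        with pytest.raises(ValueError):
            o.AcquisitionMode("reflection", 10)
        with pytest.raises(ValueError):
            o.AcquisitionMode("scatter", 15)

    def test_label_round_trip(self):
        for m in o.all_modes():
            assert o.AcquisitionMode.from_label(m.label) == m


class TestCohort:
    def test_shape_and_grade_balance(self, full_cohort):
        records, _ = full_cohort
        assert len(records) == 280
        counts = {g: sum(r.grade == g for r in records) for g in o.GRADES}
        assert all(c == 70 for c in counts.values())
        assert all(len(r.spectra) == 9 for r in records)

    def test_zero_noise_hu_is_exact_line(self):
        cfg = o.GeneratorConfig(seed=3, haugh_noise_sd=0.0)
        records = o.simulate_cohort(28, 2, [], cfg)
        for r in records:
            assert r.haugh == pytest.approx(85.70 - 1.75 * r.day, abs=1e-12)

    def test_haugh_consistent_with_height_and_weight(self, small_cohort):
        records, _, _ = small_cohort
        for r in records[:20]:
            assert o.haugh_unit(r.protein_height_mm, r.weight_g) == \
                pytest.approx(r.haugh, abs=1e-9)

    def test_weights_within_range(self, full_cohort):
        records, cfg = full_cohort
        lo, hi = cfg.weight_range_g
        assert all(lo <= r.weight_g <= hi for r in records)

    def test_same_seed_identical_cohorts(self):
        cfg = o.GeneratorConfig(seed=9)
        modes = [o.AcquisitionMode("scatter", 0)]
        a = o.simulate_cohort(3, 2, modes, cfg)
        b = o.simulate_cohort(3, 2, modes, cfg)
        for ra, rb in zip(a, b):
            assert ra.haugh == rb.haugh
            np.testing.assert_array_equal(
                ra.spectra["scatter_0"].values, rb.spectra["scatter_0"].values)

    def test_more_than_28_days_rejected(self):
        with pytest.raises(ValueError):
            o.simulate_cohort(29, 1, [], o.GeneratorConfig(seed=0))

    def test_degradation_recovery_across_seeds(self):
        """OLS on 140-egg cohorts recovers the programmed slope/intercept."""
        ok = 0
        for seed in range(25):
            cfg = o.GeneratorConfig(seed=seed)
            recs = o.simulate_cohort(28, 5, [], cfg)
            fit = o.fit_degradation([r.day for r in recs],
                                    [r.haugh for r in recs])
            ok += (abs(fit.slope + 1.75) <= 0.15
                   and abs(fit.intercept - 85.70) <= 1.5)
        assert ok >= 24


class TestEggSpectrum:
    def test_scatter_more_informative_than_reflection(self, default_config):
        rng = np.random.default_rng(0)
        cfg = default_config
        sc, refl = o.AcquisitionMode("scatter", 0), o.AcquisitionMode("reflection")
        d_sc = np.abs(o.undistorted_spectrum(80, sc, cfg).values
                      - o.undistorted_spectrum(40, sc, cfg).values).mean()
        d_re = np.abs(o.undistorted_spectrum(80, refl, cfg).values
                      - o.undistorted_spectrum(40, refl, cfg).values).mean()
        assert d_sc > d_re

    def test_zero_distortion_is_deterministic(self):
        cfg = o.GeneratorConfig(seed=1, multiplicative_sd=0, additive_sd=0,
                                channel_noise_sd=0, shell_color_sd=0)
        mode = o.AcquisitionMode("scatter", 20)
        a = o.egg_spectrum(70.0, mode, cfg, np.random.default_rng(1))
        b = o.egg_spectrum(70.0, mode, cfg, np.random.default_rng(99))
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_allclose(
            a.values, o.undistorted_spectrum(70.0, mode, cfg).values)

    def test_msc_recovers_undistorted_in_expectation(self, default_config):
        """Mean of 200 distorted draws, MSC-corrected against the clean
        reference, deviates from the clean spectrum by < 3 channel sds."""
        cfg = default_config
        mode = o.AcquisitionMode("scatter", 0)
        rng = np.random.default_rng(7)
        clean = o.undistorted_spectrum(80.0, mode, cfg)
        draws = np.vstack([o.egg_spectrum(80.0, mode, cfg, rng).values
                           for _ in range(200)])
        pre = Preprocessor(method="msc")
        pre.reference_ = clean.values
        corrected = pre.transform(SpectraMatrix(draws, clean.wavelengths_nm)).X
        dev = np.abs(corrected.mean(axis=0) - clean.values).max()
        assert dev < 3 * cfg.channel_noise_sd

    def test_nonfinite_haugh_rejected(self, default_config, rng):
        with pytest.raises(ValueError):
            o.egg_spectrum(np.nan, o.AcquisitionMode("reflection"),
                           default_config, rng)


def test_informativeness_strictly_decreasing_with_angle():
    """Fisher between/within ratio of scatter-corrected spectra falls
    monotonically with incident angle and is lowest for reflection
    (averaged over 20 seeded cohorts)."""
    modes = o.all_modes()
    sums = {m.label: 0.0 for m in modes}
    n_seeds = 20
    for seed in range(n_seeds):
        cfg = o.GeneratorConfig(seed=seed)
        recs = o.simulate_cohort(28, 10, modes, cfg)
        for m in modes:
            mat, y = o.cohort_matrix(recs, m)
            corr = Preprocessor(method="msc").fit_transform(mat)
            sums[m.label] += fisher_ratio(corr.X, y)
    means = {k: v / n_seeds for k, v in sums.items()}
    angle_means = [means[f"scatter_{a}"] for a in (0, 10, 20, 30, 40, 50, 60)]
    assert all(a > b for a, b in zip(angle_means, angle_means[1:]))
    assert means["reflection"] < min(
        v for k, v in means.items() if k != "reflection")


class TestRenderScene:
    def _scene(self, seed, n_bands=16, noise=None):
        cfg = o.GeneratorConfig(seed=seed, n_bands=n_bands,
                                **({"channel_noise_sd": noise}
                                   if noise is not None else {}))
        spec = o.undistorted_spectrum(75.0, o.AcquisitionMode("scatter", 0), cfg)
        return cfg, spec

    def test_correction_recovers_shaded_spectrum(self):
        cfg, spec = self._scene(3)
        raw, white, dark = o.render_scene(
            [spec], [((32, 32), (20, 14))], (64, 64), cfg,
            np.random.default_rng(3))
        R = o.black_white_correct(o.CorrectionFrames(raw, white, dark))
        # noise-free ground truth from the same seed
        cfg0, _ = self._scene(3, noise=0.0)
        raw0, white0, dark0 = o.render_scene(
            [spec], [((32, 32), (20, 14))], (64, 64), cfg0,
            np.random.default_rng(3))
        R0 = (raw0.data - dark0.data) / (white0.data - dark0.data)
        assert np.abs(R.data[32, 32] - R0[32, 32]).max() \
            < 3 * cfg.channel_noise_sd
        # at the ellipse centre shading is 1, so the clean correction is the
        # input spectrum itself
        np.testing.assert_allclose(R0[32, 32], spec.values, atol=1e-12)

    def test_zero_ellipses_pure_background(self):
        cfg, _ = self._scene(4, noise=0.0)
        raw, white, dark = o.render_scene([], [], (16, 16), cfg,
                                          np.random.default_rng(4))
        R = (raw.data - dark.data) / (white.data - dark.data)
        np.testing.assert_allclose(R, 0.15, atol=1e-12)

    def test_two_disjoint_ellipses_give_two_components(self):
        cfg, spec = self._scene(5)
        raw, white, dark = o.render_scene(
            [spec, spec], [((16, 16), (10, 8)), ((48, 44), (11, 9))],
            (64, 64), cfg, np.random.default_rng(5))
        R = o.black_white_correct(o.CorrectionFrames(raw, white, dark))
        mask = o.egg_mask(o.pseudo_rgb(R))
        assert mask.n_rois == 2

    def test_overlapping_ellipses_rejected(self):
        cfg, spec = self._scene(6)
        with pytest.raises(ValueError, match="overlap"):
            o.render_scene([spec, spec],
                           [((32, 32), (20, 14)), ((34, 34), (20, 14))],
                           (64, 64), cfg, np.random.default_rng(6))

    def test_out_of_bounds_ellipse_rejected(self):
        cfg, spec = self._scene(7)
        with pytest.raises(ValueError, match="bounds"):
            o.render_scene([spec], [((5, 32), (20, 14))], (64, 64), cfg,
                           np.random.default_rng(7))
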