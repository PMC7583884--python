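"""Stratified split, the six weak classifiers, and the model grid."""

import numpy as np
import pytest

import ovospec as o
from ovospec.classify import ClassifierSpec
from ovospec.preprocess import SpectraMatrix


def _grade_vector(n_per_grade=70):
    return np.repeat(list(o.GRADES), n_per_grade)


def _separable(rng, n_per_class=30, spread=0.05):
    centers = {"AA": (0, 0), "A": (3, 0), "B1": (0, 3), "B2": (3, 3)}
    X, y = [], []
    for g, c in centers.items():
        X.append(rng.normal(loc=c, scale=spread, size=(n_per_class, 2)))
        y += [g] * n_per_class
    return np.vstack(X), np.array(y)


class TestStratifiedSplit:
    def test_study_split_sizes(self):
        y = _grade_vector(70)
        tr, te = o.stratified_split(y, 0.7143, seed=0)
        assert tr.size == 200 and te.size == 80
        for g in o.GRADES:
            assert np.sum(y[tr] == g) == 50
            assert np.sum(y[te] == g) == 20
        assert np.intersect1d(tr, te).size == 0
        assert np.union1d(tr, te).size == 280

    def test_degenerate_fractions_rejected(self):
        y = _grade_vector(10)
        for frac in (0.0, 1.0, 1.2):
            with pytest.raises(ValueError):
                o.stratified_split(y, frac, seed=0)

    def test_seed_controls_split(self):
        y = _grade_vector(10)
        a = o.stratified_split(y, 0.7143, seed=1)
        b = o.stratified_split(y, 0.7143, seed=1)
        c = o.stratified_split(y, 0.7143, seed=2)
        np.testing.assert_array_equal(a[0], b[0])
        assert not np.array_equal(a[0], c[0])
        assert c[0].size == a[0].size

    def test_tiny_class_rejected(self):
        y = np.array(["AA", "AA", "A"])
        with pytest.raises(ValueError):
            o.stratified_split(y, 0.7, seed=0)


class TestClassifiers:
    @pytest.mark.parametrize("kind", o.CLASSIFIER_KINDS)
    def test_separable_problem_learned(self, kind, rng):
        X, y = _separable(rng)
        tr, te = o.stratified_split(y, 0.7, seed=0)
        res = o.train_and_eval(ClassifierSpec.make(kind, seed=0),
                               X[tr], y[tr], X[te], y[te])
        assert res.test_accuracy == 1.0
        assert res.confusion.trace() == te.size

    def test_shuffled_labels_give_chance_accuracy(self, rng):
        X, y = _separable(rng, n_per_class=50)
        y = rng.permutation(y)
        tr, te = o.stratified_split(y, 0.7, seed=0)
        res = o.train_and_eval(ClassifierSpec.make("KNN"),
                               X[tr], y[tr], X[te], y[te])
        # binomial 99% band around 0.25 for n_test = 60
        n = te.size
        band = 2.58 * np.sqrt(0.25 * 0.75 / n)
        assert abs(res.test_accuracy - 0.25) < band + 0.05

    def test_accuracy_quantised_by_test_count(self, rng):
        X, y = _separable(rng, n_per_class=70, spread=1.5)
        tr, te = o.stratified_split(y, 0.7143, seed=0)
        res = o.train_and_eval(ClassifierSpec.make("DAC"),
                               X[tr], y[tr], X[te], y[te])
        assert te.size == 80
        assert (res.test_accuracy * 80) == pytest.approx(
            round(res.test_accuracy * 80), abs=1e-9)

    def test_probabilities_available_for_all_kinds(self, rng):
        X, y = _separable(rng)
        for kind in o.CLASSIFIER_KINDS:
            model = o.make_classifier(ClassifierSpec.make(kind, seed=0))
            model.fit(X, y)
            p = model.predict_proba(X[:5])
            assert p.shape == (5, 4)
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec.make("KNN", C=10)
        with pytest.raises(ValueError):
            ClassifierSpec.make("DAC", discriminant="cubic")
        with pytest.raises(ValueError):
            ClassifierSpec.make("GBM")


class TestRunGrid:
    def _spectra(self, rng, n_bands=24):
        """Two synthetic 'modes' with different signal strengths."""
        y = _grade_vector(12)
        signal = {"AA": 1.0, "A": 2.0, "B1": 3.0, "B2": 4.0}
        wl = np.linspace(400, 1000, n_bands)
        out = {}
        for label, snr in (("strong", 4.0), ("weak", 0.5)):
            X = rng.normal(scale=1.0, size=(y.size, n_bands))
            bump = np.exp(-(((wl - 600) / 40) ** 2))
            for i, g in enumerate(y):
                X[i] += snr * signal[g] * bump
            out[label] = SpectraMatrix(X, wl)
        return out, y

    def test_single_cell_grid(self, rng):
        spectra, y = self._spectra(rng)
        results, best = o.run_grid({"strong": spectra["strong"]}, y,
                                   ["snv"], ["pca"],
                                   [ClassifierSpec.make("DAC")], seed=0)
        assert len(results) == 1
        assert best["strong"].pipeline_id == "snv-pca-DAC"

    def test_duplicated_classifier_gives_identical_cells(self, rng):
        spectra, y = self._spectra(rng)
        results, _ = o.run_grid({"strong": spectra["strong"]}, y,
                                ["snv"], ["pca"],
                                [ClassifierSpec.make("RF", seed=3),
                                 ClassifierSpec.make("RF", seed=3)], seed=0)
        assert results[0].test_accuracy == results[1].test_accuracy
        np.testing.assert_array_equal(results[0].confusion,
                                      results[1].confusion)

    def test_full_sweep_shape_and_best_selection(self, rng):
        spectra, y = self._spectra(rng)
        specs = [ClassifierSpec.make(k) for k in ("DAC", "KNN")]
        results, best = o.run_grid(spectra, y, ["snv", "mc"], ["pca"],
                                   specs, seed=0)
        assert len(results) == 2 * 2 * 1 * 2
        for label in spectra:
            cells = [r for r in results if r.mode == label and r.ok]
            top = max(c.test_accuracy for c in cells)
            assert best[label].test_accuracy == top

    def test_no_test_leakage_into_fitted_state(self, rng):
        """Perturbing test-row features changes no fitted artifact."""
        spectra, y = self._spectra(rng)
        tr, te = o.stratified_split(y, 0.7143, seed=0)
        mat = spectra["strong"]
        X2 = mat.X.copy()
        X2[te[0]] += 1000.0
        kw = dict(preprocessors=["auto"], selectors=["pca"],
                  classifiers=[ClassifierSpec.make("DAC")], seed=0,
                  split=(tr, te))
        r1, _ = o.run_grid({"m": mat}, y, **kw)
        r2, _ = o.run_grid({"m": SpectraMatrix(X2, mat.wavelengths_nm)},
                           y, **kw)
        assert r1[0].train_accuracy == r2[0].train_accuracy
        np.testing.assert_array_equal(
            r1[0].model.coef_ if hasattr(r1[0].model, "coef_")
            else r1[0].model.means_,
            r2[0].model.coef_ if hasattr(r2[0].model, "coef_")
            else r2[0].model.means_)

    def test_failed_cell_recorded_not_fatal(self, rng):
        spectra, y = self._spectra(rng)
        X = spectra["strong"].X.copy()
        X[:, 5] = 0.42          # constant band: autoscale must fail
        bad = SpectraMatrix(X, spectra["strong"].wavelengths_nm)
        results, best = o.run_grid(
            {"bad": bad}, y, ["auto", "snv"], ["pca"],
            [ClassifierSpec.make("DAC")], seed=0)
        errors = [r for r in results if not r.ok]
        assert len(errors) == 1 and errors[0].preprocessor == "auto"
        assert best["bad"].preprocessor == "snv"

    def test_empty_axis_rejected(self, rng):
        spectra, y = self._spectra(rng)
        with pytest.raises(ValueError):
            o.run_grid(spectra, y, [], ["pca"],
                       [ClassifierSpec.make("DAC")], seed=0)
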