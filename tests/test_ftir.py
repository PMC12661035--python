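import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.decomposition import PCA as SKPCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from culteval.ftir import (
    Spectrum, SpectrumSet, baseline_correct, cross_validate, fit_lda, pca,
    preprocess, read_spectrum, read_spectrum_set, slice_region,
    vector_normalize, wilson_interval, write_spectrum_set,
)
from culteval.synthdata import default_spectrum_truth, simulate_spectra


def _random_spectrum(n=50, seed=0):
    rng = np.random.default_rng(seed)
    w = np.linspace(900, 1800, n)
    return Spectrum(w=w, a=rng.random(n))


class TestBaseline:
    def test_pure_line_maps_to_zero(self):
        w = np.linspace(900, 1800, 40)
        s = baseline_correct(Spectrum(w=w, a=2.0 * w + 5.0))
        np.testing.assert_allclose(s.a, 0.0, atol=1e-9)

    def test_endpoints_always_zero(self):
        s = baseline_correct(_random_spectrum(seed=1))
        assert s.a[0] == pytest.approx(0.0, abs=1e-12)
        assert s.a[-1] == pytest.approx(0.0, abs=1e-12)

    def test_idempotent_on_corrected_values(self):
        s = baseline_correct(_random_spectrum(seed=2))
        # re-running the endpoint fit on a corrected spectrum is a no-op
        again = baseline_correct(Spectrum(w=s.w, a=s.a))
        np.testing.assert_allclose(again.a, s.a, atol=1e-12)

    def test_stage_transitions_enforced(self):
        s = baseline_correct(_random_spectrum())
        with pytest.raises(ValueError):
            baseline_correct(s)
        with pytest.raises(ValueError):
            vector_normalize(_random_spectrum())


class TestVectorNormalize:
    def test_unit_sum_of_squares(self):
        s = vector_normalize(baseline_correct(_random_spectrum(seed=3)))
        assert abs((s.a**2).sum() - 1.0) < 1e-12
        assert abs(s.a.mean()) < 1e-12

    def test_scale_invariance(self):
        raw = _random_spectrum(seed=4)
        a = preprocess(raw)
        b = preprocess(Spectrum(w=raw.w, a=raw.a * 5.0))
        np.testing.assert_allclose(a.a, b.a, atol=1e-12)

    def test_two_point_hand_example(self):
        s = Spectrum(w=np.array([1000.0, 1100.0, 1200.0]),
                     a=np.array([0.0, 0.0, 0.0]),
                     stage="baseline_corrected")
        s.a = np.array([1.0, 0.0, -1.0])
        out = vector_normalize(s)
        np.testing.assert_allclose(out.a, [1 / math.sqrt(2), 0.0, -1 / math.sqrt(2)])

    def test_constant_spectrum_rejected_by_name(self):
        s = Spectrum(w=np.linspace(900, 1800, 10), a=np.full(10, 2.0),
                     stage="baseline_corrected", name="flatliner")
        with pytest.raises(ValueError, match="flatliner"):
            vector_normalize(s)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000), st.floats(0.1, 10), st.floats(-1e-3, 1e-3),
           st.floats(-1, 1))
    def test_pipeline_invariant_to_ramp_and_scale(self, seed, scale, slope, offset):
        raw = _random_spectrum(seed=seed)
        base = preprocess(raw)
        modified = Spectrum(w=raw.w, a=raw.a * scale + slope * raw.w + offset)
        np.testing.assert_allclose(preprocess(modified).a, base.a, atol=1e-10)


class TestSliceRegion:
    def test_fingerprint_slice_point_count(self):
        w = np.arange(524.0, 4000.0 + 1, 2.0)  # grid aligned with 900/1800
        s = Spectrum(w=w, a=np.zeros_like(w))
        out = slice_region(s, "fingerprint")
        assert out.n == 451  # (1800-900)/2 + 1 inclusive
        assert out.region == "fingerprint"

    def test_full_range_is_identity(self):
        s = _random_spectrum()
        out = slice_region(s, (s.w[0], s.w[-1]))
        np.testing.assert_array_equal(out.a, s.a)

    def test_disjoint_bounds_rejected(self):
        with pytest.raises(ValueError):
            slice_region(_random_spectrum(), (5000.0, 6000.0))


class TestPCA:
    def test_single_direction_data(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=20)
        direction = np.array([3.0, 4.0, 0.0]) / 5.0
        X = np.outer(t, direction)
        res = pca(X)
        assert math.isclose(res.explained_fraction[0], 1.0, abs_tol=1e-12)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(1)
        X = rng.random((10, 6))
        res = pca(X)
        recon = res.scores @ res.loadings.T
        np.testing.assert_allclose(recon, X - res.mean, atol=1e-8)

    def test_matches_sklearn_oracle_up_to_sign(self):
        rng = np.random.default_rng(2)
        X = rng.random((15, 8))
        res = pca(X, n_components=5)
        sk = SKPCA(n_components=5).fit(X)
        np.testing.assert_allclose(res.explained_variance, sk.explained_variance_, atol=1e-10)
        for k in range(5):
            dot = abs(np.dot(res.loadings[:, k], sk.components_[k]))
            assert math.isclose(dot, 1.0, abs_tol=1e-8)

    def test_scores_uncorrelated_and_fractions_non_increasing(self):
        rng = np.random.default_rng(3)
        X = rng.random((20, 10))
        res = pca(X)
        cov = np.cov(res.scores.T)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() <= 1e-8
        assert (np.diff(res.explained_fraction) <= 1e-12).all()

    def test_too_few_spectra_rejected(self):
        with pytest.raises(ValueError):
            pca(np.ones((1, 5)))


class TestLDA:
    def test_two_separated_1d_classes(self):
        rng = np.random.default_rng(42)
        sigma, n = 0.1, 20
        X = np.concatenate([rng.normal(0, sigma, n), rng.normal(10, sigma, n)])
        X = np.column_stack([X, rng.normal(0, 1, 2 * n)])  # noise dimension
        labels = ["lo"] * n + ["hi"] * n
        model = fit_lda(X, labels, regularization="none")
        preds = model.predict(X)
        assert preds == labels
        # LD1 essentially aligned with the informative dimension
        axis = model.axes[:, 0] / np.linalg.norm(model.axes[:, 0])
        assert abs(axis[0]) > 0.99

    def test_coincident_class_means_give_zero_eigenvalues(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 3))
        Xb = np.vstack([X, X])
        labels = ["a"] * 40 + ["b"] * 40
        model = fit_lda(Xb, labels, regularization="ridge")
        assert (model.eigenvalues <= 1e-10).all()

    def test_two_class_direction_matches_closed_form(self):
        rng = np.random.default_rng(6)
        Xa = rng.normal(0, 1, size=(25, 4)) @ np.diag([1, 2, 0.5, 1])
        Xb = Xa[:20] + np.array([1.0, -2.0, 0.5, 3.0])
        X = np.vstack([Xa, Xb])
        labels = ["a"] * 25 + ["b"] * 20
        model = fit_lda(X, labels, regularization="none")
        # Fisher: w proportional to Sw^-1 (mu_a - mu_b)
        mu_a, mu_b = Xa.mean(axis=0), Xb.mean(axis=0)
        Sw = np.zeros((4, 4))
        for grp, mu in ((Xa, mu_a), (Xb, mu_b)):
            d = grp - mu
            Sw += d.T @ d
        w = np.linalg.solve(Sw, mu_a - mu_b)
        w /= np.linalg.norm(w)
        axis = model.axes[:, 0] / np.linalg.norm(model.axes[:, 0])
        assert min(np.linalg.norm(axis - w), np.linalg.norm(axis + w)) < 1e-8

    def test_agrees_with_sklearn_predictions(self):
        rng = np.random.default_rng(7)
        centers = rng.normal(scale=4, size=(3, 6))
        X = np.vstack([c + rng.normal(size=(15, 6)) for c in centers])
        labels = [f"c{i}" for i in range(3) for _ in range(15)]
        model = fit_lda(X, labels, regularization="none")
        sk = LinearDiscriminantAnalysis().fit(X, labels)
        agreement = np.mean(np.array(model.predict(X)) == sk.predict(X))
        assert agreement >= 0.95

    def test_eigenvalues_non_negative_and_axis_count(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 5))
        labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        model = fit_lda(X, labels, regularization="ridge")
        assert (model.eigenvalues >= 0).all()
        assert model.axes.shape[1] == 2

    def test_singular_scatter_without_regularization_errors(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(6, 50))  # points >> spectra
        labels = ["a"] * 3 + ["b"] * 3
        with pytest.raises(np.linalg.LinAlgError, match="regularization"):
            fit_lda(X, labels, regularization="none")


class TestCrossValidation:
    def test_disjoint_peak_classes_classify_perfectly(self):
        truth = default_spectrum_truth(5, seed=0, noise_sd=1e-3)
        sset = simulate_spectra(truth, n_per_class=8, seed=1)
        report = cross_validate(sset, k=5, seed=0)
        assert report.accuracy == 1.0
        assert report.ci_upper <= 1.0 and report.ci_lower > 0.9

    def test_confusion_matrix_consistency(self):
        truth = default_spectrum_truth(4, seed=2, noise_sd=0.05)
        sset = simulate_spectra(truth, n_per_class=6, seed=3)
        report = cross_validate(sset, k=5, seed=1)
        cm = report.confusion
        assert cm.to_numpy().sum() == len(sset)
        assert math.isclose(
            np.trace(cm.to_numpy()) / cm.to_numpy().sum(), report.accuracy
        )
        # row sums = per-class counts
        assert (cm.sum(axis=1) == 6).all()

    def test_permuted_labels_hit_chance_level(self):
        truth = default_spectrum_truth(5, seed=4, noise_sd=1e-3)
        accs = []
        for s in range(30):
            sset = simulate_spectra(truth, n_per_class=8, seed=s)
            rng = np.random.default_rng(1000 + s)
            labels = [sp.label for sp in sset.spectra]
            rng.shuffle(labels)
            for sp, l in zip(sset.spectra, labels):
                sp.label = l
            accs.append(cross_validate(sset, k=5, seed=s).accuracy)
        mean_acc = np.mean(accs)
        n_total = 30 * 40
        se = math.sqrt(0.2 * 0.8 / n_total)
        assert abs(mean_acc - 0.2) < 4 * se + 0.02

    def test_accuracy_degrades_with_noise(self):
        means = []
        for noise in (0.001, 0.05, 0.2):
            accs = []
            for s in range(10):
                truth = default_spectrum_truth(5, seed=5, noise_sd=noise)
                sset = simulate_spectra(truth, n_per_class=6, seed=s)
                accs.append(cross_validate(sset, k=5, seed=s).accuracy)
            means.append(np.mean(accs))
        assert means[0] >= means[1] >= means[2] - 0.02

    def test_single_class_rejected(self):
        truth = default_spectrum_truth(1, seed=0)
        sset = simulate_spectra(truth, n_per_class=4, seed=0)
        with pytest.raises(ValueError):
            cross_validate(sset)

    def test_wilson_interval_brackets_the_point_estimate(self):
        lo, hi = wilson_interval(38, 40)
        assert lo < 38 / 40 < hi
        lo1, hi1 = wilson_interval(40, 40)
        assert hi1 == 1.0 and lo1 > 0.9


class TestIO:
    def test_round_trip_spectrum_set(self, tmp_path):
        truth = default_spectrum_truth(2, seed=6)
        sset = simulate_spectra(truth, n_per_class=2, seed=7)
        spath, lpath = tmp_path / "spec.tsv", tmp_path / "labels.tsv"
        write_spectrum_set(sset, spath, lpath)
        back = read_spectrum_set(spath, lpath)
        assert back.labels == sset.labels
        np.testing.assert_allclose(back.grid, sset.grid)
        np.testing.assert_allclose(back.matrix(), sset.matrix(), rtol=1e-9)

    def test_two_column_reader(self, tmp_path):
        path = tmp_path / "one.txt"
        path.write_text("wavenumber\tabsorbance\n900\t0.1\n902\t0.2\n904\t0.15\n")
        s = read_spectrum(path, label="x")
        assert s.n == 3 and s.label == "x"
        np.testing.assert_allclose(s.a, [0.1, 0.2, 0.15])
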