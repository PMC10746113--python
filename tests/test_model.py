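import numpy as np
import pytest

from fftsar.model import (
    ModelError,
    PLSPredictor,
    SarDataset,
    compute_cvrmse,
    compute_r2,
    fit_pls,
    load_model,
    loocv_evaluate,
    loocv_predict,
    resolve_n_components,
    save_model,
    sweep_n_components,
)
from fftsar.mutations import Variant
from fftsar import synthetic
from fftsar.selection import SpectraCache


def toy_dataset(sequences, y):
    variants = tuple(
        Variant(label=f"V{i}", mutations=frozenset(), sequence=s, half_life=float(v))
        for i, (s, v) in enumerate(zip(sequences, y))
    )
    return SarDataset(variants=variants)


class TestMetrics:
    def test_cvrmse_examples(self):
        assert compute_cvrmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0
        # hand arithmetic: sqrt((9+16)/2)
        assert compute_cvrmse([0, 0], [3, 4]) == pytest.approx(np.sqrt(12.5))

    def test_cvrmse_homogeneity(self):
        rng = np.random.default_rng(1)
        y, yh = rng.normal(size=8), rng.normal(size=8)
        base = compute_cvrmse(y, yh)
        for c in (-2.0, 0.5, 10.0):
            assert compute_cvrmse(c * y, c * yh) == pytest.approx(abs(c) * base)

    def test_cvrmse_length_mismatch(self):
        with pytest.raises(ModelError, match="mismatch"):
            compute_cvrmse([1, 2], [1, 2, 3])

    def test_r2_perfect_and_affine(self):
        y = np.array([1.0, 3.0, 2.0, 5.0])
        assert compute_r2(y, y) == pytest.approx(1.0)
        assert compute_r2(y, 2.5 * y + 7) == pytest.approx(1.0)

    def test_r2_matches_textbook_pearson(self):
        rng = np.random.default_rng(2)
        y, yh = rng.normal(size=10), rng.normal(size=10)
        expected = np.corrcoef(y, yh)[0, 1] ** 2
        assert compute_r2(y, yh) == pytest.approx(expected, abs=1e-10)
        assert 0 <= compute_r2(y, yh) <= 1

    def test_r2_zero_variance_error(self):
        with pytest.raises(ModelError, match="zero variance"):
            compute_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ModelError, match="zero variance"):
            compute_r2([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])


class TestFitPls:
    def test_exact_linear_single_feature(self):
        x = np.arange(10.0).reshape(-1, 1)
        y = 3.0 * x.ravel() - 2.0
        model = fit_pls(x, y, n_components=1)
        np.testing.assert_allclose(model.predict(x), y, atol=1e-8)

    def test_full_components_match_least_squares(self):
        # closed-form OLS oracle: PLS with all components is OLS
        rng = np.random.default_rng(3)
        X = rng.normal(size=(9, 3))
        y = rng.normal(size=9)
        model = fit_pls(X, y, n_components=3)
        A = np.hstack([np.ones((9, 1)), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(model.predict(X), A @ beta, atol=1e-6)

    def test_duplicate_columns_match_single_column(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(8, 1))
        y = 2.0 * x.ravel() + rng.normal(scale=0.1, size=8)
        single = fit_pls(x, y, 1).predict(x)
        doubled = fit_pls(np.hstack([x, x]), y, 1).predict(np.hstack([x, x]))
        np.testing.assert_allclose(doubled, single, atol=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ModelError, match="zero-variance"):
            fit_pls(np.ones((4, 2)), np.ones(4), 1)
        with pytest.raises(ModelError, match="2 training samples"):
            fit_pls(np.ones((1, 2)), np.array([1.0]), 1)

    def test_infeasible_components_prescribe_maximum(self):
        X = np.random.default_rng(5).normal(size=(4, 2))
        y = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ModelError, match="maximum here is 2"):
            fit_pls(X, y, 3)

    def test_zero_variance_features_fall_back_to_mean(self):
        X = np.full((4, 3), 7.0)
        y = np.array([1.0, 2.0, 3.0, 4.0])
        model = fit_pls(X, y, 1)
        np.testing.assert_allclose(model.predict(X), np.full(4, 2.5))


class TestLoocv:
    def test_hand_computed_three_point_loocv(self):
        # three size-2 regressions, by hand:
        #   leave 0: line through (1,3),(2,4) -> pred(0)=2
        #   leave 1: line through (0,1),(2,4) -> pred(1)=2.5
        #   leave 2: line through (0,1),(1,3) -> pred(2)=5
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([1.0, 3.0, 4.0])
        preds = loocv_predict(X, y, 1)
        np.testing.assert_allclose(preds, [2.0, 2.5, 5.0], atol=1e-10)
        assert compute_cvrmse(y, preds) == pytest.approx(np.sqrt(0.75))

    def test_noiseless_planted_signal_recovers_exactly(self, small_pool):
        # 7 spectral bins, 13-row training folds: full-component PLS is
        # OLS and the exact linear response is identifiable
        spec = synthetic.SyntheticSpec(
            wt_length=12, n_singles=5, n_variants=14,
            planted_accessions=(small_pool.usable_accessions[0],),
            noise_sd=0.0, seed=9,
        )
        dataset, _ = synthetic.make_sar_dataset(spec, small_pool)
        fit = loocv_evaluate(dataset, spec.planted_accessions, small_pool, 7)
        assert fit.cvrmse == pytest.approx(0.0, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-6)

    def test_feature_block_permutation_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 7))
        y = rng.normal(size=10)
        base = loocv_predict(X, y, 3)
        perm = rng.permutation(7)
        np.testing.assert_allclose(loocv_predict(X[:, perm], y, 3), base, atol=1e-8)

    def test_row_permutation_permutes_predictions(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(9, 4))
        y = rng.normal(size=9)
        base = loocv_predict(X, y, 2)
        perm = rng.permutation(9)
        permuted = loocv_predict(X[perm], y[perm], 2)
        np.testing.assert_allclose(permuted, base[perm], atol=1e-8)
        assert compute_cvrmse(y[perm], permuted) == pytest.approx(
            compute_cvrmse(y, base)
        )

    def test_cvrmse_monotone_in_noise(self, small_pool):
        errs = []
        for noise in (4.0, 1.0, 0.0):
            spec = synthetic.SyntheticSpec(
                wt_length=40, n_singles=5, n_variants=14,
                planted_accessions=(small_pool.usable_accessions[0],),
                noise_sd=noise, seed=13,
            )
            dataset, _ = synthetic.make_sar_dataset(spec, small_pool)
            fit = loocv_evaluate(dataset, spec.planted_accessions, small_pool)
            errs.append(fit.cvrmse)
        assert errs[0] >= errs[1] >= errs[2]

    def test_r2_approaches_one_as_noise_vanishes(self, small_pool):
        r2s = []
        for noise in (2.0, 0.2, 0.0):
            spec = synthetic.SyntheticSpec(
                wt_length=12, n_singles=5, n_variants=14,
                planted_accessions=(small_pool.usable_accessions[1],),
                noise_sd=noise, seed=17,
            )
            dataset, _ = synthetic.make_sar_dataset(spec, small_pool)
            r2s.append(loocv_evaluate(dataset, spec.planted_accessions, small_pool, 7).r2)
        assert r2s[-1] == pytest.approx(1.0, abs=1e-6)
        assert r2s[0] <= r2s[-1]

    def test_ncomp_policy_and_sweep(self):
        assert resolve_n_components("auto", 12, 200) == 5
        assert resolve_n_components("auto", 4, 200) == 3
        assert resolve_n_components(8, 4, 200) == 3  # clipped to feasible
        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 6))
        y = X[:, 0] * 2 + rng.normal(scale=0.05, size=12)
        n = sweep_n_components(X, y, max_components=5)
        assert 1 <= n <= 5


class TestPersistence:
    def test_saved_model_replays_bit_for_bit(self, tmp_path, planted):
        pool, dataset, truth = planted
        accs = tuple(truth["planted_accessions"])
        cache = SpectraCache(dataset, pool)
        fit = loocv_evaluate(dataset, accs, pool, X=cache.matrix(accs))
        X = cache.matrix(accs)
        predictor = fit_pls(X, dataset.y, fit.n_components)
        save_model(tmp_path / "m.json", fit, predictor, [X.shape[1]], dataset_name=dataset.name)
        payload = load_model(tmp_path / "m.json")
        reloaded: PLSPredictor = payload["predictor"]
        assert np.array_equal(reloaded.predict(X), predictor.predict(X))
        assert payload["accessions"] == list(accs)
        assert payload["loocv"]["cvrmse"] == fit.cvrmse
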