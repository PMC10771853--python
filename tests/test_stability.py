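import numpy as np
import pandas as pd
import pytest

from epiresponse import preprocess, stability, synthetic
from epiresponse.errors import ValidationError


def _dataset(rng, n_samples=30, n_features=40, n_informative=2, delta=2.0):
    X = rng.normal(size=(n_samples, n_features))
    y = np.repeat([0, 1], n_samples // 2)[:n_samples]
    X[:, :n_informative] += delta * y[:, None]
    return (
        pd.DataFrame(X, index=[f"S{i:03d}" for i in range(n_samples)],
                     columns=[f"f{j:03d}" for j in range(n_features)]),
        pd.Series(y, index=[f"S{i:03d}" for i in range(n_samples)]),
    )


class TestSplit:
    def test_92_samples_split_arithmetic(self):
        rng = np.random.default_rng(0)
        X, _ = _dataset(rng, 92, 5, 0)
        y = pd.Series([1] * 49 + [0] * 43, index=X.index)
        Xtr, ytr, Xte, yte = stability.split_train_test(X, y, 0.7, seed=1)
        assert len(ytr) == 64 and len(yte) == 28
        assert ytr.sum() == 34 and (ytr == 0).sum() == 30
        assert set(Xtr.index).isdisjoint(Xte.index)
        assert len(Xtr) + len(Xte) == 92

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        X, y = _dataset(rng)
        a = stability.split_train_test(X, y, 0.7, seed=5)
        b = stability.split_train_test(X, y, 0.7, seed=5)
        assert list(a[0].index) == list(b[0].index)

    def test_full_fraction_rejected(self):
        rng = np.random.default_rng(2)
        X, y = _dataset(rng)
        with pytest.raises(ValidationError):
            stability.split_train_test(X, y, 1.0, seed=0)

    def test_tiny_class_rejected(self):
        rng = np.random.default_rng(3)
        X, _ = _dataset(rng, 10, 5, 0)
        y = pd.Series([1] + [0] * 9, index=X.index)
        with pytest.raises(ValidationError, match="at least 2"):
            stability.split_train_test(X, y, 0.7, seed=0)


class TestAuroc:
    def test_perfect_separation(self):
        assert stability.auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert stability.auroc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_brute_force_oracle(self):
        """Pair-count oracle over 200 random instances, to 1e-12."""
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            scores = np.round(rng.normal(size=n), 1)  # rounding creates ties
            pos, neg = scores[y == 1], scores[y == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            oracle = wins / (len(pos) * len(neg))
            assert abs(stability.auroc(scores, y) - oracle) < 1e-12

    def test_complement_symmetry(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=20)
        y = rng.permutation([1] * 8 + [0] * 12)
        assert stability.auroc(scores, y) + stability.auroc(-scores, y) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            stability.auroc([0.1, 0.2], [1, 1])


@pytest.fixture(scope="module")
def small_run():
    rng = np.random.default_rng(6)
    X, y = _dataset(rng, 40, 60, 2, delta=2.5)
    config = stability.BoostConfig(
        n_resamples=10, cv_folds=5, n_estimators=50, n_permutations=500, seed=42
    )
    result = stability.run_stability_selection(X, y, config)
    return X, y, config, result


class TestStabilitySelection:
    def test_minimal_run_bookkeeping(self):
        rng = np.random.default_rng(7)
        X, y = _dataset(rng, 24, 20, 1)
        config = stability.BoostConfig(n_resamples=2, n_estimators=30, cv_folds=2, seed=0)
        result = stability.run_stability_selection(X, y, config)
        W = result.win_matrix
        assert (np.diag(W) == 0).all()
        assert (W + W.T <= 2).all()
        assert (result.selection_counts <= 2).all()

    def test_informative_features_selected(self, small_run):
        X, y, config, result = small_run
        freq = pd.Series(result.selection_counts, index=result.feature_names)
        top2 = set(freq.sort_values(ascending=False).index[:2])
        assert top2 == {"f000", "f001"}

    def test_constant_feature_never_selected(self):
        rng = np.random.default_rng(8)
        X, y = _dataset(rng, 30, 20, 1)
        X["f019"] = 3.0  # constant
        config = stability.BoostConfig(n_resamples=5, n_estimators=30, seed=1)
        result = stability.run_stability_selection(X, y, config)
        assert result.selection_counts[result.feature_names.index("f019")] == 0

    def test_reproducible_from_seed(self, small_run):
        X, y, config, result = small_run
        again = stability.run_stability_selection(X, y, config)
        np.testing.assert_array_equal(result.importances, again.importances)
        np.testing.assert_array_equal(result.win_matrix, again.win_matrix)


class TestAggregation:
    def _result_from_importances(self, imp, noise, seed=0):
        n_res, n_feat = imp.shape
        sel = (imp > noise[:, None]).sum(axis=0)
        win = np.zeros((n_feat, n_feat), dtype=np.int32)
        for r in range(n_res):
            win += (imp[r][:, None] > imp[r][None, :]).astype(np.int32)
        return stability.StabilityResult(
            feature_names=[f"f{j}" for j in range(n_feat)],
            selection_counts=sel,
            importances=imp,
            noise_trace=noise,
            win_matrix=win,
            cv_auc=np.full(n_res, 0.5),
            resample_meta=[(0, r, 0) for r in range(n_res)],
            seed=seed,
        )

    def test_condorcet_winner_ranked_first(self):
        rng = np.random.default_rng(9)
        imp = rng.uniform(0, 1, size=(20, 5))
        imp[:, 3] = 2.0 + rng.uniform(0, 1, 20)  # wins every comparison
        noise = np.zeros(20)
        result = self._result_from_importances(imp, noise)
        config = stability.BoostConfig(n_permutations=500, seed=0)
        panel = stability.aggregate_pairwise(result, config)
        assert panel.features[0] == "f3"

    def test_noise_equal_feature_excluded(self):
        rng = np.random.default_rng(10)
        noise = rng.uniform(0.5, 1.0, 30)
        imp = np.column_stack([noise, 3.0 + rng.uniform(0, 1, 30)])
        result = self._result_from_importances(imp, noise)
        config = stability.BoostConfig(n_permutations=500, seed=0)
        panel = stability.aggregate_pairwise(result, config)
        assert "f0" not in panel.features
        assert panel.table.loc["f0", "p_permutation"] == pytest.approx(1.0)
        assert "f1" in panel.features

    def test_constant_margin_minimal_pvalue(self):
        noise = np.zeros(100)
        imp = np.column_stack([np.full(100, 1.0), np.zeros(100)])
        result = self._result_from_importances(imp, noise)
        config = stability.BoostConfig(n_permutations=1000, seed=0)
        panel = stability.aggregate_pairwise(result, config)
        assert panel.table.loc["f0", "p_permutation"] <= 1.0 / config.n_permutations
        assert "f0" in panel.features

    def test_alpha_monotonicity(self, small_run):
        X, y, config, result = small_run
        tight = stability.BoostConfig(
            n_resamples=10, cv_folds=5, n_estimators=50, n_permutations=500,
            aggregation_alpha=0.01, seed=42,
        )
        loose_panel = stability.aggregate_pairwise(result, config)
        tight_panel = stability.aggregate_pairwise(result, tight)
        assert set(tight_panel.features) <= set(loose_panel.features)


class TestFinalModel:
    def test_leakage_free_and_reproducible(self, small_run):
        X, y, config, result = small_run
        panel = stability.aggregate_pairwise(result, config)
        # corrupting labels outside the training set cannot change selection,
        # because selection only ever sees the training set
        again = stability.run_stability_selection(X, y, config)
        np.testing.assert_array_equal(result.importances, again.importances)
        panel2 = stability.aggregate_pairwise(again, config)
        assert panel.features == panel2.features

    def test_empty_panel_gives_no_model(self, small_run):
        X, y, config, _ = small_run
        model = stability.train_final(X, y, [], config)
        assert model is None
        perf = stability.evaluate(model, X, y)
        assert np.isnan(perf.test_auroc)
        assert "empty panel" in perf.note

    def test_separable_data_scores_high(self):
        rng = np.random.default_rng(11)
        X, y = _dataset(rng, 60, 50, 3, delta=3.0)
        config = stability.BoostConfig(
            n_resamples=10, n_estimators=50, n_permutations=500, seed=2
        )
        Xtr, ytr, Xte, yte = stability.split_train_test(X, y, 0.7, seed=3)
        result = stability.run_stability_selection(Xtr, ytr, config)
        panel = stability.aggregate_pairwise(result, config)
        assert len(panel) >= 1
        model = stability.train_final(Xtr, ytr, panel, config)
        perf = stability.evaluate(model, Xte, yte, result, config.cv_folds)
        assert perf.test_auroc >= 0.8
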