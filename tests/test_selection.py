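"""ICC stability, mRMR ranking, cross-validated LASSO, Radscore."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from periradiomics.selection import (
    RadscoreModel,
    SelectionConfig,
    icc_2_1,
    lasso_cv,
    mrmr_select,
    radscore,
    stability_filter,
    stratified_folds,
)
from periradiomics.selection import _l1_logistic


def _anova_icc_oracle(x):
    """Direct two-way ANOVA mean-squares ICC(2,1)."""
    n, k = x.shape
    gm = x.mean()
    msr = k * ((x.mean(1) - gm) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(0) - gm) ** 2).sum() / (k - 1)
    mse = (((x - x.mean(1)[:, None] - x.mean(0)[None, :] + gm) ** 2).sum()
           / ((n - 1) * (k - 1)))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_identical_raters_give_one(self, rng):
        x = rng.normal(size=50)
        assert icc_2_1(np.column_stack([x, x])) == pytest.approx(1.0)

    def test_constant_matrix_convention(self):
        assert icc_2_1(np.full((5, 2), 3.0)) == 1.0

    def test_equal_noise_limit_half(self, rng):
        """Two raters observing signal + independent equal-variance noise:
        ICC(2,1) -> 0.5 analytically (signal var = noise var)."""
        n = 2000
        s = rng.normal(size=n)
        x = np.column_stack([s + rng.normal(size=n), s + rng.normal(size=n)])
        assert icc_2_1(x) == pytest.approx(0.5, abs=0.05)

    def test_matches_anova_oracle(self, rng):
        x = rng.normal(size=(30, 3)) + rng.normal(size=(30, 1))
        assert icc_2_1(x) == pytest.approx(_anova_icc_oracle(x), abs=1e-10)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            icc_2_1(np.ones((2, 2)))


class TestStabilityFilter:
    def test_identical_tables_keep_everything(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("abcde"))
        assert stability_filter(df, df.copy(), 0.75) == list("abcde")

    def test_noise_column_dropped(self, rng):
        df1 = pd.DataFrame(rng.normal(size=(142, 3)), columns=list("abc"))
        df2 = df1 + rng.normal(scale=0.05, size=(142, 3))
        df2["b"] = rng.normal(size=142)  # second reader sees pure noise
        kept = stability_filter(df1, df2, 0.75)
        assert "b" not in kept and {"a", "c"} <= set(kept)

    def test_threshold_one_requires_identity(self, rng):
        df1 = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        df2 = df1.copy()
        df2["b"] += rng.normal(scale=1e-3, size=30)
        assert stability_filter(df1, df2, 1.0) == ["a"]

    def test_misaligned_ids_rejected(self, rng):
        df1 = pd.DataFrame(rng.normal(size=(5, 2)), index=list("abcde"))
        df2 = pd.DataFrame(rng.normal(size=(5, 2)), index=list("abcdf"))
        with pytest.raises(ValueError):
            stability_filter(df1, df2)


def _exhaustive_mrmr_oracle(X, y, k):
    """Recompute the greedy MID trace from scratch at every step."""
    from sklearn.feature_selection import f_classif

    names = sorted(X.columns)
    Z = X[names].to_numpy(float)
    Z = (Z - Z.mean(0)) / np.where(Z.std(0) == 0, 1, Z.std(0))
    f = np.nan_to_num(f_classif(Z, y)[0], nan=0.0)
    rel = np.sqrt(f / (f + len(y) - 2))  # point-biserial scale
    corr = np.nan_to_num(np.abs(np.corrcoef(Z, rowvar=False)), nan=1.0)
    chosen = []
    while len(chosen) < k:
        best_name, best_score = None, -np.inf
        for i, nm in enumerate(names):
            if nm in chosen:
                continue
            red = np.mean([corr[i, names.index(c)] for c in chosen]) if chosen else 0.0
            score = rel[i] - red
            if score > best_score + 1e-12:
                best_name, best_score = nm, score
        chosen.append(best_name)
    return chosen


class TestMrmr:
    def test_first_pick_is_max_relevance(self, rng):
        y = rng.integers(0, 2, 80)
        X = pd.DataFrame(rng.normal(size=(80, 6)), columns=list("abcdef"))
        X["d"] += 3 * y  # overwhelming relevance
        assert mrmr_select(X, y, 3)[0] == "d"

    def test_matches_exhaustive_greedy_oracle(self, rng):
        y = rng.integers(0, 2, 60)
        X = pd.DataFrame(rng.normal(size=(60, 8)),
                         columns=[f"f{i}" for i in range(8)])
        X["f1"] += y
        X["f2"] += 0.5 * y
        assert mrmr_select(X, y, 8) == _exhaustive_mrmr_oracle(X, y.astype(float), 8)

    def test_duplicate_column_never_second(self, rng):
        y = rng.integers(0, 2, 100).astype(float)
        a = rng.normal(size=100) + 2 * y
        b = rng.normal(size=100) + 1 * y
        X = pd.DataFrame({"a": a, "a_copy": a, "b": b})
        order = mrmr_select(X, y, 3)
        assert order[0] in ("a", "a_copy")
        assert order[1] == "b"  # redundancy 1 with the duplicate dominates

    def test_k_too_large_returns_all_with_warning(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        y = rng.integers(0, 2, 20)
        with pytest.warns(UserWarning):
            assert len(mrmr_select(X, y, 10)) == 3


class TestLasso:
    def test_huge_lambda_gives_null_model_with_prevalence_intercept(self, rng):
        X = (rng.normal(size=(100, 5)) - 0) / 1
        y = (rng.random(100) < 0.3).astype(float)
        beta, b0 = _l1_logistic(X, y, lam=10.0)
        assert np.all(beta == 0)
        assert b0 == pytest.approx(special.logit(y.mean()), abs=1e-6)

    def test_kkt_conditions_at_solution(self, rng):
        """|gradient| <= lambda for zero coefficients, = lambda (opposite
        sign) at nonzero coefficients, tolerance 1e-6."""
        n, p, lam = 142, 60, 0.03
        X = rng.standard_normal((n, p))
        X = (X - X.mean(0)) / X.std(0)
        beta_true = np.zeros(p)
        beta_true[:4] = 1.0
        y = (rng.random(n) < special.expit(X @ beta_true)).astype(float)
        beta, b0 = _l1_logistic(X, y, lam)
        g = X.T @ (special.expit(b0 + X @ beta) - y) / n
        nz = beta != 0
        assert np.all(np.abs(g[~nz]) <= lam + 1e-6)
        assert np.max(np.abs(g[nz] + lam * np.sign(beta[nz]))) < 1e-6
        assert abs(np.mean(special.expit(b0 + X @ beta) - y)) < 1e-6

    def test_single_class_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)))
        with pytest.raises(ValueError):
            lasso_cv(X, np.ones(20))

    def test_constant_column_dropped_with_warning(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        X["c"] = 1.0
        y = rng.integers(0, 2, 60)
        y[:5] = 0
        y[-5:] = 1
        with pytest.warns(UserWarning, match="constant"):
            m = lasso_cv(X, y, SelectionConfig(seed=0, n_lambda=10))
        assert "c" not in m.feature_names

    def test_selection_chain_invariant_to_row_order(self, rng):
        n, p = 80, 12
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"f{i:02d}" for i in range(p)],
                         index=[f"case_{i:03d}" for i in range(n)])
        y = (rng.random(n) < special.expit(2 * X["f01"])).astype(int)
        ys = pd.Series(y.to_numpy() if hasattr(y, "to_numpy") else y, index=X.index)
        cfg = SelectionConfig(seed=3, n_lambda=15)
        m1 = lasso_cv(X, ys.to_numpy(), cfg)
        perm = rng.permutation(n)
        X2, y2 = X.iloc[perm], ys.iloc[perm]
        m2 = lasso_cv(X2, y2.to_numpy(), cfg)
        assert m1.feature_names == m2.feature_names
        np.testing.assert_allclose(m1.coefficients, m2.coefficients, rtol=1e-6)


class TestRadscore:
    def test_zero_model_scores_half(self):
        m = RadscoreModel(roi_kind="GTV", feature_names=["a"],
                          coefficients=np.array([0.0]), intercept=0.0,
                          lambda_=0.1, lambda_path=np.array([]),
                          cv_deviance=np.array([]), cv_deviance_se=np.array([]),
                          seed=0)
        assert radscore(m, {"a": 123.0}) == pytest.approx(0.5)

    def test_monotone_in_positive_feature(self):
        m = RadscoreModel(roi_kind="GTV", feature_names=["a"],
                          coefficients=np.array([2.0]), intercept=-1.0,
                          lambda_=0.1, lambda_path=np.array([]),
                          cv_deviance=np.array([]), cv_deviance_se=np.array([]),
                          seed=0)
        scores = [radscore(m, {"a": v}) for v in np.linspace(-3, 3, 20)]
        assert np.all(np.diff(scores) > 0)

    def test_missing_feature_raises(self):
        m = RadscoreModel(roi_kind="GTV", feature_names=["a", "b"],
                          coefficients=np.array([1.0, 1.0]), intercept=0.0,
                          lambda_=0.1, lambda_path=np.array([]),
                          cv_deviance=np.array([]), cv_deviance_se=np.array([]),
                          seed=0)
        with pytest.raises(KeyError):
            radscore(m, {"a": 1.0})

    def test_fitted_scores_equal_generic_logistic_predictor(self, rng):
        X = pd.DataFrame(rng.normal(size=(90, 8)),
                         columns=[f"f{i}" for i in range(8)])
        y = (rng.random(90) < special.expit(X["f0"] - X["f3"])).astype(int)
        m = lasso_cv(X, y, SelectionConfig(seed=1, n_lambda=15))
        scores = m.predict(X)
        manual = special.expit(m.intercept
                               + X[m.feature_names].to_numpy() @ m.coefficients)
        np.testing.assert_allclose(scores, manual, atol=1e-12)

    def test_json_round_trip(self, tmp_path, rng):
        X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        y = (rng.random(60) < special.expit(X["a"])).astype(int)
        m = lasso_cv(X, y, SelectionConfig(seed=2, n_lambda=10))
        p = tmp_path / "model.json"
        m.to_json(p)
        m2 = RadscoreModel.from_json(p)
        np.testing.assert_allclose(m2.predict(X), m.predict(X), atol=1e-12)


class TestFolds:
    def test_assignment_depends_on_ids_not_positions(self, rng):
        ids = [f"c{i:02d}" for i in range(30)]
        y = rng.integers(0, 2, 30)
        f1 = stratified_folds(ids, y, 5, seed=4)
        perm = rng.permutation(30)
        f2 = stratified_folds([ids[i] for i in perm], y[perm], 5, seed=4)
        assert all(f1[i] == f2[i] for i in ids)

    def test_stratification_balances_classes(self, rng):
        y = np.array([0] * 40 + [1] * 60)
        ids = [f"c{i}" for i in range(100)]
        f = stratified_folds(ids, y, 10, seed=0)
        per_fold_pos = [sum(y[j] for j, i in enumerate(ids) if f[i] == k)
                        for k in range(10)]
        assert max(per_fold_pos) - min(per_fold_pos) <= 1
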