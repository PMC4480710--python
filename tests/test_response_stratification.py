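"""Separation check, response labelling, batch combination, feature selection,
ridge logistic classifier, LOO cross-validation, permutation null, and the
association screens."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st
from sklearn.linear_model import LogisticRegression

from mdm2strat import response_stratification as rs
from mdm2strat.errors import ValidationError


def null_dataset(seed, n=30, p=25, n_tissues=3, responder_rate=0.3):
    """Expression independent of labels: the no-signal benchmark."""
    rng = np.random.default_rng(seed)
    lines = [f"L{i:03d}" for i in range(n)]
    expr = pd.DataFrame(
        rng.normal(size=(p, n)),
        index=[f"pr{j:03d}" for j in range(p)], columns=lines,
    )
    labels = pd.Series(rng.random(n) < responder_rate, index=lines)
    tissue = pd.Series(
        rng.choice([f"t{k}" for k in range(n_tissues)], n), index=lines
    )
    return expr, labels, tissue


class TestSeparation:
    def test_disjoint_classes_separate(self):
        df = pd.DataFrame({
            "status": ["WT", "WT", "MUTANT", "MUTANT"],
            "ic50_um": [0.1, 0.5, 50.0, 50.0],
            "censored": [False, False, True, True],
        })
        sep, (hi, lo) = rs.check_complete_separation(df)
        assert sep and hi == 0.5 and lo == np.inf

    def test_overlap_fails(self):
        df = pd.DataFrame({
            "status": ["WT", "WT", "MUTANT"],
            "ic50_um": [0.1, 10.0, 5.0],
            "censored": [False] * 3,
        })
        assert not rs.check_complete_separation(df)[0]

    def test_empty_class_flagged(self):
        df = pd.DataFrame({"status": ["WT"], "ic50_um": [1.0], "censored": [False]})
        with pytest.raises(ValidationError):
            rs.check_complete_separation(df)

    def test_default_fixture_separates(self, curated_result):
        curated, _ = curated_result
        assert rs.check_complete_separation(curated)[0]


class TestCategorizeResponse:
    def test_interpolated_lower_quartile(self):
        labels, q1 = rs.categorize_response([1, 2, 3, 4, 5, 6, 7, 8])
        assert q1 == pytest.approx(2.75)
        assert labels.tolist() == [True, True] + [False] * 6

    def test_all_equal_all_responders(self):
        labels, _ = rs.categorize_response([2.0] * 5)
        assert labels.all()

    def test_censored_never_respond(self):
        labels, _ = rs.categorize_response(
            [0.1, 0.2, 50.0, 50.0, 0.3, 0.4], [False, False, True, True, False, False]
        )
        assert not labels[2] and not labels[3]

    def test_all_censored_no_responders(self):
        labels, _ = rs.categorize_response([50.0] * 6, [True] * 6)
        assert not labels.any()

    def test_too_few_lines_rejected(self):
        with pytest.raises(ValidationError):
            rs.categorize_response([1.0, 2.0, 3.0])


class TestRestrictBalancedTissues:
    def test_single_class_tissue_dropped(self):
        labels = pd.Series([True, False, False, False, False],
                           index=list("abcde"))
        tissue = pd.Series(["x", "x", "y", "y", "y"], index=list("abcde"))
        assert rs.restrict_balanced_tissues(labels, tissue) == ["a", "b"]

    def test_all_balanced_identity(self):
        labels = pd.Series([True, False, True, False], index=list("abcd"))
        tissue = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        assert rs.restrict_balanced_tissues(labels, tissue) == list("abcd")


class TestBatchCombination:
    def test_exact_affine_inversion(self):
        rng = np.random.default_rng(0)
        probes = [f"p{j}" for j in range(10)]
        b1 = pd.DataFrame(rng.normal(7, 1, (10, 8)), index=probes,
                          columns=[f"s{i}" for i in range(8)])
        b2 = 2.0 * b1.iloc[:, :5] + 3.0
        b2.columns = ["s0", "s1", "s2", "n0", "n1"]
        out = rs.combine_expression_batches(b1, b2, ["s0", "s1", "s2"])
        np.testing.assert_allclose(
            out["n0"].to_numpy(), (b2["n0"].to_numpy() - 3.0) / 2.0, rtol=1e-12
        )
        # shared lines keep batch1 values
        np.testing.assert_allclose(out["s0"], b1["s0"])

    def test_identical_scale_batches_identity_transform(self):
        rng = np.random.default_rng(1)
        probes = [f"p{j}" for j in range(5)]
        b1 = pd.DataFrame(rng.normal(size=(5, 4)), index=probes,
                          columns=list("abcd"))
        b2 = b1[["a", "b"]].copy()
        b2["e"] = rng.normal(size=5)  # already on the batch1 scale
        out = rs.combine_expression_batches(b1, b2, ["a", "b"])
        np.testing.assert_allclose(out["e"], b2["e"], rtol=1e-9)
        np.testing.assert_allclose(out[list("abcd")], b1)

    def test_ambiguous_overlap_rejected(self):
        b1 = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p0"], columns=list("abc"))
        with pytest.raises(ValidationError, match="shared"):
            rs.combine_expression_batches(b1, b1[["a", "b", "c"]], ["a", "b"])

    def test_noisy_slope_matches_polyfit_oracle(self):
        rng = np.random.default_rng(2)
        shared = [f"s{i}" for i in range(20)]
        b1 = pd.DataFrame(rng.normal(7, 1.5, (1, 20)), index=["p0"], columns=shared)
        noise = rng.normal(0, 0.1, 20)
        b2 = pd.DataFrame(1.4 * b1.to_numpy() - 2.0 + noise, index=["p0"],
                          columns=shared)
        out = rs.combine_expression_batches(b1, b2, shared)
        # recover the oracle fit for a probe and check a transformed point
        slope, intercept = np.polyfit(b2.loc["p0"], b1.loc["p0"], 1)
        x = 9.0
        b2x = pd.DataFrame([[x]], index=["p0"], columns=["new"])
        merged = rs.combine_expression_batches(
            b1, pd.concat([b2, b2x], axis=1), shared
        )
        assert merged.loc["p0", "new"] == pytest.approx(slope * x + intercept)

    def test_too_few_shared_rejected(self):
        b = pd.DataFrame([[1.0, 2.0]], index=["p0"], columns=["a", "b"])
        with pytest.raises(ValidationError):
            rs.combine_expression_batches(b, b, ["a"])


class TestFeatureSelection:
    def test_planted_effect_ranks_first(self):
        expr, labels, tissue = null_dataset(3, n=40, p=30)
        expr.loc["pr007"] = expr.loc["pr007"] + 3.0 * labels.to_numpy()
        ranked = rs.anova_feature_select(expr, labels, tissue)
        assert ranked.index[0] == "pr007"

    def test_constant_probe_ranks_last(self):
        expr, labels, tissue = null_dataset(4)
        expr.loc["pr000"] = 5.0
        ranked = rs.anova_feature_select(expr, labels, tissue)
        assert ranked.index[-1] == "pr000"
        assert np.isnan(ranked.loc["pr000", "p_value"])

    def test_single_tissue_degrades_to_one_way(self):
        expr, labels, tissue = null_dataset(5)
        tissue[:] = "only"
        ranked = rs.anova_feature_select(expr, labels, tissue)
        assert ranked["p_value"].notna().all()

    def test_p_value_matches_statsmodels(self):
        expr, labels, tissue = null_dataset(6, n=25, p=4)
        ranked = rs.anova_feature_select(expr, labels, tissue)
        dummies = pd.get_dummies(tissue, drop_first=True, dtype=float)
        X = sm.add_constant(
            pd.concat([labels.astype(float).rename("resp"), dummies], axis=1)
        )
        for probe in expr.index:
            fit = sm.OLS(expr.loc[probe, labels.index].to_numpy(), X).fit()
            assert ranked.loc[probe, "p_value"] == pytest.approx(
                fit.pvalues["resp"], rel=1e-8
            )

    def test_null_p_values_uniform(self):
        """Under label-independence the response-term p-value is U(0,1)."""
        from scipy.stats import kstest

        ps = []
        for seed in range(120):
            expr, labels, tissue = null_dataset(1000 + seed, n=24, p=1)
            if labels.nunique() < 2:
                continue
            ps.append(
                rs.anova_feature_select(expr, labels, tissue)["p_value"].iloc[0]
            )
        assert kstest(ps, "uniform").pvalue > 0.01


class TestRidgeLogistic:
    def test_matches_sklearn_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=40)
        y = (x + rng.normal(0, 1, 40) > 0).astype(float)
        lam = 1.0
        X = np.column_stack([np.ones(40), x])
        beta = rs.ridge_logistic_fit(X, y, lam=lam)
        sk = LogisticRegression(C=1.0 / lam, tol=1e-12, max_iter=10000)
        sk.fit(x[:, None], y)
        assert beta[0] == pytest.approx(sk.intercept_[0], abs=1e-5)
        assert beta[1] == pytest.approx(sk.coef_[0][0], abs=1e-5)

    def test_penalized_nll_is_minimized(self):
        """Independent oracle: the IRLS optimum beats nearby perturbations of
        the penalized negative log-likelihood."""
        rng = np.random.default_rng(8)
        x = rng.normal(size=25)
        y = (rng.random(25) < 0.4).astype(float)
        X = np.column_stack([np.ones(25), x])
        lam = 2.0
        beta = rs.ridge_logistic_fit(X, y, lam=lam)

        def pnll(b):
            eta = X @ b
            return np.sum(np.log1p(np.exp(-np.abs(eta))) + np.maximum(eta, 0)
                          - y * eta) + lam / 2 * b[1] ** 2

        base = pnll(beta)
        for delta in np.eye(2) * 1e-3:
            assert pnll(beta + delta) >= base - 1e-12
            assert pnll(beta - delta) >= base - 1e-12

    def test_separable_training_predicts_correct_side(self):
        pred, prob = rs.logistic_predict(
            [-2.0, -1.0, 1.0, 2.0], [False, False, True, True],
            ["t"] * 4, 1.5, "t",
        )
        assert pred and prob > 0.5

    def test_tie_probability_is_non_responder(self):
        # symmetric design: held-out point at the midpoint has probability 0.5
        pred, prob = rs.logistic_predict(
            [-1.0, 1.0], [False, True], ["t", "t"], 0.0, "t"
        )
        assert prob == pytest.approx(0.5, abs=1e-9)
        assert pred == (prob > 0.5)

    def test_single_class_training_rejected(self):
        with pytest.raises(ValidationError):
            rs.logistic_predict([1.0, 2.0], [True, True], ["t", "t"], 1.0, "t")


class TestLoo:
    def test_one_prediction_per_line(self):
        expr, labels, tissue = null_dataset(9)
        cv = rs.loo_cross_validate(expr, labels, tissue)
        assert len(cv.predictions) == len(labels)
        assert 0.0 <= cv.percent_correct <= 100.0

    def test_deterministic(self):
        expr, labels, tissue = null_dataset(10)
        a = rs.loo_cross_validate(expr, labels, tissue)
        b = rs.loo_cross_validate(expr, labels, tissue)
        assert a.predictions.equals(b.predictions)
        assert a.percent_correct == b.percent_correct

    def test_single_class_fold_flagged(self):
        expr, labels, tissue = null_dataset(11, n=10)
        labels[:] = False
        labels.iloc[0] = True  # removing line 0 leaves a single class
        cv = rs.loo_cross_validate(expr, labels, tissue)
        assert labels.index[0] in cv.flagged_folds

    def test_no_leakage_on_null_data(self):
        """With labels independent of expression, LOO accuracy must not beat
        the majority-class baseline on average (selection leakage would)."""
        diffs = []
        for seed in range(60):
            expr, labels, tissue = null_dataset(seed, n=24, p=20)
            if labels.nunique() < 2:
                continue
            cv = rs.loo_cross_validate(expr, labels, tissue)
            majority = 100.0 * max(labels.mean(), 1 - labels.mean())
            diffs.append(cv.percent_correct - majority)
        mean, se = np.mean(diffs), np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert mean < 2.58 * se  # not significantly above baseline


class TestPermutation:
    def test_margins_preserved_exactly(self):
        rng = np.random.default_rng(12)
        y = rng.random(40) < 0.35
        codes = rng.integers(0, 4, 40)
        for _ in range(25):
            shuffled = rs._shuffle_within_tissue(y.copy(), codes, rng)
            for level in np.unique(codes):
                assert shuffled[codes == level].sum() == y[codes == level].sum()

    def test_observed_above_all_permuted_is_100th(self):
        expr, labels, tissue = null_dataset(13, n=20, p=10)
        expr.loc["pr000"] = expr.loc["pr000"] + 8.0 * labels.to_numpy()
        res = rs.permutation_percentile(expr, labels, tissue, n_perm=19, seed=0)
        if (res.permuted < res.observed).all():
            assert res.percentile == 100.0

    def test_min_permutations_enforced(self):
        expr, labels, tissue = null_dataset(14)
        with pytest.raises(ValidationError):
            rs.permutation_percentile(expr, labels, tissue, n_perm=5)

    def test_strict_tie_rule_below_mid(self):
        expr, labels, tissue = null_dataset(15, n=16, p=8)
        mid = rs.permutation_percentile(expr, labels, tissue, n_perm=19, seed=1,
                                        tie="mid")
        strict = rs.permutation_percentile(expr, labels, tissue, n_perm=19,
                                           seed=1, tie="strict")
        assert strict.percentile <= mid.percentile


class TestAssociations:
    def test_bh_hand_example(self):
        np.testing.assert_allclose(
            rs.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_single_p_unchanged(self):
        assert rs.bh_adjust([0.37])[0] == pytest.approx(0.37)

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=40))
    def test_bh_matches_step_up_oracle(self, ps):
        p = np.asarray(ps)
        m = p.size
        order = np.argsort(p)
        stepped = p[order] * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(stepped[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.clip(stepped, 0, 1)
        np.testing.assert_allclose(rs.bh_adjust(p), oracle, rtol=1e-10)

    def test_mutation_association_screen(self):
        rng = np.random.default_rng(16)
        lines = [f"L{i}" for i in range(40)]
        metric = pd.Series(rng.normal(size=40), index=lines)
        muts = pd.DataFrame(
            {"GENEA": rng.random(40) < 0.3,
             "GENEB": rng.random(40) < 0.2,
             "NEVER": np.zeros(40, bool),
             "ALWAYS": np.ones(40, bool)},
            index=lines,
        ).astype(int)
        out = rs.mutation_association(metric, muts)
        assert set(out["gene"]) == {"GENEA", "GENEB"}  # degenerate genes dropped
        assert (out["q_value"] >= out["p_value"] - 1e-15).all()

    def test_expression_association_exact_linear(self):
        x = np.linspace(0, 1, 20)
        slope, p = rs.expression_association(2.0 * x + 1.0, x)
        assert slope == pytest.approx(2.0)
        assert p < 1e-10

    def test_expression_association_needs_three_points(self):
        with pytest.raises(ValidationError):
            rs.expression_association([1.0, 2.0], [0.0, 1.0])

    def test_zero_variance_regressor_flagged(self):
        slope, p = rs.expression_association([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert np.isnan(slope) and np.isnan(p)
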