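"""Survival estimation, ROC/AUC and response-combination contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmescope import (
    ExpressionMatrix,
    FractionTable,
    cell_prognostic_network,
    combine_tmb_score,
    cox_fit,
    gene_report,
    km_fit,
    logrank_test,
    roc_auc,
)
from tmescope.score import logrank_z


class TestKaplanMeier:
    def test_no_censoring_empirical_survival(self):
        fit = km_fit([1.0, 2.0, 3.0], [1, 1, 1])
        curve = fit.curves["all"].set_index("time")["survival"]
        np.testing.assert_allclose(curve.loc[[1.0, 2.0, 3.0]], [2 / 3, 1 / 3, 0.0])

    def test_all_censored_flat(self):
        fit = km_fit([5.0, 7.0, 9.0], [0, 0, 0])
        assert (fit.curves["all"]["survival"] == 1.0).all()

    def test_hand_computed_mixed_censoring(self):
        # subjects: times 2,3+,4,4,6+,7 (+=censored)
        times = [2.0, 3.0, 4.0, 4.0, 6.0, 7.0]
        events = [1, 0, 1, 1, 0, 1]
        fit = km_fit(times, events)
        curve = fit.curves["all"].set_index("time")["survival"]
        # risk sets: t=2 n=6 d=1 -> 5/6; t=4 n=4 d=2 -> 5/6*2/4; t=7 n=1 d=1 -> 0
        np.testing.assert_allclose(curve.loc[2.0], 5 / 6)
        np.testing.assert_allclose(curve.loc[4.0], 5 / 6 * 2 / 4)
        np.testing.assert_allclose(curve.loc[7.0], 0.0)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_fit([-1.0, 2.0], [1, 1])


class TestLogrank:
    def test_identical_groups_null(self):
        times = np.array([3.0, 5.0, 8.0, 11.0] * 2)
        events = np.array([1, 0, 1, 1] * 2)
        groups = np.repeat(["a", "b"], 4)
        stat, df, p = logrank_test(times, events, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_matches_permutation_reference(self):
        rng = np.random.default_rng(8)
        times = rng.exponential(20, 20)
        events = rng.integers(0, 2, 20)
        events[:4] = 1
        groups = np.repeat(["a", "b"], 10)
        stat, _df, p = logrank_test(times, events, groups)
        mask = groups == "a"
        null = np.empty(5000)
        for i in range(5000):
            null[i] = logrank_z(times, events, rng.permutation(mask)) ** 2
        perm_p = np.mean(null >= stat)
        assert abs(perm_p - p) < 0.05

    def test_single_group_refused(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], ["a", "a"])

    def test_time_scale_invariance(self):
        rng = np.random.default_rng(9)
        times = rng.exponential(10, 40)
        events = rng.integers(0, 2, 40)
        events[0] = 1
        groups = rng.integers(0, 2, 40)
        s1, _, _ = logrank_test(times, events, groups)
        s2, _, _ = logrank_test(np.log1p(times), events, groups)  # monotone map
        np.testing.assert_allclose(s1, s2, rtol=1e-9)


def _cox_sim(rng, n=500, hr=2.0, censor_target=0.3):
    x = rng.integers(0, 2, n).astype(float)
    haz = 0.05 * hr**x
    t = rng.exponential(1.0 / haz)
    c = rng.exponential(1.0 / (0.05 * censor_target / (1 - censor_target)), n)
    return pd.DataFrame({"x": x}), np.minimum(t, c), (t <= c).astype(int)


class TestCox:
    def test_hr_recovery(self):
        rng = np.random.default_rng(21)
        cov, times, events = _cox_sim(rng)
        fit = cox_fit(cov, times, events)
        hr = fit.coefficients.loc["x", "HR"]
        assert 1.7 < hr < 2.35

    def test_null_covariate_within_two_se(self):
        inside = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            cov, times, events = _cox_sim(rng, n=150, hr=1.0)
            fit = cox_fit(cov, times, events)
            row = fit.coefficients.loc["x"]
            if abs(row["beta"]) < 2 * row["se"]:
                inside += 1
        assert inside >= 90

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        cov, times, events = _cox_sim(rng, n=300)
        b1 = cox_fit(cov, times, events).coefficients.loc["x", "beta"]
        b2 = cox_fit(cov * 2.0, times, events).coefficients.loc["x", "beta"]
        np.testing.assert_allclose(b1, 2.0 * b2, atol=1e-6)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(
                pd.DataFrame({"x": np.ones(50)}),
                np.arange(1, 51, dtype=float),
                np.ones(50, dtype=int),
            )


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res["auc"] == 1.0

    def test_all_ties_half(self):
        res = roc_auc(np.ones(10), [0, 1] * 5)
        assert res["auc"] == 0.5

    def test_brute_force_pairs(self, rng):
        score = rng.normal(size=12)
        y = np.array([0, 1] * 6)
        res = roc_auc(score, y)
        pos, neg = score[y == 1], score[y == 0]
        conc = sum(
            1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
        )
        assert res["auc"] == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-15)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(-5, 5), min_size=4, max_size=20),
        st.data(),
    )
    def test_negation_symmetry(self, scores, data):
        y = data.draw(
            st.lists(st.sampled_from([0, 1]), min_size=len(scores), max_size=len(scores))
        )
        if len(set(y)) < 2:
            y[0], y[-1] = 0, 1
        s = np.asarray(scores)
        assert roc_auc(s, y)["auc"] + roc_auc(-s, y)["auc"] == pytest.approx(1.0)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


class TestCombineTmbScore:
    def test_nested_likelihood_monotone(self, rng):
        for _ in range(20):
            n = 60
            tmb = rng.normal(size=n)
            score = rng.normal(size=n)
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            res = combine_tmb_score(tmb, score, y)
            assert res["llf_combined"] >= res["llf_tmb"] - 1e-8
            assert res["llf_combined"] >= res["llf_score"] - 1e-8

    def test_null_second_covariate_lr_p_uniform(self):
        from scipy import stats

        pvals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 120
            tmb = rng.normal(size=n)
            y = (rng.uniform(size=n) < 1 / (1 + np.exp(-tmb))).astype(int)
            noise = rng.normal(size=n)
            res = combine_tmb_score(tmb, noise, y)
            pvals.append(res["lr_p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_two_informative_covariates_combine_better(self):
        rng = np.random.default_rng(12)
        n = 400
        a, b = rng.normal(size=n), rng.normal(size=n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-(0.75 * a + 0.75 * b)))).astype(int)
        res = combine_tmb_score(a, b, y)
        assert res["auc_combined"] > max(res["auc_tmb"], res["auc_score"])
        assert res["lr_p"] < 0.01

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError, match="complete cases"):
            combine_tmb_score(np.ones(5), np.ones(5), [0, 1, 0, 1, 0])


def _fraction_table(fractions: pd.DataFrame) -> FractionTable:
    stats_df = pd.DataFrame(
        {
            "fit_correlation": 1.0,
            "fit_rmse": 0.0,
            "perm_pvalue": np.nan,
        },
        index=fractions.index,
    )
    return FractionTable(fractions=fractions, stats=stats_df)


class TestCellPrognosticNetwork:
    @staticmethod
    def _cohort(rng, n=500, hazard_cell=None):
        fr = rng.dirichlet(np.ones(4) * 2.0, size=n)
        haz = 0.02 * np.ones(n)
        if hazard_cell is not None:
            # hazard doubles per +0.1 fraction of the flagged cell type
            haz = 0.02 * np.power(2.0, fr[:, hazard_cell] / 0.1)
        t = rng.exponential(1.0 / haz)
        c = rng.exponential(100.0, n)
        clin = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "os_time": np.minimum(t, c),
                "os_event": (t <= c).astype(int),
            }
        )
        fractions = pd.DataFrame(
            fr, index=clin["sample_id"], columns=[f"CT{j}" for j in range(4)]
        )
        return _fraction_table(fractions), clin

    def test_duplicated_cell_type_rho_one(self, rng):
        fr, clin = self._cohort(rng, n=100)
        dup = fr.fractions.copy()
        dup["CT0_copy"] = dup["CT0"]
        dup = dup.div(dup.sum(axis=1), axis=0)
        net = cell_prognostic_network(_fraction_table(dup), clin)
        assert net["rho"].loc["CT0", "CT0_copy"] == pytest.approx(1.0)

    def test_compositional_negative_correlation(self, rng):
        fr, clin = self._cohort(rng, n=300)
        net = cell_prognostic_network(fr, clin)
        off = net["rho"].to_numpy()[np.triu_indices(4, k=1)]
        assert off.min() < 0  # simplex closure forces some negative rho

    def test_hazardous_cell_flagged_risk(self):
        rng = np.random.default_rng(33)
        fr, clin = self._cohort(rng, n=500, hazard_cell=2)
        net = cell_prognostic_network(fr, clin)
        row = net["prognostic"].loc["CT2"]
        assert row["flag"] == "risk"
        assert row["p"] < 0.01


class TestGeneReport:
    @staticmethod
    def _setup(rng, n=60, link_cell=None, hr=None):
        fr = rng.dirichlet(np.ones(3) * 3.0, size=n)
        samples = [f"s{i}" for i in range(n)]
        genes = {"GENE1": rng.normal(5, 1, n)}
        if link_cell is not None:
            genes["GENE1"] = 4 + 3 * fr[:, link_cell] + rng.normal(0, 0.05, n)
        expr = ExpressionMatrix(
            pd.DataFrame(genes, index=samples).T.astype(float), "log2"
        )
        haz = 0.02 * np.ones(n)
        if hr is not None:
            med = np.median(genes["GENE1"])
            haz = 0.02 * np.where(genes["GENE1"] > med, hr, 1.0)
        t = rng.exponential(1.0 / haz)
        c = rng.exponential(100.0, n)
        clin = pd.DataFrame(
            {
                "sample_id": samples,
                "os_time": np.minimum(t, c),
                "os_event": (t <= c).astype(int),
                "er": rng.choice(["pos", "neg"], n),
                "pr": rng.choice(["pos", "neg"], n),
                "her2": rng.choice(["pos", "neg"], n),
            }
        )
        fractions = pd.DataFrame(fr, index=samples, columns=["CTA", "CTB", "CTC"])
        return expr, _fraction_table(fractions), clin

    def test_missing_gene_lists_neighbours(self, rng):
        expr, fr, clin = self._setup(rng)
        with pytest.raises(KeyError, match="GENE1"):
            gene_report(expr, "gene1X", fr, clin)

    def test_identical_expression_across_er_groups_p_one(self, rng):
        expr, fr, clin = self._setup(rng, n=12)
        expr.values.loc["GENE1"] = np.arange(12, dtype=float)
        clin["er"] = ["pos", "neg"] * 6
        # pair pos/neg samples with identical expression values
        expr.values.loc["GENE1"] = np.repeat(np.arange(6, dtype=float), 2)
        rep = gene_report(expr, "GENE1", fr, clin)
        p_er = rep["wilcoxon"].set_index("contrast").loc["er", "p"]
        assert p_er > 0.9

    def test_linked_cell_type_has_largest_rho(self, rng):
        expr, fr, clin = self._setup(rng, n=80, link_cell=1)
        rep = gene_report(expr, "GENE1", fr, clin)
        corr = rep["fraction_correlations"].set_index("cell_type")["rho"].abs()
        assert corr.idxmax() == "CTB"

    def test_engineered_hazard_split_detected(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            expr, fr, clin = self._setup(rng, n=400, hr=2.5)
            rep = gene_report(expr, "GENE1", fr, clin)
            if rep["logrank"]["p"] < 0.001:
                hits += 1
        assert hits >= 38
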