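"""Statistical machinery against exact enumeration and simulation oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ihcquant import cohort_statistics as st
from ihcquant import synthetic_data as sd
from ihcquant.exceptions import InsufficientDataError, ValidationError

# ---------------------------------------------------------------------------
# independent oracles


def wilcoxon_exact_oracle(x, y):
    """Two-sided signed-rank p by enumeration of all sign assignments."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    t_obs = ranks[d > 0].sum()
    ts = np.array([(ranks * np.array(signs)).sum()
                   for signs in itertools.product([0, 1], repeat=d.size)])
    return min(1.0, 2 * min((ts <= t_obs).mean(), (ts >= t_obs).mean()))


def mannwhitney_exact_oracle(a, b):
    """Two-sided U-test p by enumeration of all group assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1 = a.size

    def u_stat(aa, bb):
        return sum((ai > bj) + 0.5 * (ai == bj) for ai in aa for bj in bb)

    u_obs = u_stat(a, b)
    idx = np.arange(pooled.size)
    us = np.array([
        u_stat(pooled[list(comb)], np.delete(pooled, list(comb)))
        for comb in itertools.combinations(idx, n1)
    ])
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


def auc_pairwise_oracle(scores, labels):
    """O(n^2) concordant/tied pair count."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    num = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return num / (pos.size * neg.size)


# ---------------------------------------------------------------------------


class TestCategorizers:
    @pytest.mark.parametrize("t,want", [(1, "T1-2"), (2, "T1-2"), (3, "T3-4"), (4, "T3-4")])
    def test_t_dichotomy(self, t, want):
        assert st.categorize_t(t) == want

    @pytest.mark.parametrize("n,want", [(0, "node_negative"), (1, "node_positive"),
                                        (2, "node_positive")])
    def test_n_dichotomy(self, n, want):
        assert st.categorize_n(n) == want

    @pytest.mark.parametrize("v,want", [(0, "early"), (1, "early"), (2, "early"),
                                        (3, "advanced"), (4, "advanced")])
    def test_tnm_dichotomy(self, v, want):
        assert st.categorize_tnm(v) == want

    @pytest.mark.parametrize("fn,bad", [(st.categorize_t, 5), (st.categorize_t, 0),
                                        (st.categorize_n, -1), (st.categorize_tnm, 5)])
    def test_out_of_domain_rejected(self, fn, bad):
        with pytest.raises(ValidationError):
            fn(bad)


class TestPairedComparison:
    def test_all_zero_differences_degenerate(self):
        x = np.arange(10.0)
        res = st.compare_paired(x, x, method="wilcoxon")
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert res.flag == "degenerate_all_zero"

    def test_constant_shift_paired_t_degenerate(self):
        x = np.arange(20.0)
        res = st.compare_paired(x + 10.0, x, method="paired_t")
        assert res.flag == "degenerate_zero_variance"
        assert math.isnan(res.p_value)

    def test_paired_t_matches_closed_form(self, rng):
        x = rng.normal(5, 2, 20)
        y = rng.normal(4, 2, 20)
        res = st.compare_paired(x, y, method="paired_t")
        d = x - y
        t = d.mean() / (d.std(ddof=1) / np.sqrt(20))
        p = 2 * sps.t.sf(abs(t), 19)
        assert res.statistic == pytest.approx(t)
        assert res.p_value == pytest.approx(p)

    @pytest.mark.parametrize("n", [6, 9, 12])
    def test_wilcoxon_matches_exact_enumeration(self, n, rng):
        for _ in range(3):
            x = rng.normal(0, 1, n)
            y = rng.normal(0.3, 1, n)
            res = st.compare_paired(x, y, method="wilcoxon")
            assert res.p_value == pytest.approx(wilcoxon_exact_oracle(x, y), abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            st.compare_paired([1.0, 2.0], [2.0, 1.0])

    def test_nan_pairs_dropped(self, rng):
        x = rng.normal(0, 1, 15)
        y = rng.normal(0, 1, 15)
        x2, y2 = x.copy(), y.copy()
        x2[3] = np.nan
        res = st.compare_paired(x2, y2)
        keep = np.delete(np.arange(15), 3)
        ref = st.compare_paired(x[keep], y[keep])
        assert res.p_value == ref.p_value and res.n == 14


class TestGroupComparison:
    def test_identical_groups_give_central_u(self):
        v = np.concatenate([np.arange(6.0), np.arange(6.0)])
        g = np.array(["a"] * 6 + ["b"] * 6)
        res = st.compare_groups(v, g)
        assert res.statistic == pytest.approx(18.0)  # n1*n2/2

    def test_fully_separated_small_groups(self):
        res = st.compare_groups(np.array([1, 2, 3, 10, 11, 12.0]),
                                np.array(["a", "a", "a", "b", "b", "b"]))
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2 / C(6,3)

    @pytest.mark.parametrize("sizes", [(4, 5), (6, 6), (8, 8)])
    def test_matches_exact_enumeration(self, sizes, rng):
        n1, n2 = sizes
        a = rng.normal(0, 1, n1)
        b = rng.normal(0.5, 1, n2)
        v = np.concatenate([a, b])
        g = np.array(["a"] * n1 + ["b"] * n2)
        res = st.compare_groups(v, g)
        assert res.p_value == pytest.approx(mannwhitney_exact_oracle(a, b), abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            st.compare_groups(np.arange(5.0), np.array(["a", "a", "b", "b", "b"]))


class TestRocAuc:
    def test_perfect_ranking(self):
        assert st.roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert st.roc_auc([5.0] * 8, [0, 1] * 4) == 0.5

    def test_matches_pairwise_oracle(self, rng):
        for n in (10, 50, 120):
            scores = rng.integers(0, 20, n).astype(float)  # many ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert st.roc_auc(scores, labels) == pytest.approx(
                auc_pairwise_oracle(scores, labels), abs=1e-12)

    def test_label_reversal_complements(self, rng):
        scores = rng.normal(0, 1, 60)
        labels = rng.integers(0, 2, 60)
        labels[0], labels[1] = 0, 1
        assert st.roc_auc(scores, labels) == pytest.approx(
            1.0 - st.roc_auc(scores, 1 - labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            st.roc_auc([1.0, 2.0], [1, 1])


class TestLogistic:
    def test_null_predictor_gives_chance_auc(self, rng):
        n = 2000
        y = rng.integers(0, 2, n)
        x = pd.DataFrame({"x": rng.normal(0, 1, n)})
        res = st.fit_logistic_auc(y, x)
        assert abs(res.coefficients["x"]) < 0.15
        assert abs(res.auc - 0.5) <= 0.03

    def test_binormal_auc_matches_closed_form(self, rng):
        n = 2000
        y = np.repeat([0, 1], n // 2)
        x = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(1, 1, n // 2)])
        res = st.fit_logistic_auc(y, pd.DataFrame({"x": x}))
        assert abs(res.auc - sps.norm.cdf(1 / np.sqrt(2))) <= 0.03

    def test_perfect_separation_flagged(self):
        y = np.array([0, 0, 0, 1, 1, 1] * 4)
        x = pd.DataFrame({"x": [0.0, 1, 2, 10, 11, 12] * 4})
        res = st.fit_logistic_auc(y, x)
        assert res.separation and res.auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            st.fit_logistic_auc(np.ones(20, int), pd.DataFrame({"x": np.arange(20.0)}))


class TestCox:
    def test_partial_likelihood_matches_grid_oracle(self):
        """Estimate matches an independent partial-likelihood maximization.

        Small staggered-event toy without ties, so the partial likelihood
        has a simple closed form that can be optimized independently.
        """
        df = pd.DataFrame({
            "os_months": [2.0, 4.0, 6.0, 8.0, 10.0, 12.0],
            "os_event": [1, 1, 0, 1, 1, 0],
            "x": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
        })

        def neg_log_pl(beta):
            order = np.argsort(df["os_months"].values)
            t = df["os_months"].values[order]
            e = df["os_event"].values[order]
            x = df["x"].values[order]
            ll = 0.0
            for i in range(len(t)):
                if not e[i]:
                    continue
                risk = x[i:]
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * risk)))
            return -ll

        from scipy.optimize import minimize_scalar

        beta_oracle = minimize_scalar(neg_log_pl, bounds=(-5, 5), method="bounded",
                                      options={"xatol": 1e-10}).x
        res = st.fit_cox(df, "OS", ["x"], min_events=1)
        assert res.summary.loc["x", "log_hr"] == pytest.approx(beta_oracle, abs=1e-4)

    def test_null_covariate_hazard_near_one(self):
        hrs = []
        for s in range(30):
            df = sd.gen_cohort(sd.CohortSpec(n_patients=500, sex_male_prev=0.5,
                                             censor_rate=0.3, seed=900 + s))
            res = st.fit_cox(df, "OS", ["sex_male"])
            hrs.append(res.summary.loc["sex_male", "hr"])
        assert 0.85 <= np.mean(hrs) <= 1.18

    def test_loghr_recovery(self):
        ests = []
        for s in range(30):
            df = sd.gen_cohort(sd.CohortSpec(n_patients=500, sex_male_prev=0.5,
                                             survival_loghr={"sex_male": 0.7},
                                             censor_rate=0.3, seed=700 + s))
            res = st.fit_cox(df, "OS", ["sex_male"])
            ests.append(res.summary.loc["sex_male", "log_hr"])
        assert abs(np.mean(ests) - 0.7) <= 0.07

    def test_zero_events_and_constant_covariate_rejected(self):
        df = pd.DataFrame({"os_months": [1.0, 2, 3, 4], "os_event": [0, 0, 0, 0],
                           "x": [1.0, 2, 3, 4]})
        with pytest.raises(ValidationError):
            st.fit_cox(df, "OS", ["x"])
        df["os_event"] = [1, 1, 1, 1]
        df["x"] = 1.0
        with pytest.raises(ValidationError):
            st.fit_cox(df, "OS", ["x"])


class TestFullAnalysis:
    def test_default_cohort_reports_nuclear_dominance(self):
        """Nuclear > cytoplasmic glandular CXCR3 is detected at cohort scale."""
        df = sd.gen_cohort(sd.CohortSpec(seed=5))
        tables = st.run_full_analysis(df)
        row = tables["paired"].query(
            "marker == 'CXCR3' and contrast == 'nucleus_vs_cytoplasm' and stratum == 'gland'"
        ).iloc[0]
        assert row["mean_a"] > row["mean_b"]
        assert row["p"] < 0.005

    def test_null_cohort_type_I_error_calibrated(self):
        levels = {k: (30.0, 10.0) for k in st.MARKER_COLUMNS}
        rej = 0
        reps = 200
        for s in range(reps):
            df = sd.gen_cohort(sd.CohortSpec(marker_levels=levels, seed=3000 + s))
            res = st.compare_paired(df["cxcr3_gland_nuc"], df["cxcr3_gland_cyt"])
            rej += res.p_value < 0.05
        assert 0.02 <= rej / reps <= 0.09

    def test_single_patient_cohort_flags_everything(self):
        df = sd.gen_cohort(sd.CohortSpec(seed=1)).iloc[:1]
        tables = st.run_full_analysis(df)
        assert tables["paired"]["flag"].str.startswith("insufficient").all()
        assert tables["cox"]["flag"].notna().all()

    def test_report_tables_complete(self):
        df = sd.gen_cohort(sd.CohortSpec(seed=9))
        tables = st.run_full_analysis(df)
        assert len(tables["paired"]) == 12
        assert len(tables["groups"]) == 60  # 5 dichotomies x 12 markers
        assert set(tables["cox"]["endpoint"]) == {"OS", "DFS"}
        for t in tables.values():
            assert "p" in t.columns

    def test_bh_adjustment_optional(self):
        df = sd.gen_cohort(sd.CohortSpec(seed=9))
        tables = st.run_full_analysis(df, st.StatsConfig(adjust=True))
        assert "p_adj" in tables["paired"].columns
        ok = tables["paired"]["p"].notna()
        assert (tables["paired"].loc[ok, "p_adj"] >= tables["paired"].loc[ok, "p"] - 1e-12).all()

    def test_missing_column_named(self):
        df = sd.gen_cohort(sd.CohortSpec(seed=2)).drop(columns=["os_months"])
        with pytest.raises(ValidationError, match="os_months"):
            st.run_full_analysis(df)
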