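"""Cohort-level statistics for compartment-resolved IHC marker scores.

Implements the analysis program applied to a patient table carrying the 12
marker measurements (3 chemokine receptors x {nucleus, cytoplasm} x
{glandular, interstitial}) plus clinicopathological covariates and survival
outcomes:

* paired nuclear-vs-cytoplasmic comparisons per marker and region,
* two-group comparisons across clinicopathological strata (differentiation,
  invasion, T stage T1-2 vs T3-4, nodal status N0 vs N>0, TNM early vs
  advanced),
* multivariable logistic regression with apparent (in-sample) ROC AUC,
* Cox proportional-hazards models of overall and disease-free survival.

Defaults follow robust small-cohort practice: Wilcoxon signed-rank for
paired and Mann-Whitney U for group comparisons (exact null distributions
at small n, normal approximation above n = 25), two-sided throughout, raw
p-values (optional Benjamini-Hochberg).  Survival models use only the six
glandular marker measurements as molecular covariates to limit the
covariate count relative to the event count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InsufficientDataError, ValidationError

MARKERS = ("CXCR3", "CXCR4", "CXCR7")
REGIONS = ("gland", "inter")
COMPARTMENTS = ("nuc", "cyt")

#: The 12 marker columns of a cohort table, e.g. ``cxcr3_gland_nuc``.
MARKER_COLUMNS = tuple(
    f"{m.lower()}_{r}_{c}" for m in MARKERS for r in REGIONS for c in COMPARTMENTS
)
GLANDULAR_MARKER_COLUMNS = tuple(c for c in MARKER_COLUMNS if "_gland_" in c)

CLINICAL_COLUMNS = (
    "patient_id", "sex", "age", "differentiation", "invasion",
    "t_score", "n_score", "tnm",
    "os_months", "os_event", "dfs_months", "dfs_event",
)

_EXACT_MAX_N = 25  # exact small-sample null distributions up to here


# ---------------------------------------------------------------------------
# staging categorizers

def categorize_t(t_score: int) -> str:
    """Dichotomize tumour extent: T1-2 vs T3-4."""
    if t_score not in (1, 2, 3, 4):
        raise ValidationError(f"t_score must be in {{1,2,3,4}}, got {t_score!r}")
    return "T1-2" if t_score <= 2 else "T3-4"


def categorize_n(n_score: int) -> str:
    """Nodal status: N = 0 (node_negative) vs N > 0 (node_positive)."""
    if not isinstance(n_score, (int, np.integer)) or n_score < 0:
        raise ValidationError(f"n_score must be a non-negative integer, got {n_score!r}")
    return "node_negative" if n_score == 0 else "node_positive"


def categorize_tnm(tnm: int) -> str:
    """Overall stage: early (TNM 0-2) vs advanced (TNM 3-4)."""
    if tnm not in (0, 1, 2, 3, 4):
        raise ValidationError(f"tnm must be in {{0..4}}, got {tnm!r}")
    return "early" if tnm <= 2 else "advanced"


# ---------------------------------------------------------------------------
# comparisons

@dataclass
class ComparisonResult:
    method: str
    n: int
    group_labels: Tuple[str, str]
    group_sizes: Tuple[int, int]
    statistic: float
    p_value: float
    estimates: Dict[str, float]
    flag: Optional[str] = None


def compare_paired(x, y, method: str = "wilcoxon") -> ComparisonResult:
    """Two-sided paired comparison of two per-patient measurements.

    ``wilcoxon`` uses the signed-rank test (zero differences dropped, exact
    null for n <= 25 without ties, else normal approximation); ``paired_t``
    is Student's paired t.  Pairs with a missing member are dropped first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired samples must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {n}")
    est = {"mean_x": float(x.mean()), "mean_y": float(y.mean())}
    d = x - y

    if method == "paired_t":
        if np.allclose(d.std(ddof=1), 0.0):
            # zero-variance differences: t is undefined, flag instead of dividing by 0
            return ComparisonResult(
                "paired_t", n, ("x", "y"), (n, n), math.nan, math.nan, est,
                flag="degenerate_zero_variance",
            )
        stat, p = sps.ttest_rel(x, y)
        return ComparisonResult("paired_t", n, ("x", "y"), (n, n), float(stat), float(p), est)

    if method != "wilcoxon":
        raise ValidationError(f"unknown paired method {method!r}")
    if np.all(d == 0):
        return ComparisonResult(
            "wilcoxon", n, ("x", "y"), (n, n), 0.0, 1.0, est, flag="degenerate_all_zero",
        )
    nz = d[d != 0]
    exact_ok = nz.size <= _EXACT_MAX_N and np.unique(np.abs(nz)).size == nz.size
    mode = "exact" if exact_ok else "approx"
    stat, p = sps.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided", method=mode)
    return ComparisonResult("wilcoxon", n, ("x", "y"), (n, n), float(stat), float(p), est)


def compare_groups(values, groups, method: str = "mann_whitney") -> ComparisonResult:
    """Two-sided two-group comparison of a marker across binary labels.

    ``mann_whitney`` uses the exact U null for group sizes <= 25 without
    ties, else the tie-corrected normal approximation; ``welch_t`` is the
    unequal-variance t test.  Group labels are ordered lexicographically.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok]
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) != 2:
        raise ValidationError(f"need exactly 2 groups, got {labels}")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if min(a.size, b.size) < 3:
        raise InsufficientDataError(f"both groups need >= 3 patients, got {a.size} and {b.size}")
    est = {f"mean_{labels[0]}": float(a.mean()), f"mean_{labels[1]}": float(b.mean()),
           f"median_{labels[0]}": float(np.median(a)), f"median_{labels[1]}": float(np.median(b))}
    sizes = (int(a.size), int(b.size))
    n = a.size + b.size

    if method == "welch_t":
        stat, p = sps.ttest_ind(a, b, equal_var=False)
        return ComparisonResult("welch_t", n, (str(labels[0]), str(labels[1])), sizes,
                                float(stat), float(p), est)
    if method != "mann_whitney":
        raise ValidationError(f"unknown group method {method!r}")
    pooled = np.concatenate([a, b])
    exact_ok = max(sizes) <= _EXACT_MAX_N and np.unique(pooled).size == pooled.size
    mode = "exact" if exact_ok else "asymptotic"
    stat, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=mode)
    return ComparisonResult("mann_whitney", n, (str(labels[0]), str(labels[1])), sizes,
                            float(stat), float(p), est)


# ---------------------------------------------------------------------------
# ROC / logistic

def roc_auc(scores, labels) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) identity.

    AUC = (concordant pairs + 0.5 * tied pairs) / (n_pos * n_neg): the
    probability that a random positive outranks a random negative.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both outcome classes must be present")
    ranks = sps.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class LogisticResult:
    outcome: str
    coefficients: pd.Series  # includes "const"
    p_values: pd.Series
    auc: float
    n: int
    separation: bool = False
    flag: Optional[str] = None


def fit_logistic_auc(outcome, predictors: pd.DataFrame, outcome_label: str = "outcome") -> LogisticResult:
    """Maximum-likelihood logistic fit with apparent ROC AUC.

    Complete separation is detected (perfect in-sample prediction or
    unbounded coefficients) and flagged rather than silently diverging;
    the AUC — which is well defined even under separation — is still
    reported from the fitted scores.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

    y = np.asarray(outcome).astype(int)
    X = pd.DataFrame(predictors).astype(float)
    keep = ~(X.isna().any(axis=1) | pd.isna(y))
    X, y = X.loc[keep.values], y[keep.values]
    n = int(y.size)
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome has a single class")
    if n <= X.shape[1] + 1:
        raise InsufficientDataError("need n > #predictors + 1")
    Xc = sm.add_constant(X, has_constant="add")
    separation = False
    flag = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        params, pvals = fit.params, fit.pvalues
        score = np.asarray(fit.predict(Xc))
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        # refit leniently just to obtain a ranking score for the AUC
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=50, method="bfgs")
        params, pvals = fit.params, fit.pvalues
        score = np.asarray(fit.predict(Xc))
        separation = True
        flag = "perfect_separation"
    if not separation and np.abs(params.drop("const")).max() > 1e2 and (
        np.all((score > 0.5) == (y == 1))
    ):
        separation, flag = True, "perfect_separation"
    return LogisticResult(
        outcome=outcome_label,
        coefficients=params,
        p_values=pvals,
        auc=roc_auc(score, y),
        n=n,
        separation=separation,
        flag=flag,
    )


# ---------------------------------------------------------------------------
# survival

@dataclass
class CoxResult:
    endpoint: str  # "OS" | "DFS"
    summary: pd.DataFrame  # index: covariate; columns: log_hr, hr, ci_low, ci_high, p
    n: int
    n_events: int


def fit_cox(df: pd.DataFrame, endpoint: str, covariates: Sequence[str],
            min_events: int = 10) -> CoxResult:
    """Multivariable Cox proportional-hazards fit (Efron tie handling).

    ``endpoint`` selects the ``os_months``/``os_event`` or
    ``dfs_months``/``dfs_event`` column pair.  Confidence intervals are
    Wald intervals on the log hazard ratio.  ``min_events`` guards against
    uninterpretable fits on tiny risk sets; lower it only for toy inputs.
    """
    from lifelines import CoxPHFitter

    endpoint = endpoint.upper()
    if endpoint not in ("OS", "DFS"):
        raise ValidationError(f"endpoint must be OS or DFS, got {endpoint!r}")
    dur, evt = (("os_months", "os_event") if endpoint == "OS" else ("dfs_months", "dfs_event"))
    cols = list(covariates) + [dur, evt]
    if any(c not in df.columns for c in covariates):
        # derive staging/sex indicator covariates from the clinical columns
        try:
            design = survival_design(df)
        except (KeyError, ValidationError):
            design = pd.DataFrame(index=df.index)
        derived = [c for c in covariates if c not in df.columns and c in design.columns]
        if derived:
            df = pd.concat([df, design[derived]], axis=1)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"missing column {missing[0]!r}")
    data = df[cols].dropna()
    n_events = int(data[evt].sum())
    if n_events == 0:
        raise ValidationError("no events observed")
    for c in covariates:
        if data[c].nunique() < 2:
            raise ValidationError(f"covariate {c!r} is constant")
    if n_events < min_events:
        raise InsufficientDataError(f"need >= {min_events} events, got {n_events}")
    cph = CoxPHFitter()
    cph.fit(data, duration_col=dur, event_col=evt)
    s = cph.summary
    out = pd.DataFrame(
        {
            "log_hr": s["coef"],
            "hr": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    return CoxResult(endpoint=endpoint, summary=out, n=int(len(data)), n_events=n_events)


# ---------------------------------------------------------------------------
# full analysis

@dataclass(frozen=True)
class StatsConfig:
    paired_method: str = "wilcoxon"
    group_method: str = "mann_whitney"
    adjust: bool = False  # Benjamini-Hochberg within each report table


def survival_design(df: pd.DataFrame) -> pd.DataFrame:
    """Numeric design columns shared by the simulator and the survival models.

    Adds ``sex_male``, ``t_stage_34``, ``n_positive``, ``tnm_advanced``
    indicator columns alongside the raw marker percentages.
    """
    out = pd.DataFrame(index=df.index)
    out["sex_male"] = (df["sex"].astype(str).str.upper() == "M").astype(float)
    out["t_stage_34"] = df["t_score"].map(lambda t: float(categorize_t(int(t)) == "T3-4"))
    out["n_positive"] = df["n_score"].map(lambda v: float(categorize_n(int(v)) == "node_positive"))
    out["tnm_advanced"] = df["tnm"].map(lambda v: float(categorize_tnm(int(v)) == "advanced"))
    for col in MARKER_COLUMNS:
        if col in df.columns:
            out[col] = df[col].astype(float)
    return out


def validate_cohort(df: pd.DataFrame) -> None:
    """Schema check; raises :class:`ValidationError` naming the first missing column."""
    for col in CLINICAL_COLUMNS + MARKER_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"cohort table is missing required column '{col}'")


def _bh_adjust(p: pd.Series) -> pd.Series:
    from statsmodels.stats.multitest import multipletests

    mask = p.notna()
    out = pd.Series(np.nan, index=p.index)
    if mask.sum():
        out.loc[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def _grouping_labels(df: pd.DataFrame) -> Dict[str, pd.Series]:
    """The five clinicopathological dichotomies analysed.

    Differentiation and invasion scores are split at the cohort median
    (value > median = high); stage scores use their fixed cut-points.
    """
    out: Dict[str, pd.Series] = {}
    for name, col in (("differentiation", "differentiation"), ("invasion", "invasion")):
        med = df[col].median()
        out[name] = df[col].map(lambda v, m=med: "high" if v > m else "low")
    out["t_stage"] = df["t_score"].map(lambda v: categorize_t(int(v)))
    out["n_stage"] = df["n_score"].map(lambda v: categorize_n(int(v)))
    out["tnm_stage"] = df["tnm"].map(lambda v: categorize_tnm(int(v)))
    return out


def run_full_analysis(cohort: pd.DataFrame, config: Optional[StatsConfig] = None) -> Dict[str, pd.DataFrame]:
    """Run the whole statistical program on a validated cohort table.

    Returns four tables: ``paired`` (12 nuclear-vs-cytoplasmic tests),
    ``groups`` (5 dichotomies x 12 markers), ``logistic`` (per-dichotomy
    multivariable fit on the six glandular markers, with apparent AUC), and
    ``cox`` (OS and DFS models with sex, T, N and glandular markers).
    Per-analysis failures are recorded as flags, never abort the rest.
    """
    cfg = config or StatsConfig()
    validate_cohort(cohort)
    df = cohort.reset_index(drop=True)

    # 12 paired contrasts: nucleus vs cytoplasm within each marker x region,
    # and glandular vs interstitial within each marker x compartment
    contrasts = []
    for m in MARKERS:
        for r in REGIONS:
            contrasts.append((m, "nucleus_vs_cytoplasm", r,
                              f"{m.lower()}_{r}_nuc", f"{m.lower()}_{r}_cyt"))
        for c in COMPARTMENTS:
            contrasts.append((m, "glandular_vs_interstitial", c,
                              f"{m.lower()}_gland_{c}", f"{m.lower()}_inter_{c}"))
    paired_rows = []
    for m, contrast, stratum, col_a, col_b in contrasts:
        row = {"marker": m, "contrast": contrast, "stratum": stratum}
        try:
            res = compare_paired(df[col_a], df[col_b], method=cfg.paired_method)
            row.update(n=res.n, mean_a=res.estimates["mean_x"],
                       mean_b=res.estimates["mean_y"], statistic=res.statistic,
                       p=res.p_value, flag=res.flag)
        except InsufficientDataError as e:
            row.update(n=len(df), mean_a=np.nan, mean_b=np.nan,
                       statistic=np.nan, p=np.nan, flag=f"insufficient_data: {e}")
        paired_rows.append(row)
    paired = pd.DataFrame(paired_rows)

    groupings = _grouping_labels(df)
    group_rows = []
    for gname, glabels in groupings.items():
        for col in MARKER_COLUMNS:
            row = {"grouping": gname, "marker": col}
            try:
                res = compare_groups(df[col], glabels, method=cfg.group_method)
                row.update(n=res.n, group_a=res.group_labels[0], group_b=res.group_labels[1],
                           n_a=res.group_sizes[0], n_b=res.group_sizes[1],
                           statistic=res.statistic, p=res.p_value, flag=res.flag)
            except (InsufficientDataError, ValidationError) as e:
                row.update(n=len(df), group_a="", group_b="", n_a=0, n_b=0,
                           statistic=np.nan, p=np.nan, flag=f"insufficient_data: {e}")
            group_rows.append(row)
    groups = pd.DataFrame(group_rows)

    logit_rows = []
    predictors = df[list(GLANDULAR_MARKER_COLUMNS)]
    for gname, glabels in groupings.items():
        positive = sorted(glabels.unique())[-1] if glabels.nunique() == 2 else None
        try:
            if positive is None:
                raise ValidationError("outcome has a single class")
            y = (glabels == positive).astype(int)
            res = fit_logistic_auc(y, predictors, outcome_label=gname)
            for name in res.coefficients.index:
                if name == "const":
                    continue
                logit_rows.append({
                    "outcome": gname, "predictor": name,
                    "coef": res.coefficients[name], "p": res.p_values[name],
                    "auc": res.auc, "n": res.n, "flag": res.flag,
                })
        except (InsufficientDataError, ValidationError) as e:
            logit_rows.append({"outcome": gname, "predictor": "", "coef": np.nan,
                               "p": np.nan, "auc": np.nan, "n": len(df),
                               "flag": f"insufficient_data: {e}"})
    logistic = pd.DataFrame(logit_rows)

    cox_rows = []
    design = None
    try:
        design = survival_design(df)
    except (ValidationError, ValueError) as e:  # bad staging codes
        cox_rows.append({"endpoint": "", "covariate": "", "log_hr": np.nan, "hr": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                         "n": len(df), "n_events": 0, "flag": f"invalid_staging: {e}"})
    if design is not None:
        cox_covs = ["sex_male", "t_stage_34", "n_positive"] + list(GLANDULAR_MARKER_COLUMNS)
        surv = pd.concat(
            [design[cox_covs],
             df[["os_months", "os_event", "dfs_months", "dfs_event"]]], axis=1)
        for endpoint in ("OS", "DFS"):
            try:
                res = fit_cox(surv, endpoint, cox_covs)
                for cov, row in res.summary.iterrows():
                    cox_rows.append({"endpoint": endpoint, "covariate": cov,
                                     "log_hr": row["log_hr"], "hr": row["hr"],
                                     "ci_low": row["ci_low"], "ci_high": row["ci_high"],
                                     "p": row["p"], "n": res.n, "n_events": res.n_events,
                                     "flag": None})
            except (InsufficientDataError, ValidationError) as e:
                cox_rows.append({"endpoint": endpoint, "covariate": "", "log_hr": np.nan,
                                 "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                                 "p": np.nan, "n": len(df), "n_events": 0,
                                 "flag": f"insufficient_data: {e}"})
    cox = pd.DataFrame(cox_rows)

    if cfg.adjust:
        for table in (paired, groups, logistic, cox):
            if "p" in table.columns and len(table):
                table["p_adj"] = _bh_adjust(table["p"])

    return {"paired": paired, "groups": groups, "logistic": logistic, "cox": cox}
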