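"""Survival estimation and immunotherapy-response scoring.

Kaplan-Meier curves, log-rank tests and Cox proportional-hazards fits go
through lifelines (Efron tie handling, Newton-Raphson). On top sit the
analysis-specific reports: Mann-Whitney/DeLong ROC AUC, the logistic
combination of TMB with the TMEscore compared by likelihood ratio, the
cell-type prognostic network (Spearman co-infiltration + per-cell Cox), and
the single-gene association report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .containers import ExpressionMatrix, FractionTable
from .signature import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "SurvFit",
    "km_fit",
    "logrank_test",
    "cox_fit",
    "roc_auc",
    "combine_tmb_score",
    "cell_prognostic_network",
    "gene_report",
]


@dataclass
class SurvFit:
    """Survival-fit bundle: per-group KM curves and/or Cox coefficients."""

    curves: dict = field(default_factory=dict)  # group -> DataFrame(time, survival, ci)
    at_risk: dict = field(default_factory=dict)  # group -> DataFrame(time, n_at_risk)
    logrank_stat: float = np.nan
    logrank_df: int = 0
    logrank_p: float = np.nan
    coefficients: pd.DataFrame | None = None  # beta, HR, CI95, p per covariate


def _check_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if (t < 0).any():
        raise ValueError("negative survival times")
    return t


def km_fit(times, events, groups=None) -> SurvFit:
    """Product-limit survival estimates per group with Greenwood CIs.

    With >= 2 groups the log-rank comparison is attached.
    """
    t = _check_times(times)
    e = np.asarray(events, dtype=int)
    g = np.asarray(["all"] * len(t)) if groups is None else np.asarray(groups)
    fit = SurvFit()
    for lev in pd.unique(g):
        mask = g == lev
        if mask.sum() < 2:
            raise ValueError(f"group {lev!r} has < 2 samples")
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask], label=str(lev))
        curve = kmf.survival_function_.copy()
        curve.columns = ["survival"]
        ci = kmf.confidence_interval_
        curve["ci_lower"] = ci.iloc[:, 0].to_numpy()
        curve["ci_upper"] = ci.iloc[:, 1].to_numpy()
        fit.curves[lev] = curve.reset_index().rename(columns={"timeline": "time"})
        fit.at_risk[lev] = kmf.event_table["at_risk"].reset_index()
    if len(fit.curves) >= 2:
        stat, df, p = logrank_test(t, e, g)
        fit.logrank_stat, fit.logrank_df, fit.logrank_p = stat, df, p
    return fit


def logrank_test(times, events, groups) -> tuple[float, int, float]:
    """K-group log-rank test; returns (chi-square, df, p)."""
    t = _check_times(times)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("log-rank needs at least 2 groups")
    if e.sum() < 1:
        raise ValueError("log-rank needs at least 1 event")
    res = multivariate_logrank_test(t, g, e)
    df = len(levels) - 1
    return float(res.test_statistic), df, float(res.p_value)


def cox_fit(covariates: pd.DataFrame, times, events, min_events: int = 10) -> SurvFit:
    """Cox proportional-hazards fit (Efron ties, Newton-Raphson).

    ``covariates`` holds numeric (or already-encoded) columns. Returns
    per-covariate beta, HR, 95% Wald CI and p. Non-convergence surfaces as a
    lifelines ConvergenceError with diagnostics.
    """
    t = _check_times(times)
    e = np.asarray(events, dtype=int)
    if e.sum() < min_events:
        raise ValueError(f"need >= {min_events} events, got {int(e.sum())}")
    x = pd.DataFrame(covariates).reset_index(drop=True)
    const = [c for c in x.columns if x[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    df = x.copy()
    df["T"], df["E"] = t, e
    cph = CoxPHFitter()
    cph.fit(df, duration_col="T", event_col="E", fit_options={"precision": 1e-9})
    summ = cph.summary
    coeffs = pd.DataFrame(
        {
            "beta": summ["coef"],
            "HR": summ["exp(coef)"],
            "ci_lower": np.exp(summ["coef lower 95%"]),
            "ci_upper": np.exp(summ["coef upper 95%"]),
            "se": summ["se(coef)"],
            "p": summ["p"],
        }
    )
    return SurvFit(coefficients=coeffs)


def roc_auc(score, outcome) -> dict:
    """Mann-Whitney AUC (ties get 0.5 credit) with a DeLong-style CI."""
    s = np.asarray(score, dtype=float)
    y = np.asarray(outcome, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    if not len(pos) or not len(neg):
        raise ValueError("both outcome classes must be present")
    # placement values (midranks), DeLong 1988
    def placement_counts(a, b):
        out = np.empty(len(a))
        for i, v in enumerate(a):
            out[i] = np.sum(v > b) + 0.5 * np.sum(v == b)
        return out

    counts10 = placement_counts(pos, neg)
    # single division of the exact half-integer pair count: agrees bitwise
    # with direct concordant-pair enumeration
    auc = float(counts10.sum() / (len(pos) * len(neg)))
    v10 = counts10 / len(neg)  # per-positive placement
    v01 = placement_counts(neg, pos) / len(pos)  # per-negative placement
    s10 = v10.var(ddof=1) if len(pos) > 1 else 0.0
    s01 = v01.var(ddof=1) if len(neg) > 1 else 0.0
    var = s10 / len(pos) + s01 / len(neg)
    se = float(np.sqrt(var))
    zcrit = stats.norm.ppf(0.975)
    return {
        "auc": auc,
        "se": se,
        "ci_lower": max(0.0, auc - zcrit * se),
        "ci_upper": min(1.0, auc + zcrit * se),
    }


def _fit_logit(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Logistic fit returning (params incl. intercept, log-likelihood,
    penalized flag); falls back to a mild L2 ridge under (quasi-)separation."""
    X = sm.add_constant(x, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params = np.asarray(res.params, dtype=float)
        if not np.all(np.isfinite(params)) or np.abs(params).max() > 50:
            raise np.linalg.LinAlgError("separation")
        return params, float(res.llf), False
    except Exception:  # perfect/quasi separation: small-ridge refit
        logger.warning("logistic separation detected; using L2-penalized fit")
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=100.0, solver="lbfgs", max_iter=1000).fit(x, y)
        params = np.concatenate([lr.intercept_, lr.coef_.ravel()])
        eta = X @ params
        llf = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        return params, llf, True


def combine_tmb_score(tmb, tmescore, outcome) -> dict:
    """Compare TMB, TMEscore and their logistic combination for predicting
    responder status (CR/PR = 1 vs SD/PD = 0).

    The combined score is the linear predictor of the two-covariate logistic
    model fit in-sample; the likelihood-ratio test compares the nested
    one-covariate (TMB) and two-covariate models on 1 df.
    """
    df = pd.DataFrame(
        {
            "tmb": np.asarray(tmb, dtype=float),
            "score": np.asarray(tmescore, dtype=float),
            "y": np.asarray(outcome, dtype=int),
        }
    ).dropna()
    if len(df) < 20:
        raise ValueError(f"need >= 20 complete cases, got {len(df)}")
    y = df["y"].to_numpy()
    z = lambda v: (v - v.mean()) / (v.std(ddof=1) or 1.0)
    x1 = z(df["tmb"].to_numpy())
    x2 = z(df["score"].to_numpy())

    params_tmb, llf_tmb, _ = _fit_logit(x1[:, None], y)
    _params_s, llf_score, _ = _fit_logit(x2[:, None], y)
    params_both, llf_both, penalized = _fit_logit(np.column_stack([x1, x2]), y)
    combined = params_both[0] + params_both[1] * x1 + params_both[2] * x2

    lr = max(2.0 * (llf_both - llf_tmb), 0.0)
    lr_p = float(stats.chi2.sf(lr, df=1))
    return {
        "auc_tmb": roc_auc(x1, y)["auc"],
        "auc_score": roc_auc(x2, y)["auc"],
        "auc_combined": roc_auc(combined, y)["auc"],
        "llf_tmb": llf_tmb,
        "llf_score": llf_score,
        "llf_combined": llf_both,
        "lr_stat": float(lr),
        "lr_p": lr_p,
        "penalized": penalized,
        "n": int(len(df)),
    }


def cell_prognostic_network(fr: FractionTable, clinical: pd.DataFrame) -> dict:
    """Spearman co-infiltration network plus per-cell-type prognostic flags.

    Returns rho/p matrices among cell types, a per-cell-type table with the
    univariate Cox HR on the fraction and its p (flag 'favorable' iff
    HR < 1), and a tidy edge list for plotting. Constant fraction columns
    yield missing correlations.
    """
    clin = clinical.set_index("sample_id")
    shared = fr.fractions.index.intersection(clin.index)
    if not len(shared):
        raise ValueError("no shared samples between fractions and clinical table")
    fx = fr.fractions.loc[shared]
    times = clin.loc[shared, "os_time"].to_numpy(dtype=float)
    events = clin.loc[shared, "os_event"].to_numpy(dtype=int)

    cols = list(fx.columns)
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pmat = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = fx.iloc[:, i], fx.iloc[:, j]
            if a.std() == 0 or b.std() == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(a, b)
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pmat.iloc[i, j] = pmat.iloc[j, i] = p

    prog_rows = []
    for c in cols:
        if fx[c].std() == 0:
            prog_rows.append((c, np.nan, np.nan, np.nan, "undefined"))
            continue
        fit = cox_fit(fx[[c]], times, events, min_events=1)
        row = fit.coefficients.iloc[0]
        prog_rows.append(
            (c, row["beta"], row["HR"], row["p"], "favorable" if row["HR"] < 1 else "risk")
        )
    prognostic = pd.DataFrame(
        prog_rows, columns=["cell_type", "beta", "HR", "p", "flag"]
    ).set_index("cell_type")

    edges = []
    for i in range(k):
        for j in range(i + 1, k):
            edges.append((cols[i], cols[j], rho.iloc[i, j], pmat.iloc[i, j]))
    edge_list = pd.DataFrame(edges, columns=["a", "b", "rho", "p"])
    return {"rho": rho, "p": pmat, "prognostic": prognostic, "edges": edge_list}


def gene_report(
    m: ExpressionMatrix,
    gene_id: str,
    fr: FractionTable | None,
    clinical: pd.DataFrame,
) -> dict:
    """Single-gene association report (expression vs clinic, fractions,
    survival), with BH adjustment applied within the report.

    * Wilcoxon rank-sum of expression across each available binary clinical
      contrast (er/pr/her2 pos-vs-neg; exact p at small n);
    * Spearman correlation of the gene with every cell-type fraction;
    * Kaplan-Meier + log-rank for the median split of expression.
    """
    if gene_id not in m.gene_ids:
        import difflib

        near = difflib.get_close_matches(
            str(gene_id).upper(), [str(g).upper() for g in m.gene_ids], n=5, cutoff=0.6
        )
        raise KeyError(f"gene {gene_id!r} not found; nearest ids: {near}")
    clin = clinical.set_index("sample_id")
    shared = m.sample_ids.intersection(clin.index)
    expr = m.values.loc[gene_id, shared].astype(float)

    contrasts = []
    for col in ("er", "pr", "her2"):
        if col not in clin.columns:
            continue
        status = clin.loc[shared, col]
        a = expr[(status == "pos").to_numpy()]
        b = expr[(status == "neg").to_numpy()]
        if len(a) < 2 or len(b) < 2:
            continue
        method = "exact" if max(len(a), len(b)) <= 25 and len(np.unique(expr)) == len(expr) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        contrasts.append((col, float(a.median() - b.median()), float(res.pvalue)))
    wilcoxon = pd.DataFrame(contrasts, columns=["contrast", "median_diff", "p"])

    corr_rows = []
    if fr is not None:
        fx = fr.fractions.loc[fr.fractions.index.intersection(shared)]
        ex = expr.loc[fx.index]
        for c in fx.columns:
            if fx[c].std() == 0:
                corr_rows.append((c, np.nan, np.nan))
            else:
                r, p = stats.spearmanr(ex, fx[c])
                corr_rows.append((c, float(r), float(p)))
    correlations = pd.DataFrame(corr_rows, columns=["cell_type", "rho", "p"])

    times = clin.loc[shared, "os_time"].to_numpy(dtype=float)
    events = clin.loc[shared, "os_event"].to_numpy(dtype=int)
    high = (expr > expr.median()).to_numpy()
    groups = np.where(high, "high", "low")
    stat, dfree, km_p = logrank_test(times, events, groups)
    km = km_fit(times, events, groups)

    all_p = np.concatenate(
        [
            wilcoxon["p"].to_numpy(dtype=float),
            correlations["p"].to_numpy(dtype=float) if len(correlations) else [],
            [km_p],
        ]
    )
    finite = np.isfinite(all_p)
    q = np.full(all_p.shape, np.nan)
    if finite.any():
        q[finite] = bh_adjust(all_p[finite])
    ofs = 0
    wilcoxon["q"] = q[ofs : ofs + len(wilcoxon)]
    ofs += len(wilcoxon)
    correlations["q"] = q[ofs : ofs + len(correlations)]
    ofs += len(correlations)

    return {
        "gene": gene_id,
        "wilcoxon": wilcoxon,
        "fraction_correlations": correlations,
        "km": km,
        "logrank": {"statistic": stat, "df": dfree, "p": km_p, "q": float(q[-1])},
    }
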