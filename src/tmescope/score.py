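"""Per-sample TMEscore: PCA component sums per gene module, signed by
univariate Cox coefficients, dichotomized by maximally selected rank
statistics.

TMEscore = sum over positive-Cox modules of (PC1 + PC2) minus the same sum
over negative-Cox modules. PCA is computed within each gene module; the sign
of each principal component is fixed so that it correlates non-negatively
with the module's mean expression profile (falling back to a positive
loading sum when that correlation is degenerate), which makes scores
reproducible across linear-algebra backends.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .containers import ExpressionMatrix, GeneModuleSet

logger = logging.getLogger(__name__)

__all__ = [
    "module_pc_scores",
    "assign_cox_signs",
    "compute_tmescore",
    "maxstat_cutpoint",
    "logrank_z",
]


def module_pc_scores(m_z: ExpressionMatrix, genes) -> pd.Series:
    """PC1 + PC2 projection score per sample for one gene module.

    ``m_z`` must hold z-scored expression. Samples are observations, the
    module's genes variables; beyond the per-gene z-score only the per-gene
    mean (numerically ~0) is removed. A 1-gene module falls back to the
    z-scored gene itself (logged); a rank-1 module contributes PC1 only.
    """
    genes = list(genes)
    if m_z.n_samples < 3:
        raise ValueError("need at least 3 samples for PCA")
    if len(genes) < 2:
        logger.info("1-gene module: using the z-scored gene as its score")
        return m_z.values.loc[genes[0]].astype(float).rename("component")
    block = m_z.values.loc[genes].to_numpy(dtype=float)  # genes x samples
    x = block.T - block.mean(axis=1)  # samples x genes, gene means removed
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    mean_profile = block.mean(axis=0)  # per-sample module mean expression
    if mean_profile.std() < 1e-12 and len(genes) > 1:
        # perfectly self-cancelling module (e.g. an exactly anti-correlated
        # pair): no orientation against the mean exists, so the module's
        # component score is defined as 0 rather than an arbitrary sign
        logger.warning(
            "module mean profile is constant; component score set to 0 for "
            "%d-gene module",
            len(genes),
        )
        return pd.Series(0.0, index=m_z.sample_ids, name="component")

    total = np.zeros(x.shape[0])
    for comp in range(min(2, s.size)):
        if s[comp] <= 1e-10 * s[0]:
            continue  # degenerate component contributes 0 by convention
        score = u[:, comp] * s[comp]
        if mean_profile.std() > 0 and score.std() > 0:
            r = np.corrcoef(score, mean_profile)[0, 1]
        else:
            r = 0.0
        if abs(r) < 1e-12:
            # orientation undefined against the mean profile (e.g. perfectly
            # anti-correlated gene pair): fall back to positive loading sum
            logger.info(
                "PC%d orientation tie for %d-gene module; using loading-sum rule",
                comp + 1,
                len(genes),
            )
            if vt[comp].sum() < 0:
                score = -score
        elif r < 0:
            score = -score
        total = total + score
    return pd.Series(total, index=m_z.sample_ids, name="component")


def assign_cox_signs(
    components: pd.DataFrame,
    times,
    events,
    modules: GeneModuleSet | None = None,
    min_events: int = 10,
) -> GeneModuleSet:
    """Sign each module by its univariate Cox log-hazard on the component score.

    ``components`` is samples x modules. Refuses |beta| < 1e-8 (no defensible
    sign); warns when the Wald p exceeds 0.5 (sign likely unstable).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if e.sum() == 0:
        raise ValueError("no events: cannot fit Cox model")
    if e.sum() < min_events:
        raise ValueError(f"need >= {min_events} events, got {int(e.sum())}")
    out = modules if modules is not None else GeneModuleSet(
        modules={c: [c] for c in components.columns}
    )
    betas, signs = {}, {}
    for col in components.columns:
        df = pd.DataFrame({"T": t, "E": e, "x": components[col].to_numpy(dtype=float)})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E", fit_options={"precision": 1e-9})
        beta = float(cph.params_["x"])
        pval = float(cph.summary.loc["x", "p"])
        if abs(beta) < 1e-8:
            raise ValueError(
                f"module {col!r} has |beta| < 1e-8; assign its sign manually"
            )
        if pval > 0.5:
            logger.warning(
                "module %s sign is unstable (Wald p=%.2f); interpret with care",
                col,
                pval,
            )
        betas[col] = beta
        signs[col] = 1 if beta > 0 else -1
    return GeneModuleSet(modules=dict(out.modules), betas=betas, signs=signs)


def compute_tmescore(components: pd.DataFrame, modules: GeneModuleSet) -> pd.DataFrame:
    """Combine per-module component scores into the TMEscore table.

    tmescore_pos sums modules with sign +1, tmescore_neg those with sign -1,
    and tmescore = tmescore_pos - tmescore_neg.
    """
    missing = [c for c in components.columns if c not in modules.signs]
    if missing:
        raise ValueError(f"modules without a Cox sign: {missing}")
    pos_cols = [c for c in components.columns if modules.signs[c] == 1]
    neg_cols = [c for c in components.columns if modules.signs[c] == -1]
    out = components.copy()
    out["tmescore_pos"] = components[pos_cols].sum(axis=1) if pos_cols else 0.0
    out["tmescore_neg"] = components[neg_cols].sum(axis=1) if neg_cols else 0.0
    out["tmescore"] = out["tmescore_pos"] - out["tmescore_neg"]
    return out


class _LogrankEngine:
    """Precomputed risk-set bookkeeping for repeated two-group log-rank
    evaluations on a fixed (times, events) sample — the inner loop of the
    maximally selected statistic."""

    def __init__(self, times, events):
        t = np.asarray(times, dtype=float)
        e = np.asarray(events, dtype=int)
        self.order = np.argsort(t, kind="stable")
        self.t = t[self.order]
        self.e = e[self.order].astype(bool)
        self.n = len(t)
        ev_times = self.t[self.e]
        self.uniq_times, self.boundaries = np.unique(ev_times, return_index=True)
        self.d = np.diff(np.append(self.boundaries, ev_times.size)).astype(float)
        self.start_idx = np.searchsorted(self.t, self.uniq_times, side="left")
        self.n_tot = (self.n - self.start_idx).astype(float)

    def z_sorted(self, g_sorted: np.ndarray) -> float:
        """Standardized (O - E)/sqrt(V) for a group mask in time order."""
        if not self.uniq_times.size:
            return 0.0
        suffix = np.concatenate([np.cumsum(g_sorted[::-1])[::-1], [0]])
        n1 = suffix[self.start_idx].astype(float)
        d1 = np.add.reduceat(g_sorted[self.e].astype(float), self.boundaries)
        frac = n1 / self.n_tot
        obs = d1.sum()
        exp = (self.d * frac).sum()
        ok = self.n_tot > 1
        var = (
            self.d[ok]
            * frac[ok]
            * (1 - frac[ok])
            * (self.n_tot[ok] - self.d[ok])
            / (self.n_tot[ok] - 1)
        ).sum()
        if var <= 0:
            return 0.0
        return float((obs - exp) / np.sqrt(var))

    def z(self, in_group) -> float:
        g = np.asarray(in_group, dtype=bool)[self.order]
        return self.z_sorted(g)


def logrank_z(times, events, in_group) -> float:
    """Standardized two-group log-rank statistic (O - E)/sqrt(V) for the
    ``in_group`` mask, with hypergeometric variance at tied event times."""
    return _LogrankEngine(times, events).z(in_group)


def _lausen_p(b: float, eps_low: float, eps_high: float) -> float:
    """Improved-Bonferroni bound for the maximally selected log-rank
    statistic over the quantile band (eps_low, eps_high):

        p ~ phi(b) * (b - 1/b) * log(eps_high (1 - eps_low) /
                                     ((1 - eps_high) eps_low)) + 4 phi(b) / b

    (Ornstein-Uhlenbeck crossing approximation for the maximum of the
    standardized statistic process)."""
    if b <= 1.0:
        return 1.0
    phi = stats.norm.pdf(b)
    span = np.log(eps_high * (1 - eps_low) / ((1 - eps_high) * eps_low))
    p = phi * (b - 1.0 / b) * span + 4.0 * phi / b
    return float(min(1.0, max(0.0, p)))


def maxstat_cutpoint(
    score,
    times,
    events,
    quantile_window: tuple = (0.1, 0.9),
    n_perm: int = 0,
    seed: int = 0,
    min_inside: int = 10,
    min_events: int = 5,
):
    """Maximally selected rank-statistic cutpoint for a continuous score.

    Candidates are the observed score values strictly inside the quantile
    window; each induces a two-group split (score > cut) evaluated by the
    standardized log-rank statistic. The cut maximizing |statistic| wins
    (ties to the lower cut). Significance: improved-Bonferroni bound, plus a
    permutation p when ``n_perm`` > 0.

    Returns dict with cutpoint, groups ('high'/'low' per sample), statistic,
    p, and perm_p (NaN unless requested).
    """
    s = pd.Series(score).astype(float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if s.nunique() < 2:
        raise ValueError("all scores identical: no cutpoint exists")
    if e.sum() < min_events:
        raise ValueError(f"need >= {min_events} events")
    lo, hi = np.quantile(s, quantile_window)
    vals = np.sort(s.unique())
    candidates = vals[(vals >= lo) & (vals <= hi)]
    candidates = candidates[candidates < vals.max()]  # a split needs both sides
    if len(candidates) == 0:
        # fewer distinct values than the window resolves: split between the two
        candidates = vals[:-1]
    inside = ((s.to_numpy() >= lo) & (s.to_numpy() <= hi)).sum()
    if inside < min_inside:
        raise ValueError(f"only {inside} samples inside the quantile window")

    engine = _LogrankEngine(t, e)

    def best_cut(scores: np.ndarray) -> tuple[float, float]:
        scores_sorted = scores[engine.order]
        zbest, cbest = -np.inf, None
        for c in candidates:
            z = abs(engine.z_sorted(scores_sorted > c))
            if z > zbest + 1e-12:
                zbest, cbest = z, c
        return cbest, zbest

    arr = s.to_numpy()
    cut, zmax = best_cut(arr)
    p = _lausen_p(zmax, *quantile_window)

    perm_p = np.nan
    if n_perm:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            _c, zp = best_cut(rng.permutation(arr))
            if zp >= zmax:
                hits += 1
        perm_p = (hits + 1.0) / (n_perm + 1.0)

    groups = pd.Series(np.where(arr > cut, "high", "low"), index=s.index, name="group")
    return {
        "cutpoint": float(cut),
        "groups": groups,
        "statistic": float(zmax),
        "p": p,
        "perm_p": perm_p,
    }
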