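"""Expression normalization: TPM scaling, gene z-scores, batch correction.

Batch correction follows the parametric empirical-Bayes location/scale
model popularized for merged expression cohorts: per gene, standardize by
the pooled mean and variance, estimate per-batch location (gamma) and scale
(delta), shrink both toward cross-gene priors (normal for gamma,
inverse-gamma for delta), remove them, and restore the pooled moments.
Covariates are not supported; the merged-cohort use case passes none.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import DegenerateSampleError, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["fpkm_to_tpm", "zscore_genes", "correct_batches", "zscore_frame"]


def fpkm_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each sample so its column sums to 1e6 (FPKM -> TPM).

    TPM_gj = FPKM_gj / sum_g FPKM_gj * 1e6. Idempotent.
    """
    if m.scale != "linear":
        raise ValueError("fpkm_to_tpm expects a linear-scale matrix")
    colsums = m.values.sum(axis=0)
    dead = colsums[colsums <= 0]
    if len(dead):
        raise DegenerateSampleError(
            f"all-zero sample column(s): {list(dead.index)}"
        )
    return ExpressionMatrix(m.values / colsums * 1e6, "linear")


def zscore_frame(values: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score of a genes x samples frame, dropping zero-variance rows."""
    if values.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.warning("dropping %d zero-variance gene(s)", int((~keep).sum()))
    kept = values.loc[keep]
    return kept.sub(kept.mean(axis=1), axis=0).div(sd[keep], axis=0)


def zscore_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene across samples; zero-variance genes are dropped.

    Output rows have mean 0 and sample SD 1; the scale flag becomes log2
    (z-scores are signed)."""
    return ExpressionMatrix(zscore_frame(m.values), "log2")


def _parametric_delta_priors(delta_hat: np.ndarray) -> tuple[float, float]:
    """Method-of-moments inverse-gamma hyperparameters for the scale prior."""
    m = float(delta_hat.mean())
    s2 = float(delta_hat.var(ddof=1)) if delta_hat.size > 1 else 0.0
    if s2 < 1e-12:
        # degenerate spread across genes: prior collapses onto the mean
        return np.inf, np.inf
    a = (2.0 * s2 + m**2) / s2
    b = (m * s2 + m**3) / s2
    return a, b


def _eb_iterate(
    z_batch: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    gamma_bar: float,
    tau2: float,
    a_prior: float,
    b_prior: float,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint empirical-Bayes update of per-gene batch location and scale."""
    n_b = z_batch.shape[1]
    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    for _ in range(max_iter):
        if np.isinf(a_prior):
            new_delta = np.full_like(delta_star, delta_hat.mean())
        else:
            ss = ((z_batch - gamma_star[:, None]) ** 2).sum(axis=1)
            new_delta = (b_prior + 0.5 * ss) / (n_b / 2.0 + a_prior - 1.0)
        if tau2 < 1e-12:
            new_gamma = np.full_like(gamma_star, gamma_bar)
        else:
            new_gamma = (n_b * tau2 * gamma_hat + new_delta * gamma_bar) / (
                n_b * tau2 + new_delta
            )
        change = max(
            np.abs(new_gamma - gamma_star).max(initial=0.0),
            np.abs(new_delta - delta_star).max(initial=0.0)
            / max(np.abs(delta_star).max(initial=1.0), 1e-12),
        )
        gamma_star, delta_star = new_gamma, new_delta
        if change < tol:
            break
    return gamma_star, delta_star


def correct_batches(
    m: ExpressionMatrix, batches: pd.Series, parametric: bool = True
) -> ExpressionMatrix:
    """Remove additive per-batch location/scale effects on the log2 scale.

    ``batches`` maps every sample id to a batch label; each batch must hold
    at least 2 samples. With a single batch the matrix is returned unchanged
    (warning). ``parametric=False`` skips the empirical-Bayes shrinkage and
    uses the raw per-gene batch estimates (useful for diagnostics).
    """
    if m.scale != "log2":
        raise ValueError("correct_batches expects a log2-scale matrix")
    missing = m.sample_ids.difference(batches.index)
    if len(missing):
        raise ValueError(f"samples without batch label: {list(missing)[:5]}")
    b = batches.loc[m.sample_ids]
    levels = b.unique()
    if len(levels) < 2:
        logger.warning("single batch: nothing to correct")
        return ExpressionMatrix(m.values.copy(), "log2")
    counts = b.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(
            f"batch(es) with a single sample cannot be corrected: "
            f"{list(small.index)}; merge or drop those samples first"
        )

    x = m.values.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    masks = [np.asarray(b == lev) for lev in levels]
    n_per = np.array([mk.sum() for mk in masks])

    batch_means = np.stack([x[:, mk].mean(axis=1) for mk in masks], axis=1)
    grand_mean = batch_means @ (n_per / n_samples)
    fitted = np.zeros_like(x)
    for j, mk in enumerate(masks):
        fitted[:, mk] = batch_means[:, j : j + 1]
    var_pooled = ((x - fitted) ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    sd_pooled = np.sqrt(var_pooled)

    z = (x - grand_mean[:, None]) / sd_pooled[:, None]

    z_adj = np.empty_like(z)
    for j, mk in enumerate(masks):
        zb = z[:, mk]
        gamma_hat = zb.mean(axis=1)
        delta_hat = zb.var(axis=1, ddof=1)
        delta_hat = np.maximum(delta_hat, 1e-12)
        if parametric:
            gamma_bar = float(gamma_hat.mean())
            tau2 = float(gamma_hat.var(ddof=1)) if n_genes > 1 else 0.0
            a_prior, b_prior = _parametric_delta_priors(delta_hat)
            gamma_star, delta_star = _eb_iterate(
                zb, gamma_hat, delta_hat, gamma_bar, tau2, a_prior, b_prior
            )
        else:
            gamma_star, delta_star = gamma_hat, delta_hat
        delta_star = np.maximum(delta_star, 1e-12)
        z_adj[:, mk] = (zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    out = z_adj * sd_pooled[:, None] + grand_mean[:, None]
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids), "log2"
    )
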