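"""Immune-cell fraction estimation by linear nu-support-vector regression.

Each bulk sample is regressed on the signature matrix after joint
z-standardization; the best nu over a small grid (by reconstruction RMSE) is
kept, negative coefficients are clipped to zero and the remainder normalized
to the simplex. Significance per sample comes from a permutation null in
which the sample's marker values are shuffled across markers.

Bit-parity with the hosted CIBERSORT service is not promised: the solver is
scikit-learn's NuSVR with a linear kernel and C = 1, and quantile
normalization of the mixture is off by default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.svm import NuSVR

from .containers import (
    CoverageError,
    DegenerateSampleError,
    ExpressionMatrix,
    FractionTable,
    SignatureMatrix,
)

logger = logging.getLogger(__name__)

__all__ = ["estimate_fractions", "goodness_of_fit", "DEFAULT_NU_GRID"]

DEFAULT_NU_GRID = (0.25, 0.5, 0.75)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0:
        raise DegenerateSampleError("zero-variance vector cannot be standardized")
    return (v - v.mean()) / sd


def _fit_sample(
    y: np.ndarray, x: np.ndarray, nu_grid
) -> tuple[np.ndarray, float, float, float]:
    """Fit nu-SVR of standardized mixture y on standardized signature columns x.

    Returns (weights >= 0 summing to 1, fit correlation, rmse, best nu).
    """
    yz = _standardize(y)
    xz = np.column_stack([_standardize(x[:, j]) for j in range(x.shape[1])])
    best = None
    for nu in nu_grid:
        model = NuSVR(kernel="linear", nu=nu, C=1.0)
        model.fit(xz, yz)
        w = model.coef_.ravel()
        recon = xz @ w + model.intercept_.ravel()[0]
        rmse = float(np.sqrt(np.mean((recon - yz) ** 2)))
        if best is None or rmse < best[1]:
            corr = float(np.corrcoef(recon, yz)[0, 1]) if recon.std() > 0 else 0.0
            best = (w, rmse, corr, nu)
    w, rmse, corr, nu = best
    w = np.clip(w, 0.0, None)
    total = w.sum()
    if total <= 0:
        # pathological fit: fall back to uniform fractions
        w = np.full_like(w, 1.0 / len(w))
    else:
        w = w / total
    return w, corr, rmse, float(nu)


def estimate_fractions(
    m: ExpressionMatrix,
    sig: SignatureMatrix,
    nu_grid=DEFAULT_NU_GRID,
    n_perm: int = 0,
    seed: int = 0,
    min_marker_coverage: float = 0.5,
) -> FractionTable:
    """Estimate per-sample cell-type fractions from bulk expression.

    Requires at least ``min_marker_coverage`` of the signature's marker genes
    in ``m``. ``n_perm`` label-shuffled refits per sample give the
    permutation p-value with (r + 1)/(n_perm + 1) smoothing; 0 disables it.
    """
    if not len(nu_grid):
        raise ValueError("nu_grid must be non-empty")
    if n_perm < 0:
        raise ValueError("n_perm must be >= 0")
    shared = sig.marker_genes.intersection(m.gene_ids)
    coverage = len(shared) / len(sig.marker_genes)
    if coverage < min_marker_coverage:
        missing = sig.marker_genes.difference(m.gene_ids)
        raise CoverageError(
            f"only {coverage:.0%} of signature markers present "
            f"(need {min_marker_coverage:.0%}); missing e.g. {list(missing[:10])}"
        )
    mix = m.to_linear().values.loc[shared]
    x = sig.values.loc[shared].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    rows, stats = [], []
    for sample in mix.columns:
        y = mix[sample].to_numpy(dtype=float)
        if y.std(ddof=0) == 0:
            raise DegenerateSampleError(f"sample {sample!r} has zero marker variance")
        w, corr, rmse, nu = _fit_sample(y, x, nu_grid)
        if n_perm:
            hits = 0
            for _ in range(n_perm):
                _wp, corr_p, _r, _n = _fit_sample(rng.permutation(y), x, (nu,))
                if corr_p >= corr:
                    hits += 1
            pval = (hits + 1.0) / (n_perm + 1.0)
        else:
            pval = np.nan
        rows.append(w)
        stats.append((corr, rmse, pval))

    fractions = pd.DataFrame(rows, index=mix.columns, columns=sig.cell_types)
    stats_df = pd.DataFrame(
        stats, index=mix.columns, columns=["fit_correlation", "fit_rmse", "perm_pvalue"]
    )
    return FractionTable(fractions=fractions, stats=stats_df)


def goodness_of_fit(
    m: ExpressionMatrix, sig: SignatureMatrix, fr: FractionTable
) -> pd.DataFrame:
    """Pearson correlation and RMSE between observed and reconstructed
    standardized marker vectors, per sample.

    The reconstruction uses the estimated fractions as weights over the
    standardized signature columns, mirroring the fit-time objective.
    """
    shared = sig.marker_genes.intersection(m.gene_ids)
    mix = m.to_linear().values.loc[shared]
    x = sig.values.loc[shared].to_numpy(dtype=float)
    xz = np.column_stack([_standardize(x[:, j]) for j in range(x.shape[1])])
    out = []
    for sample in fr.sample_ids:
        if sample not in mix.columns:
            raise KeyError(f"sample {sample!r} not in expression matrix")
        yz = _standardize(mix[sample].to_numpy(dtype=float))
        w = fr.fractions.loc[sample].to_numpy(dtype=float)
        recon = xz @ w
        # refit scale/offset: fractions are simplex-normalized, so the
        # reconstruction is compared up to an affine map, as at fit time
        a, b_ = np.polyfit(recon, yz, 1) if recon.std() > 0 else (0.0, yz.mean())
        fitted = a * recon + b_
        corr = float(np.corrcoef(recon, yz)[0, 1]) if recon.std() > 0 else 0.0
        rmse = float(np.sqrt(np.mean((fitted - yz) ** 2)))
        out.append((corr, rmse))
    return pd.DataFrame(out, index=fr.sample_ids, columns=["correlation", "rmse"])
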