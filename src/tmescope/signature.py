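"""TME signature derivation.

Differential expression across TME groups uses a two-sample t statistic with
the per-gene pooled variance shrunk toward the cross-gene mean variance by a
fixed prior degrees of freedom (a self-contained moderated t). Benjamini-
Hochberg adjustment goes through statsmodels. Signature genes are clustered
into modules by K-means over genes, then optionally reduced by random-forest
permutation importance against the TME-group labels.

Two gene lists are emitted deliberately: the per-contrast significant-gene
union (the signature pool) and the all-contrast intersection (the
consistently dysregulated core) — the mapping between the two is a reporting
choice, so both are first-class outputs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, GeneModuleSet

logger = logging.getLogger(__name__)

__all__ = [
    "bh_adjust",
    "differential_genes",
    "consistent_genes",
    "signature_pool",
    "cluster_genes",
    "reduce_by_forest",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def _moderated_t(
    a: np.ndarray, b: np.ndarray, prior_df: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rows-of-a vs rows-of-b moderated two-sample t.

    Pooled per-gene variance s2_g is shrunk toward the cross-gene mean s2_0:
    s2_tilde = (d0 * s2_0 + d * s2_g) / (d0 + d), with d the pooled residual
    df and d0 = prior_df; the t reference distribution gains d0 df.
    """
    n1, n2 = a.shape[1], b.shape[1]
    d = n1 + n2 - 2
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    ss = (a - m1[:, None]) ** 2
    ss = ss.sum(axis=1) + ((b - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / d
    s2_0 = s2.mean()
    s2_tilde = (prior_df * s2_0 + d * s2) / (prior_df + d)
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    effect = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=d + prior_df)
    return effect, t, p


def differential_genes(
    m: ExpressionMatrix,
    labels: pd.Series,
    contrast: str = "one-vs-rest",
    prior_df: float = 4.0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Moderated-t differential expression across TME groups.

    ``contrast`` is ``"one-vs-rest"`` (one table row set per group) or
    ``"pairwise"`` (one per unordered group pair). Returns a long DataFrame
    with columns gene_id, contrast, effect (mean log2 difference), statistic,
    p, q (BH within contrast) and significant (q < ``q_threshold``).
    """
    if m.scale != "log2":
        raise ValueError("differential_genes expects log2-scale expression")
    lab = pd.Series(labels).loc[m.sample_ids]
    counts = lab.value_counts()
    if (counts < 3).any():
        small = counts[counts < 3]
        raise ValueError(f"groups with < 3 samples: {dict(small)}")
    x = m.values.to_numpy(dtype=float)
    groups = sorted(counts.index, key=str)

    if contrast == "one-vs-rest":
        pairs = [(g, None) for g in groups]
    elif contrast == "pairwise":
        pairs = [(g1, g2) for i, g1 in enumerate(groups) for g2 in groups[i + 1 :]]
    else:
        raise ValueError(f"unknown contrast {contrast!r}")

    out = []
    for g1, g2 in pairs:
        in1 = np.asarray(lab == g1)
        in2 = ~in1 if g2 is None else np.asarray(lab == g2)
        name = f"{g1}_vs_rest" if g2 is None else f"{g1}_vs_{g2}"
        effect, t, p = _moderated_t(x[:, in1], x[:, in2], prior_df)
        q = bh_adjust(p)
        out.append(
            pd.DataFrame(
                {
                    "gene_id": m.gene_ids,
                    "contrast": name,
                    "effect": effect,
                    "statistic": t,
                    "p": p,
                    "q": q,
                    "significant": q < q_threshold,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def consistent_genes(deg: pd.DataFrame, q_threshold: float = 0.05) -> list:
    """Genes significant (q < threshold) in every contrast, sorted.

    An empty intersection is a valid (logged) outcome, not an error.
    """
    contrasts = deg["contrast"].unique()
    if len(contrasts) < 2:
        raise ValueError("need at least 2 contrasts to intersect")
    sets = [
        set(deg.loc[(deg["contrast"] == c) & (deg["q"] < q_threshold), "gene_id"])
        for c in contrasts
    ]
    inter = set.intersection(*sets)
    if not inter:
        logger.info("no gene significant in every contrast")
    return sorted(inter)


def signature_pool(
    deg: pd.DataFrame, q_threshold: float = 0.05, min_abs_effect: float = 0.0
) -> list:
    """Union of per-contrast significant genes — the signature gene pool.

    ``min_abs_effect`` adds an optional log2 effect-size floor: in large
    cohorts library-size normalization alone makes small compositional
    shifts statistically significant, and a fold-change floor keeps the pool
    to genes with biologically meaningful differences.
    """
    keep = deg["q"] < q_threshold
    if min_abs_effect > 0:
        keep &= deg["effect"].abs() >= min_abs_effect
    return sorted(set(deg.loc[keep, "gene_id"]))


def cluster_genes(m_z: ExpressionMatrix, k: int = 2, seed: int = 0) -> GeneModuleSet:
    """K-means over genes (samples as features) into k modules.

    Module ids GeneModule1..k are assigned in decreasing module size.
    Betas/signs are left unset; see ``tmescope.score.assign_cox_signs``.
    """
    x = m_z.values.to_numpy(dtype=float)
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds number of genes {x.shape[0]}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(x)
    order = np.argsort([-np.sum(raw == c) for c in range(k)], kind="stable")
    remap = {int(c): i for i, c in enumerate(order)}
    modules: dict[str, list] = {f"GeneModule{i + 1}": [] for i in range(k)}
    for gene, c in zip(m_z.gene_ids, raw):
        modules[f"GeneModule{remap[int(c)] + 1}"].append(gene)
    modules = {mid: genes for mid, genes in modules.items() if genes}
    return GeneModuleSet(modules=modules)


def _oob_permutation_importance(
    forest: RandomForestClassifier, x: np.ndarray, y: np.ndarray, seed: int
) -> np.ndarray:
    """Per-tree out-of-bag permutation importance.

    For every tree, the accuracy on its own out-of-bag samples is compared to
    the accuracy after shuffling one feature among those samples; the drop,
    averaged over trees, is the feature's importance. Unlike whole-ensemble
    permutation importance this keeps redundant-but-informative features
    apart from pure noise, because single trees cannot compensate.
    """
    from sklearn.ensemble._forest import (  # per-tree bootstrap bookkeeping
        _generate_unsampled_indices,
        _get_n_samples_bootstrap,
    )

    rng = np.random.default_rng(seed)
    n_samples, n_features = x.shape
    # sub-trees predict class indices, not the original labels
    class_index = {c: i for i, c in enumerate(forest.classes_)}
    y = np.asarray([class_index[v] for v in y])
    n_boot = _get_n_samples_bootstrap(n_samples, forest.max_samples, None)
    drops = np.zeros(n_features)
    counts = np.zeros(n_features)
    for tree in forest.estimators_:
        oob = _generate_unsampled_indices(tree.random_state, n_samples, n_boot, None)
        if oob.size < 2:
            continue
        x_oob, y_oob = x[oob], y[oob]
        base = np.mean(tree.predict(x_oob) == y_oob)
        perm = rng.permutation(oob.size)
        for j in range(n_features):
            x_perm = x_oob.copy()
            x_perm[:, j] = x_oob[perm, j]
            acc = np.mean(tree.predict(x_perm) == y_oob)
            drops[j] += base - acc
            counts[j] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, drops / np.maximum(counts, 1), 0.0)


def reduce_by_forest(
    m: ExpressionMatrix,
    modules: GeneModuleSet,
    labels: pd.Series,
    n_trees: int = 500,
    keep_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[GeneModuleSet, pd.Series]:
    """Prune each module to its top ``keep_fraction`` genes by random-forest
    out-of-bag permutation importance for the TME-group labels.

    Every module keeps at least one gene. Returns the pruned module set and
    the per-gene importance series.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    lab = pd.Series(labels).loc[m.sample_ids]
    if lab.nunique() < 2:
        raise ValueError("need at least 2 classes for forest reduction")
    genes = modules.all_genes()
    x = m.values.loc[genes].to_numpy(dtype=float).T  # samples x genes
    y = lab.to_numpy()
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    ).fit(x, y)
    importance = pd.Series(
        _oob_permutation_importance(forest, x, y, seed), index=genes, name="importance"
    )

    pruned: dict[str, list] = {}
    for mid, mgenes in modules.modules.items():
        ranked = importance.loc[mgenes].sort_values(ascending=False, kind="stable")
        n_keep = max(1, int(np.floor(keep_fraction * len(mgenes))))
        pruned[mid] = sorted(ranked.index[:n_keep])
    return GeneModuleSet(modules=pruned), importance
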