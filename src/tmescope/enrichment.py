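"""Over-representation analysis and preranked gene-set enrichment.

ORA uses the hypergeometric upper tail against a user-supplied universe
(defaulting, by design, to the genes of the expression matrix under study —
not the union of the collection — since the choice changes p-values
materially). GSEA runs the weighted Kolmogorov-Smirnov-like running sum on a
preranked list with gene-set-label permutations for significance; phenotype
permutation does not apply when the input is already a ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .signature import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "ora", "gsea_preranked"]


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. read from a GMT file)."""

    sets: dict  # set_id -> list of gene ids
    source: str = ""

    def __post_init__(self) -> None:
        for sid, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {sid!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate genes within set {sid!r}")


def ora(gene_list, universe, collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each set.

    p = P(X >= overlap) with population N = |universe|, successes
    K = |set ∩ universe|, draws n = |list|; q is BH across the tested sets.
    Sets disjoint from the universe are dropped with a warning.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    genes = set(gene_list)
    if not genes <= universe:
        raise ValueError("gene list must be a subset of the universe")
    n_pop, n_draw = len(universe), len(genes)
    rows = []
    for sid, members in collection.sets.items():
        in_universe = set(members) & universe
        if not in_universe:
            logger.warning("set %s shares no genes with the universe; skipped", sid)
            continue
        k_succ = len(in_universe)
        overlap = len(genes & in_universe)
        expected = n_draw * k_succ / n_pop
        p = float(stats.hypergeom.sf(overlap - 1, n_pop, k_succ, n_draw))
        rows.append((sid, overlap, k_succ, expected, p))
    out = pd.DataFrame(
        rows, columns=["set_id", "overlap", "set_size", "expected", "p"]
    )
    if len(out):
        out["q"] = bh_adjust(out["p"])
        out["direction"] = np.where(out["overlap"] >= out["expected"], "over", "under")
    return out


def _running_sum_es(
    ranked_genes: np.ndarray, scores: np.ndarray, member: np.ndarray, weight: float
) -> float:
    """Signed extremum of the enrichment running sum.

    Hits increment proportionally to |score|**weight (uniform when weight=0),
    misses decrement uniformly by 1/(N - K).
    """
    n = len(ranked_genes)
    k = int(member.sum())
    hit_w = np.abs(scores) ** weight
    hit_w = np.where(member, hit_w, 0.0)
    denom = hit_w.sum()
    if denom <= 0:  # all member scores are zero: fall back to uniform hits
        hit_w = member.astype(float)
        denom = float(k)
    miss = np.where(member, 0.0, 1.0 / (n - k))
    running = np.cumsum(hit_w / denom - miss)
    return float(running[np.argmax(np.abs(running))])


def gsea_preranked(
    ranking: pd.Series,
    gene_set,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict | None:
    """Preranked GSEA of one gene set against a scored ranking.

    ``ranking`` maps gene id to ranking score (sorted internally, descending).
    ES is the signed extremum of the running sum; the null comes from
    ``n_perm`` random gene-label sets of the same size; NES divides ES by the
    mean |null ES| of the matching sign; p uses (r + 1)/(n + 1) smoothing.
    Returns None (with a warning) when fewer than 2 set members are ranked.
    """
    if ranking.index.has_duplicates:
        raise ValueError("ranking contains duplicate genes")
    ranking = ranking.sort_values(ascending=False, kind="stable")
    genes = ranking.index.to_numpy()
    scores = ranking.to_numpy(dtype=float)
    member = np.isin(genes, list(set(gene_set)))
    k = int(member.sum())
    if k < 2:
        logger.warning("gene set overlaps ranking in %d gene(s) < 2; skipped", k)
        return None
    if k == len(genes):
        raise ValueError("gene set covers the whole ranking")
    es = _running_sum_es(genes, scores, member, weight)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    idx = np.arange(len(genes))
    for i in range(n_perm):
        pick = rng.choice(idx, size=k, replace=False)
        mem = np.zeros(len(genes), dtype=bool)
        mem[pick] = True
        null[i] = _running_sum_es(genes, scores, mem, weight)
    # NES normalizes by the same-signed half of the null; the p-value is
    # two-sided, comparing |ES| against the full permutation null, which is
    # exchangeable under H0 and hence calibrated
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if not len(same_sign):
        same_sign = null
    denom = np.abs(same_sign).mean()
    nes = es / denom if denom > 0 else 0.0
    hits = int(np.sum(np.abs(null) >= abs(es)))
    p = (hits + 1.0) / (n_perm + 1.0)
    return {
        "es": es,
        "nes": float(nes),
        "p": float(p),
        "size": k,
        "direction": "up" if es >= 0 else "down",
        "null_es": null,
    }
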