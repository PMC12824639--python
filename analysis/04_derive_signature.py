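"""Derive the TME gene signature.

Moderated-t differential expression across the TME groups (one-vs-rest),
per-contrast union (signature pool) and all-contrast intersection, K-means
gene modules on the z-scored pool, and random-forest importance pruning.
"""

from pathlib import Path

import pandas as pd

from tmescope import (
    ExpressionMatrix,
    cluster_genes,
    consistent_genes,
    correct_batches,
    differential_genes,
    fpkm_to_tpm,
    reduce_by_forest,
    signature_pool,
    zscore_genes,
)
from tmescope.io import read_clinical, read_expression, read_signature

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    expr = read_expression(OUT / "expression.tsv", scale="linear")
    sig = read_signature(OUT / "signature_matrix.tsv")
    clinical = read_clinical(OUT / "clinical.tsv")
    labels = pd.read_csv(OUT / "tme_labels.tsv", sep="\t", index_col=0)["consensus"]

    log2 = fpkm_to_tpm(expr).to_log2()
    batches = pd.Series(
        clinical["batch"].to_numpy(), index=clinical["sample_id"].to_numpy()
    )
    log2 = correct_batches(log2, batches)

    deg = differential_genes(log2, labels, contrast="one-vs-rest")
    deg.to_csv(OUT / "deg_table.tsv", sep="\t", index=False)
    pool = signature_pool(deg, min_abs_effect=0.5)
    core = consistent_genes(deg)
    # markers track the fractions that defined the groups; the prognostic
    # signature is built from the remaining genes
    pool_nm = [g for g in pool if g not in set(sig.marker_genes)]

    z = zscore_genes(ExpressionMatrix(log2.values.loc[pool_nm], "log2"))
    modules = cluster_genes(z, k=2, seed=3)
    pruned, importance = reduce_by_forest(
        ExpressionMatrix(log2.values.loc[pool_nm], "log2"),
        modules,
        labels,
        n_trees=200,
        keep_fraction=0.8,
        seed=3,
    )

    rows = []
    for mid, genes in modules.modules.items():
        kept = set(pruned.modules[mid])
        for g in genes:
            rows.append((g, mid, g in kept, importance[g]))
    pd.DataFrame(rows, columns=["gene_id", "module", "kept", "importance"]).to_csv(
        OUT / "gene_modules.tsv", sep="\t", index=False
    )

    print(f"signature pool (union of significant genes): {len(pool)} "
          f"({len(pool_nm)} non-marker)")
    print(f"consistently dysregulated core (all contrasts): {len(core)} genes")
    print("module sizes after pruning: "
          + ", ".join(f"{m}: {len(g)}" for m, g in pruned.modules.items()))


if __name__ == "__main__":
    main()
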