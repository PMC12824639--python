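"""End-to-end TME characterization on one cohort.

Chains the full analysis: TPM normalization, log2, batch correction,
cell-fraction deconvolution, TME clustering on the fractions, differential
expression across TME groups, signature-gene selection and module
clustering, per-module PCA components, Cox-signed TMEscore, maxstat
dichotomization and the high-vs-low log-rank comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .clustering import hierarchical_cluster
from .containers import ExpressionMatrix, FractionTable, GeneModuleSet, SignatureMatrix
from .deconvolution import DEFAULT_NU_GRID, estimate_fractions
from .preprocess import correct_batches, fpkm_to_tpm, zscore_genes
from .score import assign_cox_signs, compute_tmescore, maxstat_cutpoint, module_pc_scores
from .signature import cluster_genes, consistent_genes, differential_genes, signature_pool
from .survival import logrank_test
from .synthetic import SimulationConfig, make_signature_matrix, simulate_cohort

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    fractions: FractionTable
    tme_labels: pd.Series
    deg: pd.DataFrame
    signature_genes: list
    intersection_genes: list
    modules: GeneModuleSet
    components: pd.DataFrame
    score_table: pd.DataFrame
    cutpoint: float
    groups: pd.Series
    logrank: dict
    clinical: pd.DataFrame
    extras: dict = field(default_factory=dict)


def run_pipeline(
    cfg: SimulationConfig,
    sig: SignatureMatrix | None = None,
    expr: ExpressionMatrix | None = None,
    clinical: pd.DataFrame | None = None,
    k_tme: int = 3,
    k_gene_modules: int = 2,
    nu_grid=DEFAULT_NU_GRID,
) -> PipelineResult:
    """Run the full pipeline, simulating the cohort from ``cfg`` unless
    expression/clinical tables are supplied."""
    if sig is None:
        sig = make_signature_matrix(cfg.n_cell_types, cfg.n_markers_per_type, seed=cfg.seed + 101)
    truth = None
    if expr is None or clinical is None:
        expr, clinical, truth = simulate_cohort(cfg, sig)

    tpm = fpkm_to_tpm(expr)
    log2 = tpm.to_log2()
    batches = pd.Series(
        clinical["batch"].to_numpy(), index=clinical["sample_id"].to_numpy()
    )
    if batches.nunique() > 1:
        log2 = correct_batches(log2, batches)

    fractions = estimate_fractions(log2, sig, nu_grid=nu_grid, n_perm=0, seed=cfg.seed)
    tme_labels = pd.Series(
        hierarchical_cluster(fractions.fractions, k=k_tme),
        index=fractions.sample_ids,
        name="tme_group",
    )

    deg = differential_genes(log2, tme_labels, contrast="one-vs-rest")
    sig_genes = signature_pool(deg, min_abs_effect=0.5)
    inter_genes = consistent_genes(deg)
    # marker genes mirror the cell fractions that defined the groups; the
    # prognostic signature is built from the remaining (non-marker) genes
    non_marker = [g for g in sig_genes if g not in set(sig.marker_genes)]
    pool = non_marker if len(non_marker) >= 2 * k_gene_modules else sig_genes

    z = zscore_genes(ExpressionMatrix(log2.values.loc[pool], "log2"))
    modules = cluster_genes(z, k=k_gene_modules, seed=cfg.seed)

    components = pd.DataFrame(
        {mid: module_pc_scores(z, genes) for mid, genes in modules.modules.items()}
    )
    times = clinical["os_time"].to_numpy(dtype=float)
    events = clinical["os_event"].to_numpy(dtype=int)
    modules = assign_cox_signs(components, times, events, modules=modules)
    score_table = compute_tmescore(components, modules)

    cut = maxstat_cutpoint(score_table["tmescore"], times, events)
    stat, dfree, p = logrank_test(times, events, cut["groups"].to_numpy())

    return PipelineResult(
        fractions=fractions,
        tme_labels=tme_labels,
        deg=deg,
        signature_genes=sig_genes,
        intersection_genes=inter_genes,
        modules=modules,
        components=components,
        score_table=score_table,
        cutpoint=cut["cutpoint"],
        groups=cut["groups"],
        logrank={"statistic": stat, "df": dfree, "p": p, "maxstat_p": cut["p"]},
        clinical=clinical,
        extras={"truth": truth, "signature_matrix": sig, "log2": log2},
    )
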