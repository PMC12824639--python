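"""Simulate the study cohort.

Draws one synthetic breast-cancer-style cohort (600 tumors, 5 immune cell
types, 3 TME archetypes, 2 batches, one hazardous and one protective
prognostic gene module) and writes the expression matrix, clinical table,
ground truth and config under results/.
"""

from pathlib import Path

from tmescope import SimulationConfig, make_signature_matrix, simulate_cohort
from tmescope.io import save_config, write_clinical, write_expression, write_signature

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260925


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = SimulationConfig(n_samples=600, seed=SEED)
    sig = make_signature_matrix(cfg.n_cell_types, cfg.n_markers_per_type, seed=SEED + 101)
    expr, clinical, truth = simulate_cohort(cfg, sig)

    write_expression(expr, OUT / "expression.tsv")
    write_clinical(clinical, OUT / "clinical.tsv")
    write_signature(sig, OUT / "signature_matrix.tsv")
    save_config(cfg, OUT / "simulation_config.yaml")
    truth.true_fractions.to_csv(OUT / "true_fractions.tsv", sep="\t")
    truth.true_group.to_csv(OUT / "true_groups.tsv", sep="\t")

    n_events = int(clinical["os_event"].sum())
    print(f"cohort: {expr.n_samples} samples x {expr.n_genes} genes")
    print(f"events: {n_events} ({n_events / len(clinical):.0%}); "
          f"response mix: {clinical['response'].value_counts().to_dict()}")
    sizes = {m: len(g) for m, g in truth.true_module_genes.items()}
    print(f"planted modules: {sizes}; betas {truth.true_betas}")


if __name__ == "__main__":
    main()
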