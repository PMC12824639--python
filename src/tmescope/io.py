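"""Plain-text readers/writers for the pipeline's tables.

Expression and signature matrices travel as TSV with genes in rows (first
column the gene id, header the sample/cell-type names), clinical tables as
one-row-per-sample TSV, gene sets as GMT (set id, description, then genes,
tab-separated), configs as YAML.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .containers import ExpressionMatrix, FractionTable, SignatureMatrix, validate_clinical
from .enrichment import GeneSetCollection
from .synthetic import SimulationConfig

__all__ = [
    "read_expression",
    "write_expression",
    "read_signature",
    "write_signature",
    "read_clinical",
    "write_clinical",
    "write_fractions",
    "read_gmt",
    "write_gmt",
    "load_config",
    "save_config",
]


def read_expression(path, scale: str = "linear") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, scale)


def write_expression(m: ExpressionMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id")


def read_signature(path) -> SignatureMatrix:
    return SignatureMatrix(pd.read_csv(path, sep="\t", index_col=0))


def write_signature(sig: SignatureMatrix, path) -> None:
    sig.values.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_clinical(df)


def write_clinical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_fractions(fr: FractionTable, path) -> None:
    out = fr.fractions.join(fr.stats)
    out.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: per line, set id, description, then member genes."""
    sets: dict[str, list] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (needs >= 3 fields): {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = [
        "\t".join([sid, collection.source or "na", *genes])
        for sid, genes in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "archetypes" in raw and raw["archetypes"] is not None:
        raw["archetypes"] = [tuple(a) for a in raw["archetypes"]]
    if "module_spec" in raw:
        raw["module_spec"] = [tuple(m) for m in raw["module_spec"]]
    return SimulationConfig(**raw)


def _plain(obj):
    """Recursively convert numpy scalars/containers to YAML-safe builtins."""
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def save_config(cfg: SimulationConfig, path) -> None:
    data = {k: _plain(v) for k, v in vars(cfg).items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
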