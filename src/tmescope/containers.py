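"""Core data containers shared across the pipeline.

Matrices are pandas DataFrames throughout: expression is genes x samples,
cell fractions are samples x cell types. Thin dataclasses add the scale
flag and validation that the bare DataFrame cannot carry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CoverageError",
    "DegenerateSampleError",
    "ExpressionMatrix",
    "SignatureMatrix",
    "FractionTable",
    "GeneModuleSet",
    "ConsensusResult",
    "CLINICAL_COLUMNS",
    "validate_clinical",
]


class DegenerateSampleError(ValueError):
    """A sample column carries no usable signal (all zero / zero variance)."""


class CoverageError(ValueError):
    """Too few signature marker genes are present in the mixture matrix."""


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with a declared scale.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample.
    scale
        ``"linear"`` for non-negative TPM-like abundances, ``"log2"`` for
        log2-transformed values (which may be negative).
    """

    values: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if self.scale == "linear" and (arr < 0).any():
            raise ValueError("linear-scale expression must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_log2(self) -> "ExpressionMatrix":
        """Return a log2-scale copy; linear values map through log2(x + 1)."""
        if self.scale == "log2":
            return ExpressionMatrix(self.values.copy(), "log2")
        return ExpressionMatrix(np.log2(self.values + 1.0), "log2")

    def to_linear(self) -> "ExpressionMatrix":
        """Return a linear-scale copy; log2 values map through 2**x - 1."""
        if self.scale == "linear":
            return ExpressionMatrix(self.values.copy(), "linear")
        lin = np.power(2.0, self.values) - 1.0
        return ExpressionMatrix(lin.clip(lower=0.0), "linear")

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.scale)


@dataclass
class SignatureMatrix:
    """Marker genes x cell types reference profiles for deconvolution."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValueError("signature matrix needs at least 2 cell types")
        if self.values.index.has_duplicates:
            raise ValueError("marker gene appears in more than one signature row")
        if self.values.columns.has_duplicates:
            raise ValueError("cell type names must be unique")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)) or (arr < 0).any():
            raise ValueError("signature values must be finite and non-negative")

    @property
    def marker_genes(self) -> pd.Index:
        return self.values.index

    @property
    def cell_types(self) -> pd.Index:
        return self.values.columns

    @property
    def n_cell_types(self) -> int:
        return self.values.shape[1]


@dataclass
class FractionTable:
    """Per-sample estimated cell-type fractions plus fit statistics.

    ``fractions`` is samples x cell types (rows on the simplex);
    ``stats`` is samples x (fit_correlation, fit_rmse, perm_pvalue).
    """

    fractions: pd.DataFrame
    stats: pd.DataFrame

    def __post_init__(self) -> None:
        fr = self.fractions.to_numpy()
        if (fr < -1e-12).any():
            raise ValueError("fractions must be non-negative")
        sums = fr.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("fraction rows must sum to 1")
        pv = self.stats["perm_pvalue"].dropna()
        if ((pv < 0) | (pv > 1)).any():
            raise ValueError("perm_pvalue outside [0, 1]")

    @property
    def sample_ids(self) -> pd.Index:
        return self.fractions.index


@dataclass
class GeneModuleSet:
    """Disjoint gene modules with optional per-module Cox coefficients.

    ``signs`` maps module id to +1/-1 following the sign of the univariate
    Cox log-hazard of the module's component score; a module with |beta|
    below resolution never receives a sign automatically.
    """

    modules: dict = field(default_factory=dict)  # module_id -> list[str]
    betas: dict = field(default_factory=dict)  # module_id -> float
    signs: dict = field(default_factory=dict)  # module_id -> {+1, -1}

    def __post_init__(self) -> None:
        seen: set = set()
        for mid, genes in self.modules.items():
            if not genes:
                raise ValueError(f"module {mid!r} is empty")
            gset = set(genes)
            if seen & gset:
                raise ValueError("modules must be disjoint")
            seen |= gset
        for mid, s in self.signs.items():
            if s not in (1, -1):
                raise ValueError(f"sign for {mid!r} must be +1 or -1")

    @property
    def module_ids(self):
        return list(self.modules)

    def all_genes(self) -> list:
        return [g for genes in self.modules.values() for g in genes]


@dataclass
class ConsensusResult:
    """Consensus clustering output for a single k."""

    k: int
    consensus_matrix: pd.DataFrame
    labels: pd.Series
    pac: float
    n_iter: int
    subsample_fraction: float

    def __post_init__(self) -> None:
        cm = self.consensus_matrix.to_numpy()
        if not np.allclose(cm, cm.T, atol=1e-12):
            raise ValueError("consensus matrix must be symmetric")
        if not np.allclose(np.diag(cm), 1.0):
            raise ValueError("consensus diagonal must be 1")
        if not (0.0 <= self.pac <= 1.0):
            raise ValueError("PAC must lie in [0, 1]")


CLINICAL_COLUMNS = (
    "sample_id",
    "os_time",
    "os_event",
    "er",
    "pr",
    "her2",
    "subtype",
    "batch",
    "tmb",
    "response",
)

_RECEPTOR_LEVELS = {"pos", "neg", "missing"}
_RESPONSE_LEVELS = {"CR", "PR", "SD", "PD", "missing"}


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical table against the documented schema.

    Required: sample_id, os_time (months, > 0 when present), os_event in
    {0, 1}. Receptor status columns take {pos, neg, missing}; response takes
    {CR, PR, SD, PD, missing}. Returns the (unmodified) frame for chaining.
    """
    missing = {"sample_id", "os_time", "os_event"} - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in clinical table")
    times = df["os_time"].dropna()
    if (times <= 0).any():
        raise ValueError("os_time must be positive")
    events = df["os_event"].dropna()
    if not set(events.unique()) <= {0, 1}:
        raise ValueError("os_event must be 0/1")
    if df["os_event"].notna().gt(df["os_time"].notna()).any():
        raise ValueError("os_event present without os_time")
    for col in ("er", "pr", "her2"):
        if col in df.columns:
            bad = set(df[col].dropna().unique()) - _RECEPTOR_LEVELS
            if bad:
                raise ValueError(f"invalid {col} levels: {sorted(bad)}")
    if "response" in df.columns:
        bad = set(df["response"].dropna().unique()) - _RESPONSE_LEVELS
        if bad:
            raise ValueError(f"invalid response levels: {sorted(bad)}")
    if "tmb" in df.columns:
        tmb = pd.to_numeric(df["tmb"], errors="coerce").dropna()
        if (tmb < 0).any():
            raise ValueError("tmb must be non-negative")
    return df
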