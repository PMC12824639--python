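"""Synthetic breast-cancer-style cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: bulk expression as signature-driven mixtures of immune cell types,
latent tumor-microenvironment (TME) groups defined by Dirichlet archetypes
over cell fractions, planted prognostic gene modules whose activity drives
exponential survival times through a Cox-form hazard, additive per-batch
shifts on the log2 scale, tumor mutational burden correlated with the latent
prognostic score, and four-level immunotherapy response labels monotone in
that score.

Every draw goes through a splittable numpy Generator seeded from a single
integer, so cohorts are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SignatureMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "default_archetypes",
    "make_signature_matrix",
    "simulate_cohort",
]

#: Dirichlet concentration given to a group's own dominant cell types versus
#: the rest. At 16 vs 1 the probability that a sample's largest off-archetype
#: coordinate exceeds its dominant one is P(Gamma(1) > Gamma(16)) = 2**-16,
#: so planted groups are recoverable essentially without misassignment.
DEFAULT_HIGH_CONCENTRATION = 16.0
DEFAULT_LOW_CONCENTRATION = 1.0

#: Cumulative response thresholds: lowest-scoring ~30% PD, next 35% SD,
#: 25% PR, top 10% CR, matching a cohort where most patients do not respond.
RESPONSE_QUANTILES = (0.30, 0.65, 0.90)
RESPONSE_LEVELS = ("PD", "SD", "PR", "CR")


def default_archetypes(
    n_cell_types: int,
    n_groups: int = 3,
    high: float = DEFAULT_HIGH_CONCENTRATION,
    low: float = DEFAULT_LOW_CONCENTRATION,
) -> list[tuple[float, ...]]:
    """Dirichlet concentration vectors for ``n_groups`` TME archetypes.

    Cell types are split into ``n_groups`` contiguous blocks; each archetype
    concentrates mass on its own block.
    """
    if n_groups < 1 or n_cell_types < n_groups:
        raise ValueError("need at least one cell type per group")
    bounds = np.linspace(0, n_cell_types, n_groups + 1).astype(int)
    out = []
    for g in range(n_groups):
        conc = np.full(n_cell_types, low)
        conc[bounds[g] : bounds[g + 1]] = high
        out.append(tuple(conc))
    return out


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    module_spec lists planted prognostic modules as (size, beta) pairs where
    beta is the log-hazard per 1-SD increase in module activity. The default
    plants one hazardous (+0.8) and one protective (-0.8) module, i.e. per-SD
    hazard ratios of ~2.2 and ~0.45.
    """

    n_samples: int = 300
    n_cell_types: int = 5
    n_markers_per_type: int = 20
    archetypes: list = None
    group_weights: tuple = None
    noise_sd: float = 0.1
    n_batches: int = 2
    batch_shift_sd: float = 0.5
    module_spec: list = field(default_factory=lambda: [(40, 0.8), (40, -0.8)])
    module_effect: float = 1.0  # log2 shift separating group means of module activity
    n_noise_genes: int = 100
    baseline_hazard: float = 0.02  # events per month
    censor_rate: float = 0.01  # censoring events per month
    tmb_link: float = 5.0  # mutations/Mb per SD of latent prognostic score
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetypes is None:
            self.archetypes = default_archetypes(self.n_cell_types)
        if self.group_weights is None:
            k = len(self.archetypes)
            self.group_weights = tuple(1.0 / k for _ in range(k))
        self.validate()

    def validate(self) -> None:
        for name in ("n_samples", "n_cell_types", "n_markers_per_type", "n_batches"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if abs(sum(self.group_weights) - 1.0) > 1e-12:
            raise ValueError("group_weights must sum to 1")
        if len(self.group_weights) != len(self.archetypes):
            raise ValueError("one weight per archetype required")
        for conc in self.archetypes:
            if len(conc) != self.n_cell_types:
                raise ValueError("archetype length must equal n_cell_types")
        if self.noise_sd < 0 or self.batch_shift_sd < 0:
            raise ValueError("noise/batch SDs must be non-negative")
        if self.baseline_hazard <= 0 or self.censor_rate <= 0:
            raise ValueError("hazard rates must be positive")
        for size, _beta in self.module_spec:
            if size < 1:
                raise ValueError("module sizes must be >= 1")


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream oracles."""

    true_fractions: pd.DataFrame  # samples x cell types, rows on the simplex
    true_group: pd.Series  # sample -> archetype index
    true_module_genes: dict  # module id -> list of gene ids
    true_betas: dict  # module id -> planted log-hazard
    latent_score: pd.Series  # protective-direction prognostic score

    def __post_init__(self) -> None:
        sums = self.true_fractions.to_numpy().sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("true fractions must lie on the simplex")


def make_signature_matrix(
    n_cell_types: int,
    n_markers_per_type: int,
    seed: int,
    fold: float = 8.0,
) -> SignatureMatrix:
    """Build an LM22-like marker signature: each marker gene is expressed
    ``fold``-times higher in its own cell type than in any other.

    Off-target expression is drawn Uniform(0.5, 2); the on-target value is
    ``fold`` times the row's off-target maximum, jittered upward, so marker
    dominance holds by construction for any fold > 1.
    """
    if n_cell_types < 2:
        raise ValueError("need at least 2 cell types")
    if n_markers_per_type < 1:
        raise ValueError("need at least 1 marker per type")
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    rng = np.random.default_rng(seed)
    n_markers = n_cell_types * n_markers_per_type
    vals = rng.uniform(0.5, 2.0, size=(n_markers, n_cell_types))
    jitter = rng.uniform(1.0, 1.5, size=n_markers)
    types = [f"CellType{t + 1:02d}" for t in range(n_cell_types)]
    genes = []
    for t in range(n_cell_types):
        for m in range(n_markers_per_type):
            row = t * n_markers_per_type + m
            off_max = np.delete(vals[row], t).max() if n_cell_types > 1 else 1.0
            vals[row, t] = fold * off_max * jitter[row]
            genes.append(f"MK_{types[t]}_{m + 1:03d}")
    return SignatureMatrix(pd.DataFrame(vals, index=genes, columns=types))


def _module_group_shifts(n_groups: int, effect: float, rng: np.random.Generator):
    """Per-group mean shifts of one module's activity: a random permutation
    of equally spaced levels in [-effect, +effect], so every module is
    differential between every pair of groups."""
    levels = np.linspace(-effect, effect, n_groups) if n_groups > 1 else np.zeros(1)
    return rng.permutation(levels)


def simulate_cohort(
    cfg: SimulationConfig, sig: SignatureMatrix
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Draw one cohort under ``cfg`` through ``sig``.

    Returns the linear-scale expression matrix (marker genes + planted module
    genes + unstructured noise genes), a clinical table, and the ground truth.

    Generative steps, per sample i in latent group g:

    * fractions f_i ~ Dirichlet(archetype_g); marker expression =
      (sig @ f_i) * exp(N(0, noise_sd)) multiplicative lognormal noise;
    * module m has activity a_im = shift_{m,g} + N(0, 0.5); each of its genes
      is base_g + a_im + N(0, 0.4) on log2 scale;
    * batch shifts ~ N(0, batch_shift_sd) per gene x batch, added on log2;
    * hazard_i = baseline_hazard * exp(sum_m beta_m * zbar_im) with zbar the
      mean per-gene z-score of module m's genes; survival ~ Exponential,
      censoring independently Exponential(censor_rate);
    * latent prognostic score = -linear predictor (high = low hazard); TMB =
      max(0, 10 + tmb_link * z(latent) + N(0, 2)); response CR/PR/SD/PD by
      thresholding z(latent) + logistic noise at fixed population quantiles.
    """
    cfg.validate()
    if sig.n_cell_types != cfg.n_cell_types:
        raise ValueError(
            f"signature has {sig.n_cell_types} cell types, config expects {cfg.n_cell_types}"
        )
    rng = np.random.default_rng(cfg.seed)
    (
        rng_group,
        rng_frac,
        rng_noise,
        rng_module,
        rng_batch,
        rng_surv,
        rng_clin,
    ) = rng.spawn(7)

    n = cfg.n_samples
    samples = [f"S{i + 1:04d}" for i in range(n)]
    n_groups = len(cfg.archetypes)
    groups = rng_group.choice(n_groups, size=n, p=np.asarray(cfg.group_weights))

    fractions = np.zeros((n, cfg.n_cell_types))
    for g in range(n_groups):
        idx = np.flatnonzero(groups == g)
        if not idx.size:
            continue
        conc = np.asarray(cfg.archetypes[g], dtype=float)
        pos = conc > 0
        if pos.sum() == 1:  # degenerate archetype: all mass on one cell type
            fractions[np.ix_(idx, np.flatnonzero(pos))] = 1.0
        else:
            fractions[np.ix_(idx, np.flatnonzero(pos))] = rng_frac.dirichlet(
                conc[pos], size=idx.size
            )

    # marker genes: mixture through the signature, multiplicative lognormal noise
    marker_lin = sig.values.to_numpy() @ fractions.T
    if cfg.noise_sd > 0:
        marker_lin = marker_lin * np.exp(
            rng_noise.normal(0.0, cfg.noise_sd, size=marker_lin.shape)
        )

    # planted prognostic modules on log2 scale
    module_genes: dict[str, list[str]] = {}
    true_betas: dict[str, float] = {}
    blocks = []
    activities = np.zeros((n, len(cfg.module_spec)))
    for m, (size, beta) in enumerate(cfg.module_spec):
        mid = f"MOD{m + 1}"
        shifts = _module_group_shifts(n_groups, cfg.module_effect, rng_module)
        act = shifts[groups] + rng_module.normal(0.0, 0.5, size=n)
        activities[:, m] = act
        base = rng_module.uniform(3.0, 8.0, size=size)
        vals = base[:, None] + act[None, :] + rng_module.normal(0.0, 0.4, size=(size, n))
        gids = [f"MG_{mid}_{j + 1:03d}" for j in range(size)]
        module_genes[mid] = gids
        true_betas[mid] = float(beta)
        blocks.append(pd.DataFrame(vals, index=gids, columns=samples))

    # unstructured filler genes
    if cfg.n_noise_genes:
        base = rng_module.uniform(2.0, 9.0, size=cfg.n_noise_genes)
        vals = base[:, None] + rng_module.normal(0.0, 0.5, size=(cfg.n_noise_genes, n))
        gids = [f"NG_{j + 1:04d}" for j in range(cfg.n_noise_genes)]
        blocks.append(pd.DataFrame(vals, index=gids, columns=samples))

    log2_part = pd.concat(blocks) if blocks else pd.DataFrame(columns=samples)

    # survival from module-gene mean z-scores (pre-batch, as planted)
    linpred = np.zeros(n)
    for m, (_size, beta) in enumerate(cfg.module_spec):
        block = log2_part.loc[module_genes[f"MOD{m + 1}"]].to_numpy()
        z = (block - block.mean(axis=1, keepdims=True)) / block.std(axis=1, ddof=1, keepdims=True)
        linpred += beta * z.mean(axis=0)
    hazard = cfg.baseline_hazard * np.exp(linpred)
    t_event = rng_surv.exponential(1.0 / hazard)
    t_cens = rng_surv.exponential(1.0 / cfg.censor_rate, size=n)
    os_time = np.minimum(t_event, t_cens)
    os_time = np.maximum(os_time, 1e-3)  # strictly positive months
    os_event = (t_event <= t_cens).astype(int)

    latent = -linpred
    z_latent = (latent - latent.mean()) / (latent.std(ddof=1) or 1.0)

    tmb = np.maximum(0.0, 10.0 + cfg.tmb_link * z_latent + rng_clin.normal(0.0, 2.0, size=n))

    u = z_latent + rng_clin.logistic(0.0, 1.0, size=n)
    cuts = np.quantile(u, RESPONSE_QUANTILES)
    response = np.asarray(RESPONSE_LEVELS)[np.searchsorted(cuts, u)]

    # receptor status mildly linked to the latent score (ER+ enriched among
    # high-score patients), HER2/PR independent
    er = np.where(rng_clin.uniform(size=n) < 1.0 / (1.0 + np.exp(-0.5 * z_latent)), "pos", "neg")
    pr = np.where(rng_clin.uniform(size=n) < 0.5, "pos", "neg")
    her2 = np.where(rng_clin.uniform(size=n) < 0.25, "pos", "neg")

    batches = rng_batch.integers(0, cfg.n_batches, size=n)
    batch_names = np.asarray([f"B{b + 1}" for b in range(cfg.n_batches)])

    # assemble linear expression; module/noise genes come off the log2 scale
    marker_frame = pd.DataFrame(marker_lin, index=sig.marker_genes, columns=samples)
    if len(log2_part):
        expr_lin = pd.concat([marker_frame, np.power(2.0, log2_part) - 1.0])
    else:
        expr_lin = marker_frame
    expr_lin = expr_lin.clip(lower=0.0)

    if cfg.n_batches > 1 and cfg.batch_shift_sd > 0:
        shifts = rng_batch.normal(0.0, cfg.batch_shift_sd, size=(expr_lin.shape[0], cfg.n_batches))
        expr_lin = expr_lin * np.power(2.0, shifts[:, batches])

    expr = ExpressionMatrix(expr_lin, "linear")

    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "os_time": os_time,
            "os_event": os_event,
            "er": er,
            "pr": pr,
            "her2": her2,
            "subtype": [f"TME{chr(ord('A') + g)}" for g in groups],
            "batch": batch_names[batches],
            "tmb": tmb,
            "response": response,
        }
    )

    truth = GroundTruth(
        true_fractions=pd.DataFrame(fractions, index=samples, columns=sig.cell_types),
        true_group=pd.Series(groups, index=samples, name="true_group"),
        true_module_genes=module_genes,
        true_betas=true_betas,
        latent_score=pd.Series(latent, index=samples, name="latent_score"),
    )
    return expr, clinical, truth
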