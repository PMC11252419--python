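"""Synthetic single-cell cohorts with known ground truth.

Emulates the data regime the semi-profiling workflow targets: a cohort of
samples, each a mixture of cell types with sample-specific mixing proportions
and expression shifts; counts drawn from zero-inflated negative binomial
(ZINB) mixtures; matched pseudobulk (per-gene mean of library-normalized
cells); and "real bulk" obtained by applying a systematic gene-wise
multiplicative distortion to the pseudobulk, mimicking the platform
discrepancy observed between bulk sequencing and pseudobulk of the same
sample.

Every quantity downstream stages try to recover (cell-type proportions, the
target pseudobulk, cluster structure) is stored explicitly, so the whole
pipeline is testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "distort_bulk",
    "generate_gene_sets",
    "default_type_profiles",
    "default_condition_shifts",
]


@dataclass
class SyntheticCohortSpec:
    """Parameters of a synthetic cohort.

    Counts for a cell of type *t* in sample *i* are ZINB with mean
    ``type_mean_profiles[t] * condition_shift[c(i)] * sample_shift[i]``,
    gene-shared inverse-dispersion ``dispersion`` and structural-zero
    probability ``dropout_rate``. Proportions are Dirichlet with
    concentration ``proportion_prior``. ``sample_shift_scale`` controls
    per-sample gene-wise log-normal expression shifts: real cohorts differ
    between samples in expression, not only in composition, and this is the
    signal bulk-guided inference and active learning exploit.
    """

    n_samples: int = 16
    n_genes: int = 200
    n_cell_types: int = 3
    cells_per_sample: int = 300
    type_mean_profiles: np.ndarray | None = None  # (n_cell_types, n_genes)
    dispersion: float | np.ndarray = 2.0
    dropout_rate: float = 0.1
    proportion_prior: float | np.ndarray = 2.0
    condition_shifts: np.ndarray | None = None  # (n_conditions, n_genes)
    condition_assignment: np.ndarray | None = None  # per-sample condition id
    sample_shift_scale: float = 0.2
    bulk_bias_scale: float = 0.5
    norm_target: float = 1e4
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_samples, self.n_genes, self.n_cell_types,
               self.cells_per_sample) < 1:
            raise ConfigurationError("all cohort dimensions must be >= 1")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ConfigurationError("dropout_rate must lie in [0, 1]")
        if np.any(np.asarray(self.dispersion) <= 0):
            raise ConfigurationError("dispersion must be positive")
        if self.bulk_bias_scale < 0:
            raise ConfigurationError("bulk_bias_scale must be non-negative")
        if self.type_mean_profiles is not None:
            tm = np.asarray(self.type_mean_profiles)
            if tm.shape != (self.n_cell_types, self.n_genes):
                raise ConfigurationError(
                    f"type_mean_profiles has shape {tm.shape}, expected "
                    f"({self.n_cell_types}, {self.n_genes})")
            if np.any(tm < 0):
                raise ConfigurationError("type mean profiles must be >= 0")
        if self.condition_shifts is not None:
            cs = np.asarray(self.condition_shifts)
            if cs.ndim not in (2, 3) or cs.shape[-1] != self.n_genes:
                raise ConfigurationError(
                    "condition_shifts must be (n_conditions, n_genes) or "
                    "(n_conditions, n_cell_types, n_genes)")
            if cs.ndim == 3 and cs.shape[1] != self.n_cell_types:
                raise ConfigurationError(
                    "type-specific condition_shifts must have n_cell_types rows")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    cell_matrices: list  # per-sample (cells, genes) raw counts
    cell_labels: list  # per-sample integer type ids
    true_proportions: np.ndarray  # empirical label fractions (samples, types)
    drawn_proportions: np.ndarray  # Dirichlet draws the labels came from
    pseudobulk: np.ndarray  # (samples, genes), mean of normalized cells
    real_bulk: np.ndarray  # distorted bulk, same shape
    condition: np.ndarray  # per-sample condition id
    sample_ids: list = field(default_factory=list)
    gene_ids: list = field(default_factory=list)
    norm_target: float = 1e4
    spec: SyntheticCohortSpec | None = None

    @property
    def n_samples(self) -> int:
        return len(self.cell_matrices)

    def normalized_cells(self, i: int) -> np.ndarray:
        """Sample ``i``'s cells scaled to a common library size (not logged)."""
        counts = np.asarray(self.cell_matrices[i], dtype=float)
        lib = counts.sum(axis=1, keepdims=True)
        return counts / lib * self.norm_target


def default_type_profiles(n_cell_types: int, n_genes: int,
                          rng: np.random.Generator,
                          marker_fraction: float = 0.05,
                          marker_boost: float = 8.0) -> np.ndarray:
    """Log-normal base rates with a disjoint boosted marker block per type."""
    base = rng.lognormal(mean=1.0, sigma=1.0, size=n_genes)
    profiles = np.tile(base, (n_cell_types, 1))
    block = max(3, int(marker_fraction * n_genes))
    for t in range(n_cell_types):
        lo = (t * block) % n_genes
        idx = (np.arange(lo, lo + block)) % n_genes
        profiles[t, idx] *= marker_boost
    return profiles


def default_condition_shifts(n_conditions: int, n_genes: int,
                             rng: np.random.Generator,
                             scale: float = 0.8,
                             n_cell_types: int | None = None) -> np.ndarray:
    """Per-condition gene-wise log-normal fold changes (first condition = 1).

    With ``n_cell_types`` given, shifts are cell-type specific
    (``(n_conditions, n_cell_types, n_genes)``): conditions then change each
    cell type's expression differently, as real perturbations do, which a
    single gene-wise bulk scaling cannot fully mimic.
    """
    scales = np.broadcast_to(np.asarray(scale, dtype=float),
                             (n_conditions,))
    if n_cell_types is None:
        shifts = np.ones((n_conditions, n_genes))
        for c in range(1, n_conditions):
            shifts[c] = np.exp(rng.normal(0.0, scales[c], size=n_genes))
        return shifts
    shifts = np.ones((n_conditions, n_cell_types, n_genes))
    for c in range(1, n_conditions):
        shifts[c] = np.exp(rng.normal(0.0, scales[c],
                                      size=(n_cell_types, n_genes)))
    return shifts


def distort_bulk(pseudobulk: np.ndarray, bulk_bias_scale: float, seed: int,
                 noise_scale: float | None = None) -> np.ndarray:
    """Turn pseudobulk into synthetic "real bulk".

    ``real = pseudobulk * exp(g) * exp(eta)`` with ``g`` a gene-wise bias
    shared by all samples (scale ``bulk_bias_scale``) and ``eta`` small
    per-sample, per-gene noise (scale ``noise_scale``, default one tenth of
    the bias scale). The shared ``g`` makes per-gene target/representative
    bulk ratios stable across samples — the assumption the conversion-ratio
    estimator relies on — while ``eta`` lets tests falsify it.
    """
    if bulk_bias_scale < 0:
        raise ConfigurationError("bulk_bias_scale must be non-negative")
    pb = np.atleast_2d(np.asarray(pseudobulk, dtype=float))
    if np.any(pb < 0):
        raise ConfigurationError("pseudobulk must be non-negative")
    if noise_scale is None:
        noise_scale = bulk_bias_scale / 10.0
    if noise_scale < 0:
        raise ConfigurationError("noise_scale must be non-negative")
    rng = np.random.default_rng(seed)
    g = rng.normal(0.0, bulk_bias_scale, size=pb.shape[1]) if bulk_bias_scale else np.zeros(pb.shape[1])
    eta = rng.normal(0.0, noise_scale, size=pb.shape) if noise_scale else np.zeros_like(pb)
    out = pb * np.exp(g)[None, :] * np.exp(eta)
    return out.reshape(np.asarray(pseudobulk).shape)


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Draw a full cohort (cells, labels, pseudobulk, real bulk) from ``spec``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    type_means = (np.asarray(spec.type_mean_profiles, dtype=float)
                  if spec.type_mean_profiles is not None
                  else default_type_profiles(spec.n_cell_types, spec.n_genes, rng))
    cond_shifts = (np.asarray(spec.condition_shifts, dtype=float)
                   if spec.condition_shifts is not None
                   else np.ones((1, spec.n_genes)))
    n_conditions = cond_shifts.shape[0]
    if spec.condition_assignment is not None:
        condition = np.asarray(spec.condition_assignment, dtype=int)
        if condition.shape != (spec.n_samples,) or condition.max() >= n_conditions:
            raise ConfigurationError("invalid condition_assignment")
    else:
        condition = np.arange(spec.n_samples) % n_conditions

    prior = np.asarray(spec.proportion_prior, dtype=float)
    if prior.ndim == 0:
        prior = np.full(spec.n_cell_types, float(prior))
    if prior.shape != (spec.n_cell_types,):
        raise ConfigurationError("proportion_prior must be scalar or per-type")
    drawn = rng.dirichlet(prior, size=spec.n_samples)

    theta = np.broadcast_to(np.asarray(spec.dispersion, dtype=float),
                            (spec.n_genes,)).copy()
    sample_shift = (np.exp(rng.normal(0.0, spec.sample_shift_scale,
                                      size=(spec.n_samples, spec.n_genes)))
                    if spec.sample_shift_scale > 0
                    else np.ones((spec.n_samples, spec.n_genes)))

    matrices, labels_all = [], []
    true_props = np.zeros_like(drawn)
    pseudobulk = np.zeros((spec.n_samples, spec.n_genes))
    for i in range(spec.n_samples):
        labels = rng.choice(spec.n_cell_types, size=spec.cells_per_sample,
                            p=drawn[i])
        cshift = cond_shifts[condition[i]]
        cell_shift = cshift[labels] if cshift.ndim == 2 else cshift[None, :]
        mu = type_means[labels] * cell_shift * sample_shift[i][None, :]
        lam = rng.gamma(shape=theta[None, :], scale=mu / theta[None, :])
        counts = rng.poisson(lam).astype(np.int64)
        if spec.dropout_rate > 0:
            counts[rng.random(counts.shape) < spec.dropout_rate] = 0
        # guarantee positive library sizes for normalization
        empty = counts.sum(axis=1) == 0
        if np.any(empty):
            counts[empty, int(np.argmax(mu.mean(axis=0)))] = 1
        matrices.append(counts)
        labels_all.append(labels)
        true_props[i] = np.bincount(labels, minlength=spec.n_cell_types) / spec.cells_per_sample
        norm = counts / counts.sum(axis=1, keepdims=True) * spec.norm_target
        pseudobulk[i] = norm.mean(axis=0)

    bulk_seed = int(rng.integers(0, 2**31 - 1))
    real_bulk = distort_bulk(pseudobulk, spec.bulk_bias_scale, bulk_seed)

    return SyntheticCohort(
        cell_matrices=matrices,
        cell_labels=labels_all,
        true_proportions=true_props,
        drawn_proportions=drawn,
        pseudobulk=pseudobulk,
        real_bulk=real_bulk,
        condition=condition,
        sample_ids=[f"S{i:03d}" for i in range(spec.n_samples)],
        gene_ids=[f"G{j:04d}" for j in range(spec.n_genes)],
        norm_target=spec.norm_target,
        spec=spec,
    )


def generate_gene_sets(n_sets: int, genes, seed: int,
                       min_size: int = 5, max_size: int = 25) -> dict:
    """Random gene-set collection over the given gene universe.

    A stand-in for curated collections: each set is a unique random subset of
    the universe, reproducible given the seed.
    """
    if n_sets < 1:
        raise ConfigurationError("n_sets must be >= 1")
    genes = list(genes)
    if not genes:
        raise ConfigurationError("gene universe is empty")
    rng = np.random.default_rng(seed)
    hi = min(max_size, len(genes))
    lo = min(min_size, hi)
    sets = {}
    for k in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        sets[f"SET{k:03d}"] = [genes[j] for j in sorted(members)]
    return sets
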