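"""Representative single-cell processing: background-noise removal, quality
control, normalization, gene-set scores, feature-importance weights, and
K-nearest-neighbour aggregation.

The fixed pipeline order is: background removal -> cell/gene QC ->
normalization -> alignment to the bulk HVG panel -> gene-set scores ->
feature weights -> neighbour aggregation. ``augment_sample`` runs the whole
chain and returns the augmented feature matrices the generative model
consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigurationError, DataError

__all__ = [
    "CellSample",
    "AugmentedCells",
    "QCConfig",
    "remove_background",
    "qc_filter",
    "normalize_log",
    "geneset_scores",
    "feature_weights",
    "neighbor_aggregate",
    "augment_sample",
]


@dataclass
class QCConfig:
    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    max_mito_fraction: float = 0.20
    max_genes_doublet: int = 6000
    min_cells_per_sample: int = 1000
    noise_fraction: float = 0.001
    norm_target: float = 1e4
    knn_k: int = 15
    mito_prefixes: tuple = ("MT-",)

    def validate(self) -> None:
        if min(self.min_genes_per_cell, self.min_cells_per_gene,
               self.max_genes_doublet, self.min_cells_per_sample) < 0:
            raise ConfigurationError("QC thresholds must be >= 0")
        if not 0 <= self.noise_fraction < 1:
            raise ConfigurationError("noise_fraction must lie in [0, 1)")
        if self.max_mito_fraction < 0 or self.norm_target <= 0 or self.knn_k < 0:
            raise ConfigurationError("invalid QC configuration")


@dataclass
class CellSample:
    """One sample's cells x genes counts plus derived matrices."""

    counts: np.ndarray
    sample_id: str = "sample"
    gene_ids: list = field(default_factory=list)
    labels: np.ndarray | None = None  # per-cell type
    norm: np.ndarray | None = None  # library-normalized counts (pre-log)
    norm_log: np.ndarray | None = None
    library_sizes: np.ndarray | None = None  # row sums before normalization
    flagged_low_cells: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if not self.gene_ids:
            self.gene_ids = [f"G{j:04d}" for j in range(self.counts.shape[1])]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]


@dataclass
class AugmentedCells:
    """Concatenated (expression, gene-set score) features for one sample."""

    features: np.ndarray  # (cells, n_genes + n_sets), log1p expression ++ scores
    aggregated: np.ndarray  # same shape, self-inclusive KNN mean
    weights: np.ndarray  # per-feature, positive, mean 1 (floored)
    n_genes: int
    n_sets: int
    norm_counts: np.ndarray  # (cells, n_genes) library-normalized, pre-log
    sample_id: str = "sample"
    gene_ids: list = field(default_factory=list)
    set_names: list = field(default_factory=list)
    labels: np.ndarray | None = None
    norm_target: float = 1e4

    @property
    def n_cells(self) -> int:
        return self.features.shape[0]

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-cell total of the modeled (HVG-aligned) normalized counts."""
        return self.norm_counts.sum(axis=1)

    def pseudobulk(self) -> np.ndarray:
        return self.norm_counts.mean(axis=0)


def remove_background(counts: np.ndarray, noise_fraction: float = 0.001) -> np.ndarray:
    """Zero out entries strictly below ``noise_fraction`` of the cell's
    library size; entries at the threshold are kept."""
    if not 0 <= noise_fraction < 1:
        raise ConfigurationError("noise_fraction must lie in [0, 1)")
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise DataError("counts must be non-negative")
    thresh = counts.sum(axis=1, keepdims=True) * noise_fraction
    out = counts.copy()
    out[counts < thresh] = 0.0
    return out


def qc_filter(sample: CellSample, cfg: QCConfig | None = None) -> CellSample:
    """Standard cell/gene quality control.

    Removes cells expressing fewer than ``min_genes_per_cell`` genes, cells
    with mitochondrial fraction or expressed-gene count above the dying-cell
    / doublet limits, and genes seen in fewer than ``min_cells_per_gene``
    cells. Samples left with fewer than ``min_cells_per_sample`` cells are
    flagged, not dropped.
    """
    cfg = cfg or QCConfig()
    cfg.validate()
    counts = sample.counts
    genes_per_cell = (counts > 0).sum(axis=1)
    mito = np.array([any(g.upper().startswith(p) for p in cfg.mito_prefixes)
                     for g in sample.gene_ids])
    lib = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(lib > 0, counts[:, mito].sum(axis=1) / np.maximum(lib, 1), 0.0)
    keep_cells = ((genes_per_cell >= cfg.min_genes_per_cell)
                  & (mito_frac <= cfg.max_mito_fraction)
                  & (genes_per_cell <= cfg.max_genes_doublet))
    counts = counts[keep_cells]
    if counts.shape[0] == 0:
        raise DataError(f"QC removed every cell of sample {sample.sample_id}")
    cells_per_gene = (counts > 0).sum(axis=0)
    keep_genes = cells_per_gene >= cfg.min_cells_per_gene
    counts = counts[:, keep_genes]
    if counts.shape[1] == 0:
        raise DataError(f"QC removed every gene of sample {sample.sample_id}")
    out = CellSample(
        counts=counts,
        sample_id=sample.sample_id,
        gene_ids=[g for g, k in zip(sample.gene_ids, keep_genes) if k],
        labels=None if sample.labels is None else np.asarray(sample.labels)[keep_cells],
    )
    out.flagged_low_cells = counts.shape[0] < cfg.min_cells_per_sample
    if out.flagged_low_cells:
        warnings.warn(
            f"sample {sample.sample_id} has {counts.shape[0]} cells "
            f"(< {cfg.min_cells_per_sample}); flagged as low quality")
    return out


def normalize_log(sample: CellSample, norm_target: float = 1e4) -> CellSample:
    """Scale each cell to ``norm_target`` total counts, then log1p."""
    lib = sample.counts.sum(axis=1)
    if np.any(lib == 0):
        raise DataError(
            f"sample {sample.sample_id} has a zero-library cell after filtering")
    sample.library_sizes = lib
    sample.norm = sample.counts / lib[:, None] * norm_target
    sample.norm_log = np.log1p(sample.norm)
    return sample


def geneset_scores(sample: CellSample, gene_sets: dict) -> np.ndarray:
    """Per-cell gene-set scores: mean of the set's library-normalized
    (pre-log) expression values, then log1p. Sets with no member among the
    sample's genes score 0 (with a warning)."""
    if sample.norm is None:
        raise DataError("normalize_log must run before gene-set scoring")
    gene_index = {g: j for j, g in enumerate(sample.gene_ids)}
    scores = np.zeros((sample.n_cells, len(gene_sets)))
    for k, (name, members) in enumerate(gene_sets.items()):
        idx = [gene_index[g] for g in members if g in gene_index]
        if not idx:
            warnings.warn(f"gene set {name!r} has no member in the data; score 0")
            continue
        scores[:, k] = np.log1p(sample.norm[:, idx].mean(axis=1))
    return scores


def feature_weights(features: np.ndarray, floor: float = 0.01) -> np.ndarray:
    """Per-feature weights proportional to variance across cells, rescaled to
    mean 1 and floored at ``floor`` so no feature loses its gradient."""
    features = np.asarray(features, dtype=float)
    if features.shape[0] < 2:
        raise ConfigurationError("feature weights need at least 2 cells")
    var = features.var(axis=0)
    mean_var = var.mean()
    w = var / mean_var if mean_var > 0 else np.ones_like(var)
    return np.maximum(w, floor)


def neighbor_aggregate(features: np.ndarray, K: int = 15) -> np.ndarray:
    """Mean over each cell and its K nearest neighbours (Euclidean, in
    feature space); computed once, before model training. ``K=0`` is the
    identity."""
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if K < 0 or K >= n:
        raise ConfigurationError(f"K={K} must satisfy 0 <= K < n_cells={n}")
    if K == 0:
        return features.copy()
    nn = NearestNeighbors(n_neighbors=K + 1).fit(features)
    _, idx = nn.kneighbors(features)  # first neighbour is the cell itself
    return features[idx].mean(axis=1)


def augment_sample(sample: CellSample, gene_sets: dict,
                   cfg: QCConfig | None = None,
                   hvg_genes=None) -> AugmentedCells:
    """Run the full processing chain and build the model-ready features."""
    cfg = cfg or QCConfig()
    cfg.validate()
    cleaned = CellSample(
        counts=remove_background(sample.counts, cfg.noise_fraction),
        sample_id=sample.sample_id, gene_ids=list(sample.gene_ids),
        labels=sample.labels)
    cleaned = qc_filter(cleaned, cfg)
    cleaned = normalize_log(cleaned, cfg.norm_target)
    if hvg_genes is not None:
        keep = [g for g in hvg_genes if g in set(cleaned.gene_ids)]
        idx = [cleaned.gene_ids.index(g) for g in keep]
        cleaned.counts = cleaned.counts[:, idx]
        cleaned.norm = cleaned.norm[:, idx]
        cleaned.norm_log = cleaned.norm_log[:, idx]
        cleaned.gene_ids = keep
    scores = geneset_scores(cleaned, gene_sets)
    features = np.concatenate([cleaned.norm_log, scores], axis=1)
    # weights live on the scale of the likelihood targets: normalized counts
    # for genes, scores for gene sets. On count scale, high-expression genes
    # get proportionally large weights, which offsets the near-flatness of
    # the overdispersed NB likelihood in its mean for large values.
    weights = feature_weights(np.concatenate([cleaned.norm, scores], axis=1))
    K = min(cfg.knn_k, cleaned.n_cells - 1)
    aggregated = neighbor_aggregate(features, K)
    return AugmentedCells(
        features=features,
        aggregated=aggregated,
        weights=weights,
        n_genes=cleaned.norm.shape[1],
        n_sets=scores.shape[1],
        norm_counts=cleaned.norm,
        sample_id=sample.sample_id,
        gene_ids=list(cleaned.gene_ids),
        set_names=list(gene_sets.keys()),
        labels=cleaned.labels,
        norm_target=cfg.norm_target,
    )
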