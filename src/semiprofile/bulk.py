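"""Bulk-cohort workflow: normalization, feature selection, PCA embedding,
clustering, and representative selection.

The cohort's bulk RNA-seq profiles are library-normalized and log1p
transformed, reduced to highly variable genes, embedded with PCA
(``min(100, n_samples - 1)`` components), and clustered with K-means; the
sample closest to each cluster centroid becomes that cluster's
representative for real single-cell sequencing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import scanpy as sc
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .errors import ConfigurationError, DataError

__all__ = [
    "BulkCohort",
    "BulkEmbedding",
    "CohortState",
    "preprocess_bulk",
    "select_features",
    "embed_bulk",
    "initial_representatives",
    "global_mode_select",
]

DEFAULT_NORM_TARGET = 1e4
DEFAULT_N_HVG = 6000


@dataclass
class BulkCohort:
    counts: np.ndarray  # (samples, genes) raw
    norm_log: np.ndarray  # library-normalized, log1p
    sample_ids: list
    gene_ids: list
    hvg_mask: np.ndarray | None = None  # boolean per gene

    def index_of(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)


@dataclass
class BulkEmbedding:
    coords: np.ndarray  # (samples, n_pcs)
    n_pcs: int
    explained_variance: np.ndarray
    sample_ids: list = field(default_factory=list)

    def coord(self, sample_id: str) -> np.ndarray:
        return self.coords[self.sample_ids.index(sample_id)]


@dataclass
class CohortState:
    """Current representative set Rs and per-sample assignment R(i)."""

    representatives: list  # ordered sample ids
    assignment: dict  # sample id -> representative id
    batch_size: int
    round: int = 0

    def is_representative(self, sample_id: str) -> bool:
        return sample_id in self.representatives

    def validate(self) -> None:
        for r in self.representatives:
            if self.assignment.get(r) != r:
                raise DataError(f"representative {r} not assigned to itself")
        for s, r in self.assignment.items():
            if r not in self.representatives:
                raise DataError(f"sample {s} assigned to non-representative {r}")


def preprocess_bulk(counts: np.ndarray, sample_ids=None, gene_ids=None,
                    norm_target: float = DEFAULT_NORM_TARGET) -> BulkCohort:
    """Library-size normalize each sample to ``norm_target`` and log1p."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise DataError("bulk counts must be a samples x genes matrix")
    if np.any(counts < 0):
        raise DataError("bulk counts must be non-negative")
    sample_ids = list(sample_ids) if sample_ids is not None else [
        f"S{i:03d}" for i in range(counts.shape[0])]
    gene_ids = list(gene_ids) if gene_ids is not None else [
        f"G{j:04d}" for j in range(counts.shape[1])]
    if len(set(sample_ids)) != len(sample_ids):
        raise DataError("sample_ids must be unique")
    libs = counts.sum(axis=1)
    if np.any(libs == 0):
        bad = sample_ids[int(np.argmin(libs))]
        raise DataError(f"sample {bad} has an all-zero bulk profile")
    norm_log = np.log1p(counts / libs[:, None] * norm_target)
    return BulkCohort(counts=counts, norm_log=norm_log,
                      sample_ids=sample_ids, gene_ids=gene_ids)


def select_features(bulk: BulkCohort, n_hvg: int = DEFAULT_N_HVG,
                    forced_markers=()) -> np.ndarray:
    """Top-``n_hvg`` genes by Seurat-style mean-binned normalized dispersion,
    united with any forced marker genes; stores and returns the mask."""
    if n_hvg < 1:
        raise ConfigurationError("n_hvg must be >= 1")
    gene_index = {g: j for j, g in enumerate(bulk.gene_ids)}
    forced_idx = []
    for m in forced_markers:
        if m not in gene_index:
            raise DataError(f"forced marker {m!r} not among gene_ids")
        forced_idx.append(gene_index[m])

    n_genes = len(bulk.gene_ids)
    if n_hvg >= n_genes:
        mask = np.ones(n_genes, dtype=bool)
    else:
        adata = ad.AnnData(X=bulk.norm_log.copy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.highly_variable_genes(adata, n_top_genes=n_hvg,
                                        flavor="seurat", n_bins=20)
        mask = np.asarray(adata.var["highly_variable"], dtype=bool)
    mask[forced_idx] = True
    bulk.hvg_mask = mask
    return mask


def embed_bulk(bulk: BulkCohort, n_pcs: int | None = None) -> BulkEmbedding:
    """PCA of the HVG-masked normalized log expression.

    Uses ``min(100, n_samples - 1)`` components; the sign of each component
    is fixed so its largest-magnitude loading is positive.
    """
    X = bulk.norm_log
    if bulk.hvg_mask is not None:
        X = X[:, bulk.hvg_mask]
    n_samples = X.shape[0]
    if n_samples < 2:
        raise DataError("PCA embedding needs at least 2 samples")
    if n_pcs is None:
        n_pcs = min(100, n_samples - 1)
    n_pcs = min(n_pcs, n_samples - 1, X.shape[1])
    pca = PCA(n_components=n_pcs, svd_solver="full")
    coords = pca.fit_transform(X)
    flip = np.sign(pca.components_[
        np.arange(n_pcs), np.argmax(np.abs(pca.components_), axis=1)])
    flip[flip == 0] = 1.0
    coords = coords * flip[None, :]
    return BulkEmbedding(coords=coords, n_pcs=n_pcs,
                         explained_variance=pca.explained_variance_,
                         sample_ids=list(bulk.sample_ids))


def _representative_of_cluster(coords, members, centroid):
    d = np.linalg.norm(coords[members] - centroid[None, :], axis=1)
    return members[int(np.argmin(d))]  # argmin ties -> lowest index


def initial_representatives(emb: BulkEmbedding, B: int, seed: int = 0) -> CohortState:
    """K-means the embedding into ``B`` clusters; each cluster's sample
    closest to the centroid becomes its representative."""
    n = emb.coords.shape[0]
    if not 1 <= B <= n:
        raise ConfigurationError(f"B={B} out of range [1, {n}]")
    km = KMeans(n_clusters=B, n_init=10, random_state=seed)
    labels = km.fit_predict(emb.coords)
    reps, assignment = [], {}
    for c in range(B):
        members = np.flatnonzero(labels == c)
        rep_idx = _representative_of_cluster(emb.coords, members,
                                             km.cluster_centers_[c])
        rep = emb.sample_ids[rep_idx]
        reps.append(rep)
        for i in members:
            assignment[emb.sample_ids[i]] = rep
    state = CohortState(representatives=reps, assignment=assignment,
                        batch_size=B, round=0)
    state.validate()
    return state


def global_mode_select(emb: BulkEmbedding, candidate_Bs, seed: int = 0,
                       chosen_B: int | None = None):
    """Silhouette score for each candidate batch size, plus the cohort state
    at the chosen (or best-scoring) one."""
    candidate_Bs = sorted(set(int(b) for b in candidate_Bs))
    n = emb.coords.shape[0]
    if not candidate_Bs:
        raise ConfigurationError("no candidate batch sizes given")
    if any(b < 2 or b > n - 1 for b in candidate_Bs):
        raise ConfigurationError("candidate Bs must lie in [2, n_samples - 1]")
    scores = {}
    for b in candidate_Bs:
        labels = KMeans(n_clusters=b, n_init=10,
                        random_state=seed).fit_predict(emb.coords)
        scores[b] = float(silhouette_score(emb.coords, labels))
    if chosen_B is None:
        chosen_B = max(scores, key=lambda b: (scores[b], -b))
    state = initial_representatives(emb, chosen_B, seed=seed)
    return scores, state
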