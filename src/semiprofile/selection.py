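"""Representative selection: passive uncertainty sampling and the
heterogeneity-driven active-learning algorithm, plus the stop criteria.

Passive selection repeatedly promotes the sample farthest (in bulk PCA
space) from its current representative. Active selection instead scores
whole clusters by their total heterogeneity — the sum over members of
``D_b + lambda_sc * D_sc + lambda_pb * D_pb`` (bulk embedding distance,
directional single-cell KNN distance, log1p-pseudobulk distance) — splits
the most heterogeneous clusters, and inside each picks the new
representative that minimizes the total bulk distance of members to their
nearest of (old, new) representative. After any selection, every sample is
reassigned to its bulk-nearest representative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .bulk import BulkEmbedding, CohortState
from .errors import ConfigurationError, DataError

__all__ = [
    "HeterogeneityConfig",
    "SelectionRound",
    "StopDecision",
    "bulk_distance",
    "sc_distance",
    "pb_distance",
    "sample_heterogeneity",
    "cluster_heterogeneity_table",
    "cohort_difficulty",
    "passive_select",
    "active_select",
    "update_membership",
    "check_stop",
]


@dataclass
class HeterogeneityConfig:
    lambda_sc: float = 1.0
    lambda_pb: float = 1.0
    knn_k: int = 1
    batch_size: int = 4

    def validate(self) -> None:
        if self.lambda_sc < 0 or self.lambda_pb < 0:
            raise ConfigurationError("lambda scaling factors must be >= 0")
        if self.knn_k < 1 or self.batch_size < 1:
            raise ConfigurationError("K and batch size must be >= 1")


@dataclass
class SelectionRound:
    new_representatives: list
    state: CohortState
    cluster_table: pd.DataFrame
    difficulty: float  # mean D_sc(R(i), i) over the cohort


@dataclass
class StopDecision:
    level: int
    correlations: dict
    mean_correlation: float
    stop: bool
    threshold: float = 0.85


def bulk_distance(i: str, j: str, emb: BulkEmbedding) -> float:
    """Euclidean distance between two samples' PCA-reduced bulk profiles."""
    for s in (i, j):
        if s not in emb.sample_ids:
            raise DataError(f"unknown sample {s!r}")
    return float(np.linalg.norm(emb.coord(i) - emb.coord(j)))


def sc_distance(a: np.ndarray, b: np.ndarray, K: int = 1) -> float:
    """Directional single-cell distance from sample a to sample b.

    ``(1/N_a) * sum_i sum_{j in KNN_b(i)} ED(v_a_i, v_b_j)`` with both cell
    matrices already reduced in a joint PCA space.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    if K >= b.shape[0] + 1:
        raise ConfigurationError(f"K={K} must not exceed N_b={b.shape[0]}")
    nn = NearestNeighbors(n_neighbors=K).fit(b)
    dist, _ = nn.kneighbors(a)
    return float(dist.sum() / a.shape[0])


def pb_distance(pb_a: np.ndarray, pb_b: np.ndarray) -> float:
    """Euclidean distance of log1p-transformed pseudobulk vectors."""
    pb_a = np.asarray(pb_a, float)
    pb_b = np.asarray(pb_b, float)
    if pb_a.shape != pb_b.shape:
        raise DataError("pseudobulk dimension mismatch")
    return float(np.linalg.norm(np.log1p(pb_a) - np.log1p(pb_b)))


def sample_heterogeneity(i: str, state: CohortState, emb: BulkEmbedding,
                         sc_coords: dict | None = None,
                         pseudobulks: dict | None = None,
                         cfg: HeterogeneityConfig | None = None) -> float:
    """Combined distance of sample ``i`` to its representative; 0 for
    representatives themselves."""
    cfg = cfg or HeterogeneityConfig()
    cfg.validate()
    if state.is_representative(i):
        return 0.0
    r = state.assignment[i]
    h = bulk_distance(r, i, emb)
    if cfg.lambda_sc > 0:
        if sc_coords is None or i not in sc_coords or r not in sc_coords:
            raise DataError(f"missing single-cell estimate for {i!r} or {r!r}")
        h += cfg.lambda_sc * sc_distance(sc_coords[r], sc_coords[i], cfg.knn_k)
    if cfg.lambda_pb > 0:
        if pseudobulks is None or i not in pseudobulks or r not in pseudobulks:
            raise DataError(f"missing pseudobulk for {i!r} or {r!r}")
        h += cfg.lambda_pb * pb_distance(pseudobulks[r], pseudobulks[i])
    return float(h)


def cluster_heterogeneity_table(state: CohortState, emb: BulkEmbedding,
                                sc_coords=None, pseudobulks=None,
                                cfg: HeterogeneityConfig | None = None) -> pd.DataFrame:
    cfg = cfg or HeterogeneityConfig()
    rows = []
    for rep in state.representatives:
        members = [s for s, r in state.assignment.items() if r == rep]
        het = sum(sample_heterogeneity(s, state, emb, sc_coords, pseudobulks, cfg)
                  for s in members)
        rows.append({"representative": rep, "n_members": len(members),
                     "heterogeneity": het})
    return pd.DataFrame(rows)


def cohort_difficulty(state: CohortState, sc_coords: dict, K: int = 1) -> float:
    """Mean directional single-cell distance of each sample to its
    representative (representatives contribute 0)."""
    vals = []
    for s, r in state.assignment.items():
        vals.append(0.0 if s == r else sc_distance(sc_coords[r], sc_coords[s], K))
    return float(np.mean(vals))


def update_membership(state: CohortState, emb: BulkEmbedding) -> CohortState:
    """Reassign every sample to its closest representative (ties broken by
    the lowest sample index)."""
    if not state.representatives:
        raise DataError("no representatives to assign to")
    reps_by_index = sorted(state.representatives, key=emb.sample_ids.index)
    assignment = {}
    for s in emb.sample_ids:
        d = [bulk_distance(r, s, emb) for r in reps_by_index]
        assignment[s] = reps_by_index[int(np.argmin(d))]
    new_state = CohortState(representatives=list(state.representatives),
                            assignment=assignment,
                            batch_size=state.batch_size,
                            round=state.round)
    new_state.validate()
    return new_state


def passive_select(state: CohortState, emb: BulkEmbedding, B: int) -> tuple:
    """Pick B new representatives by iterated argmax of bulk distance to the
    current representative, updating membership after each pick."""
    state = update_membership(state, emb)
    picked = []
    for _ in range(B):
        candidates = [s for s in emb.sample_ids
                      if s not in state.representatives]
        if not candidates:
            warnings.warn("cohort exhausted: fewer representatives than requested")
            break
        dists = [bulk_distance(state.assignment[s], s, emb) for s in candidates]
        new_rep = candidates[int(np.argmax(dists))]
        picked.append(new_rep)
        state = CohortState(representatives=state.representatives + [new_rep],
                            assignment=state.assignment,
                            batch_size=state.batch_size,
                            round=state.round + 1)
        state = update_membership(state, emb)
    return picked, state


def active_select(state: CohortState, emb: BulkEmbedding, sc_coords: dict,
                  pseudobulks: dict,
                  cfg: HeterogeneityConfig | None = None) -> SelectionRound:
    """One active-learning round: split the most heterogeneous clusters.

    Clusters are ranked by total member heterogeneity (bulk + single-cell +
    pseudobulk distances to the representative); within each of the top-B
    splittable clusters the new representative minimizes the total bulk
    distance of members to the nearer of (old representative, candidate).
    """
    cfg = cfg or HeterogeneityConfig()
    cfg.validate()
    state = update_membership(state, emb)
    table = cluster_heterogeneity_table(state, emb, sc_coords, pseudobulks, cfg)
    new_reps = []
    # split one cluster at a time so a large cluster may be split repeatedly
    # when fewer than B distinct clusters are splittable
    for _ in range(cfg.batch_size):
        table = cluster_heterogeneity_table(state, emb, sc_coords,
                                            pseudobulks, cfg)
        splittable = table[(table.n_members > 1) & (table.heterogeneity > 0)]
        if splittable.empty:
            if not new_reps:
                warnings.warn("no splittable cluster; returning empty selection")
            break
        rep = splittable.sort_values("heterogeneity",
                                     ascending=False).representative.iloc[0]
        members = [s for s, r in state.assignment.items() if r == rep]
        candidates = sorted((s for s in members if s != rep),
                            key=emb.sample_ids.index)
        scores = [sum(min(bulk_distance(j, i, emb), bulk_distance(rep, i, emb))
                      for i in members) for j in candidates]
        new_rep = candidates[int(np.argmin(scores))]
        new_reps.append(new_rep)
        state = CohortState(representatives=state.representatives + [new_rep],
                            assignment=state.assignment,
                            batch_size=state.batch_size,
                            round=state.round)
        state = update_membership(state, emb)
    state = CohortState(representatives=list(state.representatives),
                        assignment=state.assignment,
                        batch_size=state.batch_size,
                        round=state.round + 1)
    state = update_membership(state, emb)
    difficulty = cohort_difficulty(state, sc_coords, cfg.knn_k)
    table = cluster_heterogeneity_table(state, emb, sc_coords, pseudobulks, cfg)
    return SelectionRound(new_reps, state, table, difficulty)


def check_stop(semi_profiled_prev: dict, real_profiled_new: dict,
               level: int = 1, threshold: float = 0.85) -> StopDecision:
    """Compare the previous round's inferred data with the newly sequenced
    real data for the same samples.

    Level 1 compares cell-type proportion vectors, level 2 marker dot-plot
    summaries (sizes/colors), level 3 downstream analysis matrices; in all
    cases via Pearson correlation of the flattened arrays, stopping when the
    mean correlation reaches the threshold.
    """
    if level not in (1, 2, 3):
        raise ConfigurationError("level must be 1, 2 or 3")
    shared = [s for s in real_profiled_new if s in semi_profiled_prev]
    if not shared:
        raise DataError("no overlapping newly sequenced samples")
    corr = {}
    for s in shared:
        a = np.asarray(semi_profiled_prev[s], float).ravel()
        b = np.asarray(real_profiled_new[s], float).ravel()
        if a.shape != b.shape:
            raise DataError(f"shape mismatch for sample {s!r}")
        corr[s] = (1.0 if np.allclose(a, b) and a.std() == 0
                   else float(stats.pearsonr(a, b)[0]))
    mean_corr = float(np.mean(list(corr.values())))
    return StopDecision(level=level, correlations=corr,
                        mean_correlation=mean_corr,
                        stop=mean_corr >= threshold, threshold=threshold)
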