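"""Evaluation of semi-profiling fidelity and cost.

Core fidelity metric: the bidirectional K-nearest-neighbour distance
``Dif_sc`` between two single-cell matrices in a shared PCA space, and the
cohort-level normalized error ``E_N = (mean Dif_sc - LB) / (UB - LB)``
where the upper bound UB is the mean ``Dif_sc`` of randomly paired samples
(the worst, random, representative selection) and the lower bound LB the
``Dif_sc`` between two random halves of the pooled cells (two in-silico
replicates of the same study). Also implements deconvolution metrics
(Lin's CCC, Pearson, RMSE), an MLP cell-type annotator, gene-set activation
fold-change matrices, rank-rank hypergeometric overlap (RRHO), grid-binned
summary correlations for 2-D embeddings, and the sequencing cost model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier

from .errors import ConfigurationError, DataError

__all__ = [
    "EvalConfig",
    "CostModel",
    "joint_pca",
    "difsc",
    "directed_knn_distance",
    "upper_bound",
    "lower_bound",
    "normalized_error",
    "annotate_cells",
    "proportion_metrics",
    "activation_matrix",
    "rrho_matrix",
    "grid_summary_correlation",
    "cost_estimate",
    "validate_global_mode",
]


@dataclass
class EvalConfig:
    knn_k: int = 1
    n_pcs: int = 100
    ub_pairings: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.knn_k < 1 or self.n_pcs < 1 or self.ub_pairings < 1:
            raise ConfigurationError("invalid evaluation configuration")


@dataclass
class CostModel:
    """Sequencing cost assumptions (USD)."""

    run_cost: float = 7000.0  # one bulk sequencing run
    library_cost: float = 110.0  # library preparation per bulk sample
    per_cell: float = 0.3
    cells_per_sample: int = 5000


def joint_pca(matrices, n_pcs: int = 100):
    """Reduce several cells x features matrices in one shared PCA space.

    Fit on the row-wise union; returns the same container type (list or
    dict) with reduced matrices.
    """
    items = list(matrices.items()) if isinstance(matrices, dict) else list(enumerate(matrices))
    stacked = np.vstack([np.asarray(m, dtype=float) for _, m in items])
    n_pcs = min(n_pcs, stacked.shape[1], stacked.shape[0] - 1)
    pca = PCA(n_components=n_pcs, svd_solver="auto", random_state=0)
    red = pca.fit_transform(stacked)
    out, lo = [], 0
    for key, m in items:
        n = np.asarray(m).shape[0]
        out.append((key, red[lo:lo + n]))
        lo += n
    return dict(out) if isinstance(matrices, dict) else [m for _, m in out]


def directed_knn_distance(a: np.ndarray, b: np.ndarray, K: int = 1) -> float:
    """Sum over cells of ``a`` of distances to their K nearest cells in ``b``."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if K >= b.shape[0] + 1 or K < 1:
        raise ConfigurationError(f"K={K} must satisfy 1 <= K <= {b.shape[0]}")
    nn = NearestNeighbors(n_neighbors=K).fit(b)
    dist, _ = nn.kneighbors(a)
    return float(dist.sum())


def difsc(m_a: np.ndarray, m_b: np.ndarray, cfg: EvalConfig | None = None) -> float:
    """Symmetric single-cell difference between two matrices in a shared
    PCA space: both directed KNN distance sums divided by ``N_a + N_b``."""
    cfg = cfg or EvalConfig()
    cfg.validate()
    m_a = np.atleast_2d(np.asarray(m_a, float))
    m_b = np.atleast_2d(np.asarray(m_b, float))
    if cfg.knn_k >= min(m_a.shape[0], m_b.shape[0]) + 1:
        raise ConfigurationError("K must not exceed either matrix's cell count")
    total = (directed_knn_distance(m_a, m_b, cfg.knn_k)
             + directed_knn_distance(m_b, m_a, cfg.knn_k))
    return total / (m_a.shape[0] + m_b.shape[0])


def upper_bound(real_matrices, cfg: EvalConfig | None = None) -> float:
    """Mean ``Dif_sc`` over seeded random sample pairings (the expected
    error of a random representative assignment)."""
    cfg = cfg or EvalConfig()
    mats = list(real_matrices.values()) if isinstance(real_matrices, dict) else list(real_matrices)
    if len(mats) < 2:
        raise DataError("upper bound needs at least 2 samples")
    rng = np.random.default_rng(cfg.seed)
    vals = []
    for _ in range(cfg.ub_pairings):
        i, j = rng.choice(len(mats), size=2, replace=False)
        vals.append(difsc(mats[i], mats[j], cfg))
    return float(np.mean(vals))


def lower_bound(all_cells: np.ndarray, cfg: EvalConfig | None = None) -> float:
    """``Dif_sc`` between two seeded random halves of the pooled cells."""
    cfg = cfg or EvalConfig()
    all_cells = np.asarray(all_cells, dtype=float)
    if all_cells.shape[0] < 2:
        raise DataError("lower bound needs at least 2 pooled cells")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(all_cells.shape[0])
    half = all_cells.shape[0] // 2
    return difsc(all_cells[order[:half]], all_cells[order[half:]], cfg)


def normalized_error(per_sample_difsc: dict, representatives, UB: float,
                     LB: float) -> float:
    """Cohort error scaled between the random-pairing upper bound and the
    split-half lower bound; representatives contribute LB by definition."""
    if UB <= LB:
        raise DataError("degenerate normalization: UB must exceed LB")
    reps = set(representatives)
    vals = [LB if sid in reps else v for sid, v in per_sample_difsc.items()]
    if not vals:
        raise DataError("no samples to evaluate")
    return float((np.mean(vals) - LB) / (UB - LB))


def annotate_cells(rep_features: np.ndarray, rep_labels, generated_features: np.ndarray,
                   seed: int = 0, hidden: tuple = (64,), max_iter: int = 500):
    """Cell-type annotation: an MLP classifier trained on the
    representatives' labelled cells, applied to generated cells."""
    rep_labels = np.asarray(rep_labels)
    if len(np.unique(rep_labels)) < 2:
        raise DataError("annotation needs at least 2 labelled classes")
    clf = MLPClassifier(hidden_layer_sizes=hidden, max_iter=max_iter,
                        random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(np.asarray(rep_features, float), rep_labels)
    return clf.predict(np.asarray(generated_features, float))


def _ccc(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.var(), y.var()
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    denom = sx + sy + (x.mean() - y.mean()) ** 2
    return float(2 * sxy / denom) if denom > 0 else np.nan


def proportion_metrics(true_props: np.ndarray, est_props: np.ndarray) -> pd.DataFrame:
    """Per-sample Lin's CCC, Pearson r and RMSE between estimated and true
    cell-type proportion vectors. Zero-variance vectors yield NaN for the
    correlation metrics."""
    t = np.atleast_2d(np.asarray(true_props, float))
    e = np.atleast_2d(np.asarray(est_props, float))
    if t.shape != e.shape:
        raise DataError("proportion matrices must have matching shapes")
    rows = []
    for i in range(t.shape[0]):
        x, y = t[i], e[i]
        if x.std() == 0 or y.std() == 0:
            r = np.nan
            ccc = np.nan
        else:
            r = float(stats.pearsonr(x, y)[0])
            ccc = _ccc(x, y)
        rows.append({"sample": i, "ccc": ccc, "pearson": r,
                     "rmse": float(np.sqrt(np.mean((x - y) ** 2)))})
    return pd.DataFrame(rows)


def activation_matrix(cells: np.ndarray, labels, conditions, gene_set,
                      gene_ids, reference_condition, min_cells: int = 500) -> pd.DataFrame:
    """Gene-set activation fold changes per (cell type, condition).

    Mean gene-set expression per group, expressed as fold change versus the
    reference condition within each cell type; entries backed by fewer than
    ``min_cells`` cells are left blank (NaN).
    """
    if len(gene_set) == 0:
        raise DataError("gene set is empty")
    labels = np.asarray(labels)
    conditions = np.asarray(conditions)
    if reference_condition not in set(conditions.tolist()):
        raise DataError(f"unknown reference condition {reference_condition!r}")
    gene_index = {g: j for j, g in enumerate(gene_ids)}
    idx = [gene_index[g] for g in gene_set if g in gene_index]
    if not idx:
        raise DataError("gene set has no member among gene_ids")
    set_expr = np.asarray(cells, float)[:, idx].mean(axis=1)
    types = sorted(set(labels.tolist()))
    conds = sorted(set(conditions.tolist()))
    means = pd.DataFrame(index=types, columns=conds, dtype=float)
    counts = pd.DataFrame(0, index=types, columns=conds, dtype=int)
    for t in types:
        for c in conds:
            mask = (labels == t) & (conditions == c)
            counts.loc[t, c] = int(mask.sum())
            if mask.sum() >= min_cells:
                means.loc[t, c] = set_expr[mask].mean()
    out = means.divide(means[reference_condition], axis=0)
    out[means.isna()] = np.nan
    return out


def rrho_matrix(ranked_list_a, ranked_list_b, universe_size: int,
                step: int = 1) -> np.ndarray:
    """Rank-rank hypergeometric overlap matrix.

    Entry (i, j) is ``-log10 P(X >= k)`` for the overlap k between the top
    ``(i+1)*step`` genes of list A and top ``(j+1)*step`` of list B, under a
    hypergeometric draw from a universe of ``universe_size`` genes.
    """
    a, b = list(ranked_list_a), list(ranked_list_b)
    if len(set(a)) != len(a) or len(set(b)) != len(b):
        raise DataError("ranked lists must not contain duplicate genes")
    if universe_size < max(len(a), len(b)):
        raise DataError("universe smaller than a ranked list")
    steps_a = range(step, len(a) + 1, step)
    steps_b = range(step, len(b) + 1, step)
    set_b_prefix = []
    seen = set()
    for g in b:
        seen = seen | {g}
        set_b_prefix.append(seen)
    out = np.zeros((len(list(steps_a)), len(list(steps_b))))
    for ii, i in enumerate(range(step, len(a) + 1, step)):
        top_a = set(a[:i])
        for jj, j in enumerate(range(step, len(b) + 1, step)):
            k = len(top_a & set_b_prefix[j - 1])
            p = stats.hypergeom.sf(k - 1, universe_size, i, j)
            out[ii, jj] = -np.log10(max(p, 1e-320))
    return out


def grid_summary_correlation(coords_a, values_a, coords_b, values_b,
                             grid: int = 20) -> float:
    """Pearson correlation between grid-binned mean values of two 2-D
    embeddings (e.g. pseudotime over matched UMAPs). NaN when fewer than 2
    grid cells are co-occupied."""
    ca = np.asarray(coords_a, float)
    cb = np.asarray(coords_b, float)
    va = np.asarray(values_a, float)
    vb = np.asarray(values_b, float)
    lo = np.minimum(ca.min(axis=0), cb.min(axis=0))
    hi = np.maximum(ca.max(axis=0), cb.max(axis=0))
    span = np.where(hi > lo, hi - lo, 1.0)

    def bin_means(coords, values):
        ij = np.clip(((coords - lo) / span * grid).astype(int), 0, grid - 1)
        flat = ij[:, 0] * grid + ij[:, 1]
        sums = np.bincount(flat, weights=values, minlength=grid * grid)
        cnt = np.bincount(flat, minlength=grid * grid)
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, sums / np.maximum(cnt, 1), np.nan)

    ma, mb = bin_means(ca, va), bin_means(cb, vb)
    both = ~np.isnan(ma) & ~np.isnan(mb)
    if both.sum() < 2 or ma[both].std() == 0 or mb[both].std() == 0:
        return float("nan")
    return float(stats.pearsonr(ma[both], mb[both])[0])


def cost_estimate(n_samples: int, n_representatives: int,
                  model: CostModel | None = None) -> dict:
    """Semi-profiling sequencing cost versus full single-cell profiling.

    ``bulk = run_cost + library_cost * n_samples``;
    ``sc = n_representatives * cells_per_sample * per_cell``;
    ``ratio = (bulk + sc) / (n_samples * cells_per_sample * per_cell)``.
    """
    model = model or CostModel()
    if not 0 <= n_representatives <= n_samples:
        raise ConfigurationError("need 0 <= n_representatives <= n_samples")
    bulk = model.run_cost + model.library_cost * n_samples
    sc = n_representatives * model.cells_per_sample * model.per_cell
    full_sc = n_samples * model.cells_per_sample * model.per_cell
    total = bulk + sc
    return {"bulk": bulk, "sc": sc, "total": total, "full_sc": full_sc,
            "ratio": total / full_sc if full_sc > 0 else np.nan}


def validate_global_mode(representatives: dict, rep_bulk: dict,
                         n_train: int, n_test: int,
                         schedule=None, seed: int = 0,
                         cfg: EvalConfig | None = None) -> pd.DataFrame:
    """Hold-out validation of one-batch (global mode) selection.

    The last ``n_test`` representatives are treated as targets: each is
    inferred from its bulk-nearest training representative and compared with
    its real cells (``Dif_sc`` in a joint PCA space; proportion Pearson when
    labels exist).
    """
    from .training import infer_target

    cfg = cfg or EvalConfig()
    ids = list(representatives.keys())
    if n_test < 1 or n_train < 1:
        raise ConfigurationError("split must keep at least 1 train and 1 test sample")
    if n_train + n_test > len(ids):
        raise ConfigurationError("split larger than the representative set")
    train_ids, test_ids = ids[:n_train], ids[n_train:n_train + n_test]
    cache: dict = {}
    rows = []
    for tid in test_ids:
        tb = np.log1p(np.asarray(rep_bulk[tid], float))
        nearest = min(train_ids, key=lambda r: float(np.linalg.norm(
            np.log1p(np.asarray(rep_bulk[r], float)) - tb)))
        res = infer_target(representatives[nearest], rep_bulk[nearest],
                           rep_bulk[tid], schedule=schedule, target_id=tid,
                           seed=seed, model_cache=cache)
        real = np.log1p(representatives[tid].norm_counts)
        gen = np.log1p(res.generated_cells)
        red = joint_pca([real, gen], cfg.n_pcs)
        row = {"target": tid, "representative": nearest,
               "difsc": difsc(red[0], red[1], cfg)}
        rep_cells = representatives[nearest]
        if representatives[tid].labels is not None and rep_cells.labels is not None:
            pred = annotate_cells(np.log1p(rep_cells.norm_counts),
                                  rep_cells.labels, gen, seed=seed)
            classes = sorted(set(np.asarray(representatives[tid].labels).tolist())
                             | set(pred.tolist()))
            tp = np.array([(np.asarray(representatives[tid].labels) == c).mean()
                           for c in classes])
            ep = np.array([(pred == c).mean() for c in classes])
            row["proportion_pearson"] = (float(stats.pearsonr(tp, ep)[0])
                                         if tp.std() > 0 and ep.std() > 0 else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
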