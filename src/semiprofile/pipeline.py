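"""End-to-end semi-profiling of a (synthetic) cohort.

Given a cohort with bulk profiles for every sample and single-cell data for
representatives only, this module wires the stages together: bulk
preprocessing/embedding -> representative selection -> per-representative
model pretraining -> per-target in silico inference -> evaluation (the
normalized cohort error E_N, the selection-only copy baseline, cell-type
proportion recovery, and the single-cell inference difficulty used to
compare active against passive selection).

`run_semi_profiling` grows the representative set through a series of
counts (e.g. 2 -> 4 -> 8) with either passive or active selection and
reports the evaluation at each step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bulk import (
    BulkEmbedding,
    CohortState,
    embed_bulk,
    initial_representatives,
    preprocess_bulk,
    select_features,
)
from .cells import AugmentedCells, CellSample, QCConfig, augment_sample
from .errors import ConfigurationError
from .evaluate import (
    EvalConfig,
    annotate_cells,
    difsc,
    joint_pca,
    lower_bound,
    normalized_error,
    proportion_metrics,
    upper_bound,
)
from .model import GeneratorConfig, LossWeights
from .selection import (
    HeterogeneityConfig,
    active_select,
    cohort_difficulty,
    passive_select,
    update_membership,
)
from .synthetic import SyntheticCohort, generate_gene_sets
from .training import TrainingSchedule, derive_seed, infer_target

__all__ = [
    "PipelineConfig",
    "RoundReport",
    "SemiProfilingReport",
    "synthetic_qc_config",
    "process_representatives",
    "infer_cohort",
    "evaluate_round",
    "estimate_proportions",
    "run_semi_profiling",
]


def synthetic_qc_config(norm_target: float = 1e4, knn_k: int = 15) -> QCConfig:
    """QC thresholds adapted to small synthetic fixtures.

    Synthetic cohorts have tens-to-hundreds of genes, so the default
    thresholds (tuned for ~20k-gene experiments) would discard everything;
    gene filtering is disabled to keep all samples in one gene space.
    """
    return QCConfig(min_genes_per_cell=1, min_cells_per_gene=0,
                    max_genes_doublet=10**9, min_cells_per_sample=20,
                    norm_target=norm_target, knn_k=knn_k)


@dataclass
class PipelineConfig:
    n_gene_sets: int = 5
    hidden_dim: int = 128
    latent_dim: int = 16
    use_real_bulk: bool = False  # ratio path vs direct pseudobulk path
    schedule: TrainingSchedule | None = None
    weights: LossWeights | None = None
    qc: QCConfig | None = None
    eval_cfg: EvalConfig | None = None
    het_cfg: HeterogeneityConfig | None = None
    seed: int = 0


@dataclass
class RoundReport:
    n_reps: int
    representatives: list
    e_n: float | None
    e_n_selection_only: float | None
    difficulty_real: float
    proportion_pearson: float | None = None
    per_sample_difsc: dict = field(default_factory=dict)


@dataclass
class SemiProfilingReport:
    mode: str
    rounds: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"n_reps": r.n_reps, "E_N": r.e_n,
             "E_N_selection_only": r.e_n_selection_only,
             "difficulty": r.difficulty_real,
             "proportion_pearson": r.proportion_pearson}
            for r in self.rounds])


def _cohort_bulk_matrix(cohort: SyntheticCohort, use_real_bulk: bool) -> np.ndarray:
    return cohort.real_bulk if use_real_bulk else cohort.pseudobulk


def processed_real_cells(cohort: SyntheticCohort, i: int,
                         noise_fraction: float = 0.001) -> np.ndarray:
    """A sample's real cells as the evaluation sees them: background noise
    removed, library-normalized, log1p — the same preprocessing the
    representatives' profiled data receives."""
    from .cells import remove_background

    counts = remove_background(cohort.cell_matrices[i], noise_fraction)
    counts = counts[counts.sum(axis=1) > 0]
    return np.log1p(counts / counts.sum(axis=1, keepdims=True)
                    * cohort.norm_target)


def build_bulk_embedding(cohort: SyntheticCohort, use_real_bulk: bool = False,
                         n_hvg: int | None = None) -> BulkEmbedding:
    bulk = preprocess_bulk(_cohort_bulk_matrix(cohort, use_real_bulk),
                           sample_ids=cohort.sample_ids,
                           gene_ids=cohort.gene_ids)
    select_features(bulk, n_hvg or len(cohort.gene_ids))
    return embed_bulk(bulk)


def process_representatives(cohort: SyntheticCohort, rep_ids, gene_sets: dict,
                            qc: QCConfig | None = None,
                            cache: dict | None = None) -> dict:
    """Augment the single-cell data of each representative."""
    qc = qc or synthetic_qc_config(cohort.norm_target)
    out = {}
    for rid in rep_ids:
        if cache is not None and rid in cache:
            out[rid] = cache[rid]
            continue
        i = cohort.sample_ids.index(rid)
        sample = CellSample(counts=cohort.cell_matrices[i], sample_id=rid,
                            gene_ids=list(cohort.gene_ids),
                            labels=np.asarray(cohort.cell_labels[i]))
        out[rid] = augment_sample(sample, gene_sets, qc,
                                  hvg_genes=list(cohort.gene_ids))
        if cache is not None:
            cache[rid] = out[rid]
    return out


def infer_cohort(cohort: SyntheticCohort, state: CohortState, rep_cells: dict,
                 cfg: PipelineConfig, model_cache: dict | None = None) -> dict:
    """Infer single-cell matrices for every non-representative sample."""
    bulk = _cohort_bulk_matrix(cohort, cfg.use_real_bulk)
    generated = {}
    for sid, rid in state.assignment.items():
        if sid == rid:
            continue
        i = cohort.sample_ids.index(sid)
        r = cohort.sample_ids.index(rid)
        rep = rep_cells[rid]
        res = infer_target(
            rep, bulk[r], bulk[i],
            schedule=cfg.schedule, target_id=sid, seed=cfg.seed,
            model_cache=model_cache, use_ratio=cfg.use_real_bulk,
            config=GeneratorConfig(n_genes=rep.n_genes, n_sets=rep.n_sets,
                                   latent_dim=cfg.latent_dim,
                                   hidden_dim=cfg.hidden_dim),
            weights=cfg.weights)
        generated[sid] = res.generated_cells
    return generated


def evaluate_round(cohort: SyntheticCohort, state: CohortState,
                   generated: dict, eval_cfg: EvalConfig | None = None) -> dict:
    """Cohort error of a semi-profiled round versus the real cells.

    All matrices (real and generated, log1p scale) are reduced in one joint
    PCA space; E_N normalizes the mean per-sample Dif_sc between the
    random-pairing upper bound and the split-half lower bound.
    """
    eval_cfg = eval_cfg or EvalConfig()
    real = {sid: processed_real_cells(cohort, i)
            for i, sid in enumerate(cohort.sample_ids)}
    gen = {sid: np.log1p(m) for sid, m in generated.items()}
    stacked = {**{("real", s): m for s, m in real.items()},
               **{("gen", s): m for s, m in gen.items()}}
    red = joint_pca(stacked, eval_cfg.n_pcs)
    real_red = {s: red[("real", s)] for s in real}
    per_sample = {}
    for sid in cohort.sample_ids:
        if state.is_representative(sid) or sid not in gen:
            continue
        per_sample[sid] = difsc(real_red[sid], red[("gen", sid)], eval_cfg)
    ub = upper_bound(list(real_red.values()), eval_cfg)
    lb = lower_bound(np.vstack(list(real_red.values())), eval_cfg)
    full = dict(per_sample)
    for rid in state.representatives:
        full[rid] = lb
    e_n = normalized_error(full, state.representatives, ub, lb)
    return {"e_n": e_n, "ub": ub, "lb": lb, "per_sample_difsc": per_sample,
            "real_red": real_red}


def selection_only_generated(cohort: SyntheticCohort, state: CohortState) -> dict:
    """Baseline: each target simply receives a copy of its representative's
    real cells."""
    out = {}
    for sid, rid in state.assignment.items():
        if sid == rid:
            continue
        out[sid] = cohort.normalized_cells(cohort.sample_ids.index(rid))
    return out


def estimate_proportions(cohort: SyntheticCohort, state: CohortState,
                         rep_cells: dict, generated: dict,
                         seed: int = 0) -> pd.DataFrame:
    """Annotate generated cells with an MLP trained on the representatives'
    labelled cells and compare estimated against true proportions."""
    train_X = np.vstack([np.log1p(rep_cells[r].norm_counts)
                         for r in state.representatives])
    train_y = np.concatenate([rep_cells[r].labels
                              for r in state.representatives])
    n_types = cohort.true_proportions.shape[1]
    est, truth = [], []
    for sid in cohort.sample_ids:
        i = cohort.sample_ids.index(sid)
        if state.is_representative(sid):
            labels = np.asarray(cohort.cell_labels[i])
        elif sid in generated:
            labels = annotate_cells(train_X, train_y,
                                    np.log1p(generated[sid]), seed=seed)
        else:
            continue
        est.append(np.bincount(labels.astype(int), minlength=n_types) / len(labels))
        truth.append(cohort.true_proportions[i])
    metrics = proportion_metrics(np.asarray(truth), np.asarray(est))
    metrics["sample"] = [s for s in cohort.sample_ids
                        if state.is_representative(s) or s in generated]
    return metrics


def _grow_state(state: CohortState, emb: BulkEmbedding, mode: str, B: int,
                real_red: dict, cohort: SyntheticCohort, generated: dict,
                gen_red: dict, het_cfg: HeterogeneityConfig) -> CohortState:
    if mode == "passive":
        _, state = passive_select(state, emb, B)
        return state
    if mode != "active":
        raise ConfigurationError(f"unknown selection mode {mode!r}")
    # representatives contribute their real cells; targets the inferred ones
    sc_coords = {**{s: real_red[s] for s in state.representatives}, **gen_red}
    pseudobulks = {}
    for sid in cohort.sample_ids:
        i = cohort.sample_ids.index(sid)
        if state.is_representative(sid):
            pseudobulks[sid] = cohort.pseudobulk[i]
        elif sid in generated:
            pseudobulks[sid] = generated[sid].mean(axis=0)
    cfg = HeterogeneityConfig(lambda_sc=het_cfg.lambda_sc,
                              lambda_pb=het_cfg.lambda_pb,
                              knn_k=het_cfg.knn_k, batch_size=B)
    return active_select(state, emb, sc_coords, pseudobulks, cfg).state


def run_semi_profiling(cohort: SyntheticCohort, rep_counts=(2, 4, 8),
                       mode: str = "active",
                       cfg: PipelineConfig | None = None,
                       compute_inference: bool = True) -> SemiProfilingReport:
    """Semi-profile a cohort while growing the representative set.

    At each count: process representatives, infer all targets, evaluate E_N
    (full pipeline and selection-only baseline) and the real-cell inference
    difficulty; then grow the representative set with the chosen mode.
    Passive runs may skip inference (`compute_inference=False`) since both
    their selection and their difficulty need only bulk and real cells.
    """
    cfg = cfg or PipelineConfig()
    rep_counts = sorted(rep_counts)
    if rep_counts[-1] > cohort.n_samples:
        raise ConfigurationError("more representatives than samples")
    schedule = cfg.schedule or TrainingSchedule.reduced(seed=cfg.seed)
    cfg.schedule = schedule
    eval_cfg = cfg.eval_cfg or EvalConfig(seed=derive_seed(cfg.seed, "eval"))
    het_cfg = cfg.het_cfg or HeterogeneityConfig()
    gene_sets = generate_gene_sets(cfg.n_gene_sets, cohort.gene_ids,
                                   derive_seed(cfg.seed, "sets"))
    emb = build_bulk_embedding(cohort, cfg.use_real_bulk)
    state = initial_representatives(emb, rep_counts[0],
                                    seed=derive_seed(cfg.seed, "kmeans"))
    state = update_membership(state, emb)
    rep_cache: dict = {}
    model_cache: dict = {}
    qc = cfg.qc or synthetic_qc_config(cohort.norm_target,
                                       knn_k=min(15, cohort.spec.cells_per_sample - 1
                                                 if cohort.spec else 15))
    real_log = {sid: processed_real_cells(cohort, i)
                for i, sid in enumerate(cohort.sample_ids)}
    # difficulty lives in a real-cells-only PCA space so active and passive
    # runs (with and without inference) are compared in the same coordinates
    real_only_red = joint_pca(real_log, eval_cfg.n_pcs)
    round_states, round_generated, rounds = [], [], []
    for step, count in enumerate(rep_counts):
        rep_cells = process_representatives(cohort, state.representatives,
                                            gene_sets, qc, rep_cache)
        generated, gen_red, prop_r = {}, {}, None
        if compute_inference:
            generated = infer_cohort(cohort, state, rep_cells, cfg, model_cache)
            metrics = estimate_proportions(cohort, state, rep_cells, generated,
                                           seed=derive_seed(cfg.seed, "annot"))
            prop_r = float(np.nanmean(metrics["pearson"]))
            stacked = {**{("real", s): m for s, m in real_log.items()},
                       **{("gen", s): np.log1p(m) for s, m in generated.items()}}
            red = joint_pca(stacked, eval_cfg.n_pcs)
            gen_red = {s: red[("gen", s)] for s in generated}
        difficulty = cohort_difficulty(state, real_only_red, het_cfg.knn_k)
        round_states.append(state)
        round_generated.append(generated)
        rounds.append(RoundReport(
            n_reps=len(state.representatives),
            representatives=list(state.representatives),
            e_n=None, e_n_selection_only=None,
            difficulty_real=difficulty, proportion_pearson=prop_r))
        if step + 1 < len(rep_counts):
            real_red_now = ({s: red[("real", s)] for s in real_log}
                            if compute_inference else real_only_red)
            state = _grow_state(state, emb, mode,
                                rep_counts[step + 1] - count,
                                real_red_now, cohort, generated, gen_red,
                                het_cfg)
    if compute_inference:
        # one shared PCA space (real cells plus every round's generated
        # cells) keeps E_N comparable across representative counts
        stacked = {**{("real", s): m for s, m in real_log.items()}}
        for ridx, gen in enumerate(round_generated):
            stacked.update({("gen", ridx, s): np.log1p(m)
                            for s, m in gen.items()})
        red = joint_pca(stacked, eval_cfg.n_pcs)
        real_red = {s: red[("real", s)] for s in real_log}
        ub = upper_bound(list(real_red.values()), eval_cfg)
        lb = lower_bound(np.vstack(list(real_red.values())), eval_cfg)
        for ridx, (st, gen, rr) in enumerate(zip(round_states, round_generated,
                                                 rounds)):
            per_sample, per_sample_sel = {}, {}
            for sid in cohort.sample_ids:
                if st.is_representative(sid):
                    continue
                per_sample[sid] = difsc(real_red[sid], red[("gen", ridx, sid)],
                                        eval_cfg)
                per_sample_sel[sid] = difsc(real_red[sid],
                                            real_red[st.assignment[sid]],
                                            eval_cfg)
            for rid in st.representatives:
                per_sample[rid] = per_sample_sel[rid] = lb
            rr.e_n = normalized_error(per_sample, st.representatives, ub, lb)
            rr.e_n_selection_only = normalized_error(
                per_sample_sel, st.representatives, ub, lb)
            rr.per_sample_difsc = {s: v for s, v in per_sample.items()
                                   if not st.is_representative(s)}
    return SemiProfilingReport(mode=mode, rounds=rounds)
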