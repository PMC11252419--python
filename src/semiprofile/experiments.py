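"""Benchmark experiments on synthetic cohorts with known ground truth.

Each function builds its study data with a fixed internal seed (the data
play the role of a published dataset: the conditions of the study, not a
source of run-to-run variation) and takes a ``seed`` argument that drives
the *algorithmic* randomness — model initialization, training, clustering,
random pairings. The experiments cover:

- sequencing cost of semi-profiling versus full single-cell profiling for
  published cohort layouts;
- identity-target recovery: fine-tuning toward the representative's own
  pseudobulk must reproduce it;
- composition transformation: a target equal to the representative but with
  one cell type's proportion doubled must pull the generated pseudobulk and
  annotated proportions toward the target;
- conversion-ratio pseudobulk inference under systematic bulk distortion;
- representative-selection curves: the normalized cohort error E_N as the
  representative set grows, the selection-only copy baseline, and active-
  versus passive-learning inference difficulty.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .evaluate import CostModel, annotate_cells, cost_estimate
from .model import conversion_ratio
from .pipeline import PipelineConfig, process_representatives, run_semi_profiling
from .synthetic import (
    SyntheticCohortSpec,
    default_condition_shifts,
    default_type_profiles,
    generate_cohort,
    generate_gene_sets,
)
from .training import (
    SemiProfileModel,
    StageInference,
    TrainingSchedule,
    derive_seed,
    infer_pseudobulk,
)

__all__ = [
    "cost_experiments",
    "identity_recovery",
    "proportion_doubling",
    "pseudobulk_ratio_inference",
    "selection_curves",
]

#: cohort layouts (n_samples, n_representatives) with published cost figures
COHORT_LAYOUTS = {
    "covid": (124, 28),
    "colorectal": (112, 36),
    "imgl": (25, 8),
}


def cost_experiments() -> dict:
    """Cost of semi-profiling for the three benchmark cohort layouts plus
    the per-sample and per-20k-cells reference prices."""
    model = CostModel()
    out = {}
    for name, (n, r) in COHORT_LAYOUTS.items():
        est = cost_estimate(n, r, model)
        out[f"{name}_total_usd"] = est["total"]
        out[f"{name}_full_sc_usd"] = est["full_sc"]
        out[f"{name}_cost_ratio_pct"] = 100.0 * est["ratio"]
    out["per_sample_usd"] = model.cells_per_sample * model.per_cell
    out["per_20k_cells_usd"] = 20_000 * model.per_cell
    return out


def _representative_fixture(n_genes=200, cells=300, data_seed=3):
    spec = SyntheticCohortSpec(n_samples=2, n_genes=n_genes, n_cell_types=3,
                               cells_per_sample=cells, seed=data_seed)
    cohort = generate_cohort(spec)
    sets = generate_gene_sets(5, cohort.gene_ids, seed=1)
    rep = process_representatives(cohort, [cohort.sample_ids[0]], sets)[
        cohort.sample_ids[0]]
    return cohort, rep


def identity_recovery(seed: int = 0) -> dict:
    """Fine-tune with the representative's own pseudobulk as the target
    (conversion ratio = 1) and report how well the generated pseudobulk
    reproduces it."""
    _, rep = _representative_fixture()
    model = SemiProfileModel(rep, schedule=TrainingSchedule(seed=derive_seed(seed, "id")),
                             seed=derive_seed(seed, "id-model"))
    res = model.fit(target_pseudobulk=rep.pseudobulk(), target_id="identity")
    r = float(stats.pearsonr(res.inferred_pseudobulk, rep.pseudobulk())[0])
    return {"pseudobulk_pearson": r, "n_cells": rep.n_cells,
            "n_genes": rep.n_genes}


def proportion_doubling(seed: int = 0) -> dict:
    """Target = representative with the second cell type's proportion
    doubled. Reports the L2 distance of the generated pseudobulk to the
    target's true pseudobulk (versus the representative's distance) and the
    Pearson correlation of annotated against true proportions."""
    data_rng = np.random.default_rng(11)
    profiles = default_type_profiles(3, 200, data_rng)
    base = np.array([0.5, 0.3, 0.2])
    doubled = np.array([0.5, 0.6, 0.2])
    doubled = doubled / doubled.sum()

    def cohort_for(props, data_seed):
        return generate_cohort(SyntheticCohortSpec(
            n_samples=1, n_genes=200, n_cell_types=3, cells_per_sample=300,
            type_mean_profiles=profiles, sample_shift_scale=0.0,
            proportion_prior=props * 1e6, seed=data_seed))

    rep_cohort = cohort_for(base, 1)
    tgt_cohort = cohort_for(doubled, 2)
    sets = generate_gene_sets(5, rep_cohort.gene_ids, seed=1)
    rep = process_representatives(rep_cohort, ["S000"], sets)["S000"]
    target_pb = tgt_cohort.pseudobulk[0]
    model = SemiProfileModel(rep, schedule=TrainingSchedule(seed=derive_seed(seed, "dbl")),
                             seed=derive_seed(seed, "dbl-model"))
    res = model.fit(target_pseudobulk=target_pb, target_id="doubled")
    d_gen = float(np.linalg.norm(res.inferred_pseudobulk - target_pb))
    d_rep = float(np.linalg.norm(rep.pseudobulk() - target_pb))
    pred = annotate_cells(np.log1p(rep.norm_counts), rep.labels,
                          np.log1p(res.generated_cells),
                          seed=derive_seed(seed, "annot"))
    est = np.bincount(pred.astype(int), minlength=3) / len(pred)
    r = float(stats.pearsonr(est, tgt_cohort.true_proportions[0])[0])
    return {"generated_to_target_l2": d_gen,
            "representative_to_target_l2": d_rep,
            "l2_ratio": d_gen / d_rep,
            "proportion_pearson": r,
            "n_cells": rep.n_cells}


def pseudobulk_ratio_inference(seed: int = 0, n_samples: int = 12) -> dict:
    """Conversion-ratio estimation under gene-wise-consistent bulk
    distortion: correlation (log scale) of the inferred target pseudobulk
    with the truth, against the correlation of the raw real bulk."""
    spec = SyntheticCohortSpec(n_samples=n_samples, n_genes=200,
                               cells_per_sample=200, bulk_bias_scale=0.5,
                               seed=17)
    cohort = generate_cohort(spec)
    rng = np.random.default_rng(derive_seed(seed, "pairs"))
    r_inf, r_raw = [], []
    for _ in range(30):
        t, r = rng.choice(n_samples, size=2, replace=False)
        alpha = conversion_ratio(cohort.real_bulk[t], cohort.real_bulk[r])
        inferred = infer_pseudobulk(cohort.pseudobulk[r], alpha)
        truth = np.log1p(cohort.pseudobulk[t])
        r_inf.append(stats.pearsonr(np.log1p(inferred), truth)[0])
        # real bulk rescaled to the pseudobulk's total for a fair comparison
        raw = cohort.real_bulk[t] / cohort.real_bulk[t].sum() * cohort.pseudobulk[t].sum()
        r_raw.append(stats.pearsonr(np.log1p(raw), truth)[0])
    return {"inferred_vs_truth_pearson": float(np.mean(r_inf)),
            "real_bulk_vs_truth_pearson": float(np.mean(r_raw)),
            "n_pairs": 30}


def selection_cohort() -> "SyntheticCohort":
    """The 16-sample cohort with four planted condition clusters used for
    the representative-selection experiments.

    Conditions shift each cell type differently (a gene-wise bulk scaling
    cannot fully mimic them) and samples carry their own gene-wise
    expression shifts. Cluster sizes are unequal (6/4/3/3) with unequal
    shift magnitudes, as in real cohorts where condition groups are rarely
    balanced — budget allocation across clusters is exactly what
    heterogeneity-based selection is designed to get right."""
    data_rng = np.random.default_rng(5)
    profiles = default_type_profiles(3, 120, data_rng, marker_fraction=0.1,
                                     marker_boost=12.0) * 5.0
    shifts = default_condition_shifts(4, 120, data_rng,
                                      scale=[0.0, 0.8, 1.0, 1.6],
                                      n_cell_types=3)
    assignment = np.array([0] * 6 + [1] * 4 + [2] * 3 + [3] * 3)
    spec = SyntheticCohortSpec(
        n_samples=16, n_genes=120, n_cell_types=3, cells_per_sample=120,
        type_mean_profiles=profiles, dropout_rate=0.05,
        condition_shifts=shifts, condition_assignment=assignment,
        sample_shift_scale=0.4, seed=5)
    return generate_cohort(spec)


def _selection_schedule(seed: int) -> TrainingSchedule:
    sched = TrainingSchedule(seed=seed)
    # fine-tuning capped per mini-stage to keep the 16-sample sweep tractable
    sched.inference = StageInference(max_epochs_per_stage=60,
                                     min_epochs_per_stage=20)
    return sched


def selection_curves(seed: int = 0, rep_counts=(2, 4, 8)) -> dict:
    """Grow the representative set on the planted-cluster cohort with active
    and passive selection; report E_N (full pipeline and selection-only
    baseline) and the real-cell inference difficulty per count."""
    cohort = selection_cohort()
    sched = _selection_schedule(derive_seed(seed, "sched"))
    active = run_semi_profiling(
        cohort, rep_counts=rep_counts, mode="active",
        cfg=PipelineConfig(schedule=sched, seed=derive_seed(seed, "act"),
                           hidden_dim=256, latent_dim=32))
    passive = run_semi_profiling(
        cohort, rep_counts=rep_counts, mode="passive",
        cfg=PipelineConfig(schedule=sched, seed=derive_seed(seed, "act"),
                           hidden_dim=256, latent_dim=32),
        compute_inference=False)
    out = {}
    for r in active.rounds:
        out[f"e_n_at_{r.n_reps}"] = r.e_n
        out[f"e_n_selection_only_at_{r.n_reps}"] = r.e_n_selection_only
        out[f"difficulty_active_at_{r.n_reps}"] = r.difficulty_real
        out[f"proportion_pearson_at_{r.n_reps}"] = r.proportion_pearson
    for r in passive.rounds:
        out[f"difficulty_passive_at_{r.n_reps}"] = r.difficulty_real
    out["n_samples"] = cohort.n_samples
    return out
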