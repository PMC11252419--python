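"""Three-stage training and in silico inference.

Stage 1 (pretrain 1) teaches the VAE generator to reconstruct the
representative's cells — first alone, then adversarially against the
discriminator in alternating 3-epoch blocks. Stage 2 (pretrain 2) repeats
the joint training full-batch with the representative bulk loss added,
aligning reconstruction pseudobulk with the representative's pseudobulk.
Stage 3 (inference) retires the discriminator and fine-tunes the generator
so the generated pseudobulk matches the *target* sample's pseudobulk
estimate, in a sequence of mini-stages: each mini-stage masks the bulk-loss
contribution of genes whose representative expression exceeds a decreasing
threshold (relative to the peak normalized expression) while the bulk-loss
weight is quadrupled, shifting optimization from highly to lowly expressed
genes. Decoding every representative cell through the fine-tuned generator
and zeroing entries below the activation threshold yields the inferred
single-cell matrix for the target.

`SemiProfileModel` packages this as a model object built from a
representative's processed cells: `fit()` returns an `InferenceResult`
carrying the generated cells, loss traces and a `summary()` table.
Pretraining is cached so one representative serves many targets.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._nn import Adam
from .cells import AugmentedCells
from .errors import ConfigurationError, DataError, TrainingDivergedError
from .model import (
    Discriminator,
    DiscriminatorConfig,
    Generator,
    GeneratorConfig,
    LossWeights,
    conversion_ratio,
    gaussian_nll,
    infer_pseudobulk,
    kl_to_standard_normal,
    loss_bulk_target,
    loss_d_fake,
    loss_discriminator,
    pseudobulk,
    zinb_nll,
)
from ._autodiff import Tensor, log1p, concat

__all__ = [
    "TrainingSchedule",
    "StagePretrain1",
    "StagePretrain2",
    "StageInference",
    "InferenceResult",
    "SemiProfileModel",
    "stage_pretrain1",
    "stage_pretrain2",
    "stage_inference",
    "apply_activation_threshold",
    "infer_pseudobulk",
    "infer_target",
    "derive_seed",
]

DEFAULT_THRESHOLDS = (math.inf, 0.5, 0.25, 0.125, 1.0 / (8.0 * math.sqrt(2.0)))


def derive_seed(base: int, *keys) -> int:
    """Deterministically derive a sub-seed (< 2^31) from a base seed and keys."""
    h = hashlib.sha256(("|".join([str(base), *map(str, keys)])).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


@dataclass
class StagePretrain1:
    gen_epochs: int = 100
    joint_iterations: int = 100
    epochs_per_side: int = 3
    lr: float = 1e-3
    batch_size: int = 128


@dataclass
class StagePretrain2:
    gen_epochs: int = 50
    joint_iterations: int = 50
    epochs_per_side: int = 3
    lr: float = 1e-4
    full_batch: bool = True
    cell_budget: int = 20000  # above this, full-batch falls back to accumulation


@dataclass
class StageInference:
    thresholds: tuple = DEFAULT_THRESHOLDS  # fractions of max_expr
    max_epochs_per_stage: int = 150
    lr: float = 2e-4
    bulk_weight_multiplier: float = 4.0
    patience: int = 10
    # epochs before patience may trigger: a freshly initialized optimizer
    # transiently raises the loss, which must not count as convergence
    min_epochs_per_stage: int = 30


@dataclass
class TrainingSchedule:
    pretrain1: StagePretrain1 = field(default_factory=StagePretrain1)
    pretrain2: StagePretrain2 = field(default_factory=StagePretrain2)
    inference: StageInference = field(default_factory=StageInference)
    seed: int = 0

    def validate(self) -> None:
        t = self.inference.thresholds
        if len(t) < 1 or not math.isinf(t[0]):
            raise ConfigurationError("first mini-stage must be unthresholded")
        finite = [x for x in t[1:]]
        if any(b >= a for a, b in zip(t[1:], t[2:])) or any(x <= 0 for x in finite):
            raise ConfigurationError("mini-stage thresholds must be strictly decreasing and positive")
        if self.inference.bulk_weight_multiplier <= 1:
            raise ConfigurationError("bulk weight multiplier must exceed 1")

    @classmethod
    def reduced(cls, scale: float = 0.2, seed: int = 0) -> "TrainingSchedule":
        """A proportionally shortened schedule for small problems."""
        s = max(scale, 0.01)
        return cls(
            pretrain1=StagePretrain1(gen_epochs=max(5, int(100 * s)),
                                     joint_iterations=max(2, int(100 * s))),
            pretrain2=StagePretrain2(gen_epochs=max(3, int(50 * s)),
                                     joint_iterations=max(2, int(50 * s))),
            inference=StageInference(
                max_epochs_per_stage=max(10, int(150 * s)),
                min_epochs_per_stage=min(30, max(10, int(150 * s)))),
            seed=seed,
        )


@dataclass
class _TrainData:
    """Arrays the stages consume, extracted once from AugmentedCells."""

    agg: np.ndarray  # encoder input (aggregated log features)
    raw_features: np.ndarray  # un-aggregated features, shown to the discriminator
    x: np.ndarray  # normalized counts (ZINB target)
    s: np.ndarray | None  # gene-set scores (Gaussian target)
    w_genes: np.ndarray
    w_sets: np.ndarray | None
    library: np.ndarray

    @classmethod
    def from_cells(cls, rep: AugmentedCells) -> "_TrainData":
        G = rep.n_genes
        s = rep.features[:, G:] if rep.n_sets else None
        return cls(
            agg=rep.aggregated,
            raw_features=rep.features,
            x=rep.norm_counts,
            s=s,
            w_genes=rep.weights[:G],
            w_sets=rep.weights[G:] if rep.n_sets else None,
            library=rep.norm_counts.sum(axis=1),
        )

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def subset(self, idx) -> "_TrainData":
        return _TrainData(
            agg=self.agg[idx], raw_features=self.raw_features[idx],
            x=self.x[idx], s=None if self.s is None else self.s[idx],
            w_genes=self.w_genes, w_sets=self.w_sets, library=self.library[idx])


def _check_finite(value: float, stage: str) -> float:
    if not np.isfinite(value):
        raise TrainingDivergedError(f"non-finite loss in {stage}")
    return value


def _vae_terms(gen: Generator, data: _TrainData, rng=None):
    latent, params, recon_genes, recon_sets = gen.reconstruct(
        data.agg, data.library)
    nll = zinb_nll(data.x, params, data.w_genes)
    if data.s is not None and recon_sets is not None:
        nll = nll + gaussian_nll(data.s, recon_sets, data.w_sets)
    kl = kl_to_standard_normal(latent.mu, latent.sigma)
    return latent, recon_genes, recon_sets, nll, kl


def _fake_features(recon_genes, recon_sets):
    """Features of a generated cell as the discriminator sees them.

    Expression is compressed with log1p to keep the discriminator's input on
    the same scale as the (log-space) real feature matrix."""
    parts = [log1p(recon_genes)]
    if recon_sets is not None:
        parts.append(recon_sets)
    return concat(parts, axis=1)


def _real_features(data: _TrainData):
    parts = [np.log1p(data.x)]
    if data.s is not None:
        parts.append(data.s)
    return np.concatenate(parts, axis=1)


def _gen_step(gen, disc, data, opt, lambda_d, bulk_fn):
    """One generator update on a batch; returns the loss components."""
    opt.zero_grad()
    latent, recon_genes, recon_sets, nll, kl = _vae_terms(gen, data)
    n = data.n
    loss = (nll + kl) * (1.0 / n)
    ld_fake_val = 0.0
    if disc is not None and lambda_d > 0:
        ld_fake = loss_d_fake(disc(_fake_features(recon_genes, recon_sets)))
        loss = loss - lambda_d * (1.0 / n) * ld_fake
        ld_fake_val = float(ld_fake.data)
    bulk_val = 0.0
    if bulk_fn is not None:
        bulk = bulk_fn(recon_genes)
        loss = loss + bulk
        bulk_val = float(bulk.data)
    loss.backward()
    opt.step()
    return {
        "loss": _check_finite(loss.item(), "generator step"),
        "nll": float(nll.data), "kl": float(kl.data),
        "l_d_fake": ld_fake_val, "bulk": bulk_val,
        "l_vae": (float(nll.data) + float(kl.data)) / n,
    }


def _disc_step(gen, disc, data, opt):
    opt.zero_grad()
    _, _, recon_genes, recon_sets = gen.reconstruct(data.agg, data.library)
    fake = _fake_features(recon_genes, recon_sets)
    fake = Tensor(fake.data)  # detach: discriminator step leaves G fixed
    ld = loss_discriminator(disc(_real_features(data)), disc(fake))
    scaled = ld * (1.0 / data.n)
    scaled.backward()
    opt.step()
    return _check_finite(float(ld.data), "discriminator step")


def _epoch_batches(data: _TrainData, batch_size: int, rng: np.random.Generator):
    if batch_size >= data.n:
        yield data
        return
    order = rng.permutation(data.n)
    for lo in range(0, data.n, batch_size):
        yield data.subset(order[lo:lo + batch_size])


def stage_pretrain1(gen: Generator, disc: Discriminator | None,
                    rep: AugmentedCells, schedule: TrainingSchedule,
                    weights: LossWeights | None = None) -> list:
    """Reconstruction pretraining: generator-only, then alternating blocks."""
    weights = weights or LossWeights()
    cfg = schedule.pretrain1
    data = _TrainData.from_cells(rep)
    rng = np.random.default_rng(derive_seed(schedule.seed, "pretrain1"))
    gen_opt = Adam(gen.parameters(), lr=cfg.lr,
                   weight_decay=gen.config.weight_decay)
    trace = []
    for epoch in range(cfg.gen_epochs):
        logs = [_gen_step(gen, None, b, gen_opt, 0.0, None)
                for b in _epoch_batches(data, cfg.batch_size, rng)]
        trace.append({"phase": "gen", "epoch": epoch,
                      "loss": float(np.mean([l["loss"] for l in logs])),
                      "l_vae": float(np.mean([l["l_vae"] for l in logs]))})
    if disc is not None and cfg.joint_iterations > 0:
        disc_opt = Adam(disc.parameters(), lr=cfg.lr)
        for it in range(cfg.joint_iterations):
            for epoch in range(cfg.epochs_per_side):
                logs = [_gen_step(gen, disc, b, gen_opt, weights.lambda_d, None)
                        for b in _epoch_batches(data, cfg.batch_size, rng)]
                trace.append({"phase": "joint-gen", "epoch": it * cfg.epochs_per_side + epoch,
                              "loss": float(np.mean([l["loss"] for l in logs])),
                              "l_vae": float(np.mean([l["l_vae"] for l in logs]))})
            for epoch in range(cfg.epochs_per_side):
                ld = [_disc_step(gen, disc, b, disc_opt)
                      for b in _epoch_batches(data, cfg.batch_size, rng)]
                trace.append({"phase": "joint-disc",
                              "epoch": it * cfg.epochs_per_side + epoch,
                              "loss": float(np.mean(ld))})
    return trace


def stage_pretrain2(gen: Generator, disc: Discriminator | None,
                    rep: AugmentedCells, schedule: TrainingSchedule,
                    weights: LossWeights | None = None) -> list:
    """Full-batch pretraining with the representative bulk loss added."""
    weights = weights or LossWeights()
    cfg = schedule.pretrain2
    data = _TrainData.from_cells(rep)
    rng = np.random.default_rng(derive_seed(schedule.seed, "pretrain2"))
    batch = data.n if cfg.full_batch and data.n <= cfg.cell_budget else min(
        data.n, cfg.cell_budget)
    rep_pb = rep.pseudobulk()

    def bulk_fn(recon_genes):
        # trained in squared-error form (vanishing gradient at the optimum);
        # the reported L_BulkR is the L2 norm itself
        l = loss_bulk_target(recon_genes, rep_pb, target_pseudobulk=rep_pb)
        return weights.lambda_bulk_r * l * l

    bulk = bulk_fn if weights.lambda_bulk_r > 0 else None
    gen_opt = Adam(gen.parameters(), lr=cfg.lr,
                   weight_decay=gen.config.weight_decay)
    trace = []
    for epoch in range(cfg.gen_epochs):
        logs = [_gen_step(gen, None, b, gen_opt, 0.0, bulk)
                for b in _epoch_batches(data, batch, rng)]
        trace.append({"phase": "gen", "epoch": epoch,
                      "loss": float(np.mean([l["loss"] for l in logs])),
                      "l_vae": float(np.mean([l["l_vae"] for l in logs])),
                      "l_bulk_r": float(np.mean([l["bulk"] for l in logs]))})
    if disc is not None and cfg.joint_iterations > 0:
        disc_opt = Adam(disc.parameters(), lr=cfg.lr)
        for it in range(cfg.joint_iterations):
            for epoch in range(cfg.epochs_per_side):
                logs = [_gen_step(gen, disc, b, gen_opt, weights.lambda_d, bulk)
                        for b in _epoch_batches(data, batch, rng)]
                trace.append({"phase": "joint-gen",
                              "epoch": it * cfg.epochs_per_side + epoch,
                              "loss": float(np.mean([l["loss"] for l in logs])),
                              "l_vae": float(np.mean([l["l_vae"] for l in logs])),
                              "l_bulk_r": float(np.mean([l["bulk"] for l in logs]))})
            for epoch in range(cfg.epochs_per_side):
                ld = [_disc_step(gen, disc, b, disc_opt)
                      for b in _epoch_batches(data, batch, rng)]
                trace.append({"phase": "joint-disc",
                              "epoch": it * cfg.epochs_per_side + epoch,
                              "loss": float(np.mean(ld))})
    return trace


def stage_inference(gen: Generator, rep: AugmentedCells,
                    target_pb_estimate: np.ndarray,
                    schedule: TrainingSchedule,
                    weights: LossWeights | None = None) -> list:
    """Mini-stage fine-tuning toward the target pseudobulk estimate.

    The discriminator is retired. In mini-stage k, genes whose peak
    representative normalized expression exceeds ``thresholds[k] * max_expr``
    are excluded from the bulk loss (their bulk gradients are zeroed) and
    the bulk weight is multiplied by ``bulk_weight_multiplier`` per stage.
    Each mini-stage early-stops on patience and is capped at
    ``max_epochs_per_stage`` epochs; the best parameters are kept.
    """
    weights = weights or LossWeights()
    schedule.validate()
    cfg = schedule.inference
    data = _TrainData.from_cells(rep)
    max_expr = float(rep.norm_counts.max())
    gene_peak = rep.norm_counts.max(axis=0)
    target_pb_estimate = np.asarray(target_pb_estimate, dtype=float)
    if target_pb_estimate.shape[0] != rep.n_genes:
        raise DataError("target pseudobulk estimate has wrong gene dimension")
    gen_opt = Adam(gen.parameters(), lr=cfg.lr,
                   weight_decay=gen.config.weight_decay)
    trace = []
    lam = weights.lambda_bulk_t

    def full_objective():
        # stage-wide model-selection score: reconstruction quality plus the
        # *unmasked* bulk mismatch at the base weight
        _, params, recon, _ = gen.reconstruct(data.agg, data.library,
                                              sample=False)
        recon = np.asarray(recon.data)
        params.pi, params.theta, params.mu = (
            np.asarray(params.pi.data), np.asarray(params.theta.data),
            np.asarray(params.mu.data))
        l = float(loss_bulk_target(recon, target_pb_estimate,
                                   target_pseudobulk=target_pb_estimate))
        nll = float(zinb_nll(data.x, params, data.w_genes))
        return nll / data.n + lam * l * l

    global_best, global_state = np.inf, None
    for k, frac in enumerate(cfg.thresholds):
        mask = (np.ones_like(gene_peak, dtype=bool) if math.isinf(frac)
                else gene_peak <= frac * max_expr)
        lam_k = lam * cfg.bulk_weight_multiplier**k

        def bulk_fn(recon_genes, _m=mask, _l=lam_k):
            # squared-error form: its gradient grows with the residual, which
            # is what the decreasing-threshold mini-stage strategy equalizes
            l = loss_bulk_target(recon_genes, target_pb_estimate,
                                 target_pseudobulk=target_pb_estimate,
                                 gene_mask=_m)
            return _l * l * l

        best, stall = np.inf, 0
        for epoch in range(cfg.max_epochs_per_stage):
            log = _gen_step(gen, None, data, gen_opt, 0.0, bulk_fn)
            trace.append({"phase": f"mini-{k}", "epoch": epoch,
                          "loss": log["loss"], "l_vae": log["l_vae"],
                          "l_bulk_t": log["bulk"], "lambda_bulk_t": lam_k})
            score = full_objective()
            if score < global_best - 1e-9:
                global_best, global_state = score, gen.state_dict()
            if log["loss"] < best - 1e-9:
                best, stall = log["loss"], 0
            else:
                stall += 1
                if stall >= cfg.patience and epoch + 1 >= cfg.min_epochs_per_stage:
                    break
    if global_state is not None:
        gen.load_state_dict(global_state)
    return trace


def apply_activation_threshold(generated: np.ndarray, library_size: float,
                               fraction: float = 0.001) -> np.ndarray:
    """Zero generated entries below ``fraction`` of the library size (the
    neuron activation threshold, matching background-noise removal)."""
    if not 0 <= fraction < 1:
        raise ConfigurationError("fraction must lie in [0, 1)")
    generated = np.asarray(generated, dtype=float)
    if np.any(generated < 0):
        raise DataError("generated expression must be non-negative")
    out = generated.copy()
    out[out < fraction * library_size] = 0.0
    return out


class InferenceResult:
    """Results of fitting a `SemiProfileModel`: the inferred single-cell
    matrix for one target plus training diagnostics."""

    def __init__(self, generated_cells, loss_trace, target_id,
                 representative_id, target_pb_estimate=None, alpha=None,
                 schedule=None, seed=0, norm_target=1e4):
        self.generated_cells = generated_cells  # (cells, genes) normalized
        self.inferred_pseudobulk = pseudobulk(generated_cells)
        self.loss_trace = loss_trace  # stage name -> list of epoch dicts
        self.target_id = target_id
        self.representative_id = representative_id
        self.target_pb_estimate = target_pb_estimate
        self.alpha = alpha
        self.schedule = schedule
        self.seed = seed
        self.norm_target = norm_target

    @property
    def n_cells(self) -> int:
        return self.generated_cells.shape[0]

    def final_losses(self) -> dict:
        out = {}
        for stage, rows in self.loss_trace.items():
            gen_rows = [r for r in rows if not r.get("phase", "").endswith("disc")]
            if gen_rows:
                out[stage] = gen_rows[-1]["loss"]
        return out

    def summary(self) -> pd.DataFrame:
        rows = [
            ("target", self.target_id),
            ("representative", self.representative_id),
            ("n_cells", self.n_cells),
            ("n_genes", self.generated_cells.shape[1]),
        ]
        for stage, val in self.final_losses().items():
            rows.append((f"final loss [{stage}]", round(val, 4)))
        if self.target_pb_estimate is not None:
            r = np.corrcoef(self.inferred_pseudobulk, self.target_pb_estimate)[0, 1]
            rows.append(("pearson(generated pb, target estimate)", round(float(r), 4)))
        return pd.DataFrame(rows, columns=["quantity", "value"])

    def __repr__(self):
        return (f"<InferenceResult target={self.target_id!r} "
                f"rep={self.representative_id!r} cells={self.n_cells}>")


class SemiProfileModel:
    """Generative semi-profiling model for one representative sample.

    Built from the representative's augmented cells (and optionally its real
    bulk profile); ``fit`` pretrains once (cached), fine-tunes toward a
    target sample's bulk, and returns an :class:`InferenceResult`.
    """

    def __init__(self, rep: AugmentedCells, rep_bulk: np.ndarray | None = None,
                 config: GeneratorConfig | None = None,
                 disc_config: DiscriminatorConfig | None = None,
                 weights: LossWeights | None = None,
                 schedule: TrainingSchedule | None = None,
                 seed: int = 0, representative_id: str | None = None):
        self.rep = rep
        self.rep_bulk = None if rep_bulk is None else np.asarray(rep_bulk, float)
        self.config = config or GeneratorConfig(n_genes=rep.n_genes,
                                                n_sets=rep.n_sets)
        if (self.config.n_genes, self.config.n_sets) != (rep.n_genes, rep.n_sets):
            raise ConfigurationError("generator config does not match the data")
        self.disc_config = disc_config or DiscriminatorConfig()
        self.weights = weights or LossWeights()
        self.weights.validate()
        self.schedule = schedule or TrainingSchedule()
        self.schedule.validate()
        self.seed = seed
        self.representative_id = representative_id or rep.sample_id
        self.generator = Generator(self.config, seed=derive_seed(seed, "gen"))
        self.discriminator = Discriminator(
            self.config.input_dim, self.disc_config,
            seed=derive_seed(seed, "disc"))
        self._pretrain_trace = None
        self._pretrained_state = None

    # -- stages -----------------------------------------------------------
    def pretrain(self) -> "SemiProfileModel":
        """Run both pretraining stages once; subsequent calls are no-ops."""
        if self._pretrained_state is None:
            t1 = stage_pretrain1(self.generator, self.discriminator, self.rep,
                                 self.schedule, self.weights)
            t2 = stage_pretrain2(self.generator, self.discriminator, self.rep,
                                 self.schedule, self.weights)
            self._pretrain_trace = {"pretrain1": t1, "pretrain2": t2}
            self._pretrained_state = self.generator.state_dict()
        return self

    def target_pseudobulk_estimate(self, target_bulk=None,
                                   target_pseudobulk=None, eps: float = 0.1):
        """Pseudobulk estimate for the target and the conversion ratio used.

        With real bulk profiles for both samples the estimate is
        ``rep_pseudobulk * alpha``; with a direct target pseudobulk the
        ratio path is bypassed.
        """
        rep_pb = self.rep.pseudobulk()
        if target_pseudobulk is not None:
            return np.asarray(target_pseudobulk, float), None
        if target_bulk is None:
            return rep_pb, None
        if self.rep_bulk is None:
            raise DataError("representative bulk needed for the ratio path")
        alpha = conversion_ratio(np.asarray(target_bulk, float),
                                 self.rep_bulk, eps)
        return infer_pseudobulk(rep_pb, alpha), alpha

    def fit(self, target_bulk=None, target_pseudobulk=None,
            target_id: str = "target", eps: float = 0.1,
            sample_latent: bool = True) -> InferenceResult:
        """Pretrain (cached), fine-tune toward the target, generate cells."""
        self.pretrain()
        self.generator.load_state_dict(self._pretrained_state)
        # fine-tuning and generation are seeded per target so results do not
        # depend on the order targets are fitted in
        self.generator.rng = np.random.default_rng(
            derive_seed(self.seed, "target", target_id))
        target_pb, alpha = self.target_pseudobulk_estimate(
            target_bulk, target_pseudobulk, eps)
        trace = dict(self._pretrain_trace)
        trace["inference"] = stage_inference(
            self.generator, self.rep, target_pb, self.schedule, self.weights)
        generated = self.generate(sample_latent=sample_latent,
                                  rng=np.random.default_rng(
                                      derive_seed(self.seed, "generate", target_id)))
        return InferenceResult(
            generated_cells=generated, loss_trace=trace, target_id=target_id,
            representative_id=self.representative_id,
            target_pb_estimate=target_pb, alpha=alpha,
            schedule=self.schedule, seed=self.seed,
            norm_target=self.rep.norm_target)

    def generate(self, sample_latent: bool = True, rng=None,
                 activation_fraction: float = 0.001) -> np.ndarray:
        """Decode every representative cell through the current generator."""
        gen = self.generator
        saved_rng = gen.rng
        if rng is not None:
            gen.rng = rng
        try:
            _, _, recon, _ = gen.reconstruct(
                self.rep.aggregated, self.rep.norm_counts.sum(axis=1),
                sample=sample_latent)
        finally:
            gen.rng = saved_rng
        return apply_activation_threshold(
            np.asarray(recon.data), self.rep.norm_target, activation_fraction)

    # -- persistence ------------------------------------------------------
    def save_checkpoint(self, path) -> None:
        path = Path(path)
        state = {f"gen.{k}": v for k, v in self.generator.state_dict().items()}
        state.update({f"disc.{k}": v for k, v in self.discriminator.state_dict().items()})
        np.savez(path.with_suffix(".npz"), **state)
        sidecar = {
            "representative_id": self.representative_id,
            "seed": self.seed,
            "n_genes": self.config.n_genes,
            "n_sets": self.config.n_sets,
            "latent_dim": self.config.latent_dim,
            "hidden_dim": self.config.hidden_dim,
            "lambda_d": self.weights.lambda_d,
            "lambda_bulk_r": self.weights.lambda_bulk_r,
            "lambda_bulk_t": self.weights.lambda_bulk_t,
            "schedule_seed": self.schedule.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    def load_checkpoint(self, path) -> "SemiProfileModel":
        archive = np.load(Path(path).with_suffix(".npz"))
        self.generator.load_state_dict(
            {k[4:]: archive[k] for k in archive.files if k.startswith("gen.")})
        self.discriminator.load_state_dict(
            {k[5:]: archive[k] for k in archive.files if k.startswith("disc.")})
        self._pretrained_state = self.generator.state_dict()
        self._pretrain_trace = {"pretrain1": [], "pretrain2": []}
        return self


def infer_target(rep: AugmentedCells, rep_bulk, target_bulk,
                 schedule: TrainingSchedule | None = None,
                 target_id: str = "target", seed: int = 0,
                 model_cache: dict | None = None,
                 use_ratio: bool = True, **model_kwargs) -> InferenceResult:
    """Infer a target sample's single-cell matrix from its representative.

    ``model_cache`` (keyed by representative id) lets one pretrained model
    serve every target assigned to the same representative. When
    ``use_ratio`` is False the bulk vectors are treated as pseudobulk and
    the conversion-ratio path is bypassed.
    """
    key = rep.sample_id
    if model_cache is not None and key in model_cache:
        model = model_cache[key]
    else:
        model = SemiProfileModel(rep, rep_bulk=rep_bulk, schedule=schedule,
                                 seed=derive_seed(seed, "rep", key),
                                 **model_kwargs)
        if model_cache is not None:
            model_cache[key] = model
    if use_ratio:
        return model.fit(target_bulk=target_bulk, target_id=target_id)
    return model.fit(target_pseudobulk=target_bulk, target_id=target_id)
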