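"""The VAE-GAN generative model and its loss terms.

The generator is a variational autoencoder: an MLP encoder maps each cell's
(neighbour-aggregated) concatenated expression/gene-set features to a
diagonal Gaussian over a latent variable z; an MLP decoder maps z to the
parameters of a zero-inflated negative binomial (ZINB) over gene expression
— mean fractions ``rho`` on the gene simplex, dropout probabilities ``pi``,
and a free gene-wise inverse-dispersion ``theta`` — following the SCVI
parameterization. A separate decoder head reconstructs gene-set scores with
a weighted Gaussian (squared-error) likelihood; gene-set features never
enter the bulk losses. The discriminator is an MLP scoring the probability
that a cell is real rather than generated. The reconstructed cell exchanged
with the discriminator and the bulk losses is the ZINB mean
``library * rho * (1 - pi)``.

Bulk-matching terms: the representative bulk loss is the L2 distance between
the pseudobulk (per-gene mean of normalized cells) of the reconstruction and
of the input; the target bulk loss replaces the input pseudobulk by the
target estimate — the representative pseudobulk times the conversion ratio
``alpha = (B_T + eps) / (B_R + eps)`` computed from real bulk profiles.

All loss functions are written against dual-dispatch math helpers, so the
same code is a differentiable training objective on tensors and a plain
numerical routine on arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ag
from ._autodiff import Tensor, concat, exp, lgamma, log, log1p, relu, sigmoid, softmax, tsum
from ._nn import Adam, Linear, Parameter, collect_state, load_state
from .errors import ConfigurationError, DataError

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "LossWeights",
    "LatentState",
    "ZINBParams",
    "Generator",
    "Discriminator",
    "zinb_nll",
    "gaussian_nll",
    "kl_to_standard_normal",
    "loss_discriminator",
    "loss_generator_pretrain1",
    "pseudobulk",
    "loss_bulk_representative",
    "conversion_ratio",
    "loss_bulk_target",
]

#: floor used inside log terms of the adversarial and ZINB losses
P_CLAMP = 1e-8


@dataclass
class GeneratorConfig:
    n_genes: int
    n_sets: int = 0
    latent_dim: int = 32
    hidden_dim: int = 256
    weight_decay: float = 1e-6

    @property
    def input_dim(self) -> int:
        return self.n_genes + self.n_sets

    def validate(self) -> None:
        if min(self.n_genes, self.latent_dim, self.hidden_dim) < 1 or self.n_sets < 0:
            raise ConfigurationError("model dimensions must be >= 1")
        if self.weight_decay < 0:
            raise ConfigurationError("weight_decay must be non-negative")


@dataclass
class DiscriminatorConfig:
    hidden_dims: tuple = (256, 128, 10)
    leaky_slope: float = 0.01


@dataclass
class LossWeights:
    """Scaling factors of the composite generator losses (all empirical)."""

    lambda_d: float = 0.01
    lambda_bulk_r: float = 1.0
    lambda_bulk_t: float = 1.0

    def validate(self) -> None:
        if min(self.lambda_d, self.lambda_bulk_r, self.lambda_bulk_t) < 0:
            raise ConfigurationError("loss weights must be non-negative")


@dataclass
class LatentState:
    mu: object  # (n, latent)
    sigma: object  # positive diagonal scales
    z: object  # reparameterized sample


@dataclass
class ZINBParams:
    rho: object  # normalized mean fractions, simplex over genes
    pi: object  # dropout probabilities in (0, 1)
    theta: object  # free positive gene-wise inverse dispersion
    mu: object  # NB mean: library * rho
    mean: object  # ZINB mean: mu * (1 - pi)


def _data(x):
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=float)


class Generator:
    """VAE generator: two-branch encoder, ZINB decoder, gene-set head."""

    def __init__(self, config: GeneratorConfig, seed: int = 0):
        config.validate()
        self.config = config
        self.rng = np.random.default_rng(seed)
        G, S, H, L = (config.n_genes, config.n_sets,
                      config.hidden_dim, config.latent_dim)
        self.enc_g = Linear(G, H, self.rng)
        self.enc_s = Linear(S, H, self.rng) if S else None
        self.enc_mu = Linear(H, L, self.rng)
        self.enc_logvar = Linear(H, L, self.rng)
        self.dec_h = Linear(L, H, self.rng)
        self.dec_rho = Linear(H, G, self.rng)
        self.dec_pi = Linear(H, G, self.rng)
        self.dec_s = Linear(H, S, self.rng) if S else None
        self.log_theta = Parameter(np.zeros(G))

    # -- parameters -------------------------------------------------------
    def named_parameters(self) -> dict:
        out = {"log_theta": self.log_theta}
        for name in ("enc_g", "enc_s", "enc_mu", "enc_logvar",
                     "dec_h", "dec_rho", "dec_pi", "dec_s"):
            layer = getattr(self, name)
            if layer is not None:
                out[f"{name}.W"] = layer.W
                out[f"{name}.b"] = layer.b
        return out

    def parameters(self):
        return list(self.named_parameters().values())

    def state_dict(self) -> dict:
        return collect_state(self.named_parameters())

    def load_state_dict(self, state: dict) -> None:
        load_state(self.named_parameters(), state)

    # -- forward ----------------------------------------------------------
    def encode(self, features, sample: bool = True) -> LatentState:
        """Map aggregated features to the latent Gaussian and draw z."""
        f = features if isinstance(features, Tensor) else Tensor(features)
        G = self.config.n_genes
        if f.shape[1] != self.config.input_dim:
            raise ConfigurationError(
                f"encoder expects {self.config.input_dim} features, got {f.shape[1]}")
        h = self.enc_g(f[:, :G])
        if self.enc_s is not None:
            h = h + self.enc_s(f[:, G:])
        h = relu(h)
        mu = self.enc_mu(h)
        logvar = self.enc_logvar(h)
        sigma = exp(logvar * 0.5)
        if sample:
            eps = self.rng.standard_normal(size=mu.shape)
            z = mu + sigma * eps
        else:
            z = mu
        return LatentState(mu=mu, sigma=sigma, z=z)

    def decode(self, z, library_size):
        """ZINB parameters and reconstructions from a latent sample.

        Returns ``(params, recon_genes, recon_sets)`` where ``recon_genes``
        is the ZINB mean and ``recon_sets`` the gene-set head output (or
        None when the model has no gene-set features).
        """
        lib = np.asarray(library_size, dtype=float).reshape(-1, 1)
        if np.any(lib <= 0):
            raise DataError("library sizes must be positive")
        zt = z if isinstance(z, Tensor) else Tensor(z)
        if zt.shape[1] != self.config.latent_dim:
            raise ConfigurationError("latent dimension mismatch")
        h = relu(self.dec_h(zt))
        rho = softmax(self.dec_rho(h), axis=1)
        pi = sigmoid(self.dec_pi(h))
        theta = exp(self.log_theta)
        mu = rho * lib
        mean = mu * (1.0 - pi)
        params = ZINBParams(rho=rho, pi=pi, theta=theta, mu=mu, mean=mean)
        recon_sets = self.dec_s(h) if self.dec_s is not None else None
        return params, mean, recon_sets

    def reconstruct(self, aggregated, library_size, sample: bool = True):
        latent = self.encode(aggregated, sample=sample)
        params, recon_genes, recon_sets = self.decode(latent.z, library_size)
        return latent, params, recon_genes, recon_sets


class Discriminator:
    """MLP scoring the probability that a cell is real-profiled."""

    def __init__(self, input_dim: int, config: DiscriminatorConfig | None = None,
                 seed: int = 0):
        self.config = config or DiscriminatorConfig()
        self.input_dim = input_dim
        rng = np.random.default_rng(seed)
        dims = [input_dim, *self.config.hidden_dims, 1]
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def named_parameters(self) -> dict:
        out = {}
        for i, layer in enumerate(self.layers):
            out[f"layer{i}.W"] = layer.W
            out[f"layer{i}.b"] = layer.b
        return out

    def parameters(self):
        return list(self.named_parameters().values())

    def state_dict(self) -> dict:
        return collect_state(self.named_parameters())

    def load_state_dict(self, state: dict) -> None:
        load_state(self.named_parameters(), state)

    def __call__(self, features):
        x = features if isinstance(features, Tensor) else Tensor(features)
        if x.shape[1] != self.input_dim:
            raise ConfigurationError(
                f"discriminator expects {self.input_dim} features, got {x.shape[1]}")
        for layer in self.layers[:-1]:
            x = ag.leaky_relu(layer(x), self.config.leaky_slope)
        return sigmoid(self.layers[-1](x))[:, 0]


# -- losses ----------------------------------------------------------------


def zinb_nll(x, params: ZINBParams, w=None):
    """Feature-weighted negative log likelihood of x under the ZINB.

    ``-sum_cells sum_features w_f log ZINB(x | rho, pi, theta)``; finite for
    finite non-negative x (the zero-mixture and NB log terms are floored at
    ``P_CLAMP`` inside the logarithms).
    """
    xd = _data(x)
    if np.any(xd < 0):
        raise DataError("expression values must be non-negative")
    pi, theta, mu = params.pi, params.theta, params.mu
    if _data(mu).shape != xd.shape:
        raise DataError("ZINB parameter/data shape mismatch")
    log_theta_over_theta_mu = log(theta) - log(theta + mu)
    nb_log_zero = theta * log_theta_over_theta_mu  # log P_NB(0)
    case_zero = log(pi + (1.0 - pi) * exp(nb_log_zero) + P_CLAMP)
    case_pos = (log(1.0 - pi + P_CLAMP)
                + lgamma(x + theta) - lgamma(theta) - lgamma(x + 1.0)
                + theta * log_theta_over_theta_mu
                + x * (log(mu + P_CLAMP) - log(theta + mu)))
    zero_mask = (xd < 1e-12).astype(float)
    ll = zero_mask * case_zero + (1.0 - zero_mask) * case_pos
    if w is not None:
        ll = ll * np.asarray(w, dtype=float)[None, :]
    return -tsum(ll)


def gaussian_nll(x, x_hat, w=None):
    """Weighted squared-error reconstruction loss for gene-set scores."""
    diff = x_hat - x
    sq = diff * diff
    if w is not None:
        sq = sq * np.asarray(w, dtype=float)[None, :]
    return 0.5 * tsum(sq)


def kl_to_standard_normal(mu, sigma):
    """Closed-form KL( N(mu, diag(sigma^2)) || N(0, I) ), summed over cells."""
    if np.any(_data(sigma) <= 0):
        raise DataError("sigma must be strictly positive")
    return 0.5 * tsum(mu * mu + sigma * sigma - 1.0 - 2.0 * log(sigma))


def loss_discriminator(d_real, d_fake):
    """Cross-entropy discriminator loss sum[-log D(real) - log(1 - D(fake))]."""
    if _data(d_real).size == 0 or _data(d_fake).size == 0:
        raise DataError("discriminator batches must be non-empty")
    return -tsum(log(d_real + P_CLAMP)) - tsum(log(1.0 - d_fake + P_CLAMP))


def loss_d_fake(d_fake):
    """Generator-side adversarial term sum[-log(1 - D(G(x)))]."""
    return -tsum(log(1.0 - d_fake + P_CLAMP))


def loss_generator_pretrain1(l_vae, l_d_fake, lambda_d: float):
    """First-stage generator loss ``L_VAE - lambda_d * L_D_Fake``."""
    return l_vae - lambda_d * l_d_fake


def pseudobulk(cells_norm):
    """Per-gene mean of a normalized cells x genes matrix (gene features
    only; gene-set scores must not be passed in)."""
    cd = _data(cells_norm)
    if cd.ndim != 2 or cd.shape[0] == 0:
        raise DataError("pseudobulk needs a non-empty cells x genes matrix")
    return ag.tmean(cells_norm, axis=0)


def _l2norm(v):
    return ag.sqrt(tsum(v * v) + 1e-30)


def loss_bulk_representative(reconstructed, original):
    """L2 distance between reconstruction pseudobulk and input pseudobulk."""
    if _data(reconstructed).shape[1] != _data(original).shape[1]:
        raise DataError("gene dimension mismatch in representative bulk loss")
    return _l2norm(pseudobulk(reconstructed) - pseudobulk(original))


def conversion_ratio(B_T, B_R, eps: float = 0.1) -> np.ndarray:
    """Element-wise pseudocount-stabilized ratio ``(B_T + eps) / (B_R + eps)``
    of target to representative real-bulk expression."""
    B_T = np.asarray(B_T, dtype=float)
    B_R = np.asarray(B_R, dtype=float)
    if B_T.shape != B_R.shape:
        raise DataError("bulk vectors must have the same length")
    if np.any(B_T < 0) or np.any(B_R < 0):
        raise DataError("bulk vectors must be non-negative")
    if eps <= 0 and np.any(B_R == 0):
        raise ZeroDivisionError(
            "eps must be positive when the representative bulk has zeros")
    return (B_T + eps) / (B_R + eps)


def loss_bulk_target(generated, rep_pseudobulk, alpha=None,
                     target_pseudobulk=None, gene_mask=None):
    """L2 distance between the generated pseudobulk and the target estimate.

    The estimate is ``rep_pseudobulk * alpha`` (conversion-ratio path) or,
    when pseudobulk inputs are available directly, ``target_pseudobulk``
    itself. ``gene_mask`` restricts the loss to a subset of genes (the
    fine-tuning mini-stages mask out highly expressed genes).
    """
    rep_pb = np.asarray(rep_pseudobulk, dtype=float)
    if target_pseudobulk is not None:
        target = np.asarray(target_pseudobulk, dtype=float)
    elif alpha is not None:
        alpha = np.asarray(alpha, dtype=float)
        if alpha.shape != rep_pb.shape:
            raise DataError("alpha/pseudobulk length mismatch")
        target = rep_pb * alpha
    else:
        target = rep_pb
    if _data(generated).shape[1] != target.shape[0]:
        raise DataError("gene dimension mismatch in target bulk loss")
    diff = pseudobulk(generated) - target
    if gene_mask is not None:
        diff = diff * np.asarray(gene_mask, dtype=float)
    return _l2norm(diff)


def infer_pseudobulk(rep_pseudobulk, alpha) -> np.ndarray:
    """Target pseudobulk estimate: representative pseudobulk ⊙ alpha."""
    rep_pb = np.asarray(rep_pseudobulk, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if rep_pb.shape != alpha.shape:
        raise DataError("alpha/pseudobulk length mismatch")
    return rep_pb * alpha
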