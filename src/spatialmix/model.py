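"""Gaussian-mixture VAE with a graph-attention encoder.

Generative model, for each unit i and mixture component j of
``n_clusters`` total:

    p(y_i = j)          = 1 / n_clusters                 (uniform prior)
    p(z_i | y_i = j)    = N(mu_prior_j, diag(sigma_prior_j^2))
    p(x_i | z_i)        = N(mu_x_i, diag(sigma_x_i^2))   (unit-wise Gaussian)

Inference couples each unit with its graph neighbors: a single-hop
graph-attention (GAT) layer aggregates the neighborhood, a softmax head
yields the soft cluster assignment q(y_i | x_i, {x}_neigh) = Yhat_i, and
per-component heads yield the Gaussian posterior q(z_i | ., y_i = j).
The unit-wise Gaussian output adapts to z-scored continuous inputs; no
count likelihood is assumed.

All arithmetic runs on the package's reverse-mode autodiff tensors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor
from .graph import MiniBatch

LOG_2PI = float(np.log(2.0 * np.pi))
_SOFTPLUS_INV_1 = float(np.log(np.expm1(1.0)))  # softplus(x) = 1


@dataclass(frozen=True)
class SoftAssignment:
    """Row-stochastic n x n_clusters soft cluster labels (Yhat)."""

    Y_hat: np.ndarray

    def __post_init__(self):
        Y = np.asarray(self.Y_hat)
        if not np.allclose(Y.sum(axis=1), 1.0, atol=1e-6) or (Y < -1e-12).any():
            raise ValueError("soft assignment rows must be probabilities summing to 1")

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.Y_hat, axis=1)


@dataclass(frozen=True)
class PosteriorParams:
    """Per-unit, per-component Gaussian posterior (n, k, d_z)."""

    mu_post: np.ndarray
    sigma_post: np.ndarray

    def __post_init__(self):
        if (np.asarray(self.sigma_post) <= 0).any():
            raise ValueError("posterior sigmas must be positive")


@dataclass
class GATLayerParams:
    """Single-hop attention layer: per-edge scores from a leaky-ReLU of the
    transformed endpoints, softmax-normalized over each target's
    in-neighborhood (self-loop included)."""

    weight: Tensor  # (d_in, d_out)
    att_src: Tensor  # (d_out,)
    att_dst: Tensor  # (d_out,)
    bias: Tensor  # (d_out,)
    negative_slope: float = 0.2


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


class MixtureModelState:
    """All learnable parameters plus architecture config.

    Prior component means are learnable (warm-started from k-means by the
    trainer); prior sigmas are learnable through a softplus with floor,
    initialized at 1. Posterior and output sigmas share the same floor,
    preventing collapse to zero variance.
    """

    def __init__(
        self,
        n_features: int,
        n_clusters: int,
        hidden_dim: int = 64,
        latent_dim: int = 16,
        sigma_floor: float = 1e-4,
        seed: int = 0,
    ):
        if n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        self.n_features = n_features
        self.n_clusters = n_clusters
        self.hidden_dim = hidden_dim
        self.latent_dim = latent_dim
        self.sigma_floor = float(sigma_floor)
        self.seed = seed
        rng = np.random.default_rng(seed)
        m, h, dz, K = n_features, hidden_dim, latent_dim, n_clusters

        def P(arr):
            return Tensor(arr, requires_grad=True)

        self.gat = GATLayerParams(
            weight=P(_glorot(rng, m, h)),
            att_src=P(rng.uniform(-0.1, 0.1, h)),
            att_dst=P(rng.uniform(-0.1, 0.1, h)),
            bias=P(np.zeros(h)),
        )
        self.params: dict[str, Tensor] = {
            "gat.weight": self.gat.weight,
            "gat.att_src": self.gat.att_src,
            "gat.att_dst": self.gat.att_dst,
            "gat.bias": self.gat.bias,
            "head_y.W": P(_glorot(rng, h, K)),
            "head_y.b": P(np.zeros(K)),
            "head_mu.W": P(_glorot(rng, h, K * dz)),
            "head_mu.b": P(np.zeros(K * dz)),
            "head_sig.W": P(_glorot(rng, h, K * dz)),
            "head_sig.b": P(np.full(K * dz, _SOFTPLUS_INV_1)),
            "dec.W1": P(_glorot(rng, dz, h)),
            "dec.b1": P(np.zeros(h)),
            "dec_mu.W": P(_glorot(rng, h, m)),
            "dec_mu.b": P(np.zeros(m)),
            "dec_sig.W": P(_glorot(rng, h, m)),
            "dec_sig.b": P(np.full(m, _SOFTPLUS_INV_1)),
            "prior.mu": P(rng.normal(0.0, 1.0, (K, dz))),
            "prior.s": P(np.full((K, dz), _SOFTPLUS_INV_1)),
        }

    # -- prior ---------------------------------------------------------------
    @property
    def mu_prior(self) -> Tensor:
        return self.params["prior.mu"]

    @property
    def sigma_prior(self) -> Tensor:
        return self.params["prior.s"].softplus() + self.sigma_floor

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        cfg = {
            "n_features": self.n_features,
            "n_clusters": self.n_clusters,
            "hidden_dim": self.hidden_dim,
            "latent_dim": self.latent_dim,
            "sigma_floor": self.sigma_floor,
            "seed": self.seed,
        }
        arrays = {k.replace(".", "__"): v.data for k, v in self.params.items()}
        np.savez(path, __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "MixtureModelState":
        with np.load(path) as f:
            cfg = json.loads(bytes(f["__config__"]).decode())
            state = cls(**cfg)
            for k in state.params:
                state.params[k].data = np.array(f[k.replace(".", "__")])
        return state


@dataclass
class InferenceOutputs:
    """Autodiff tensors from one encoder pass over batch members."""

    hidden: Tensor  # (M, h) post-activation encoder output
    Y_hat: Tensor  # (M, K)
    mu_post: Tensor  # (M, K, dz)
    sigma_post: Tensor  # (M, K, dz)

    def soft_assignment(self, rows=None) -> SoftAssignment:
        Y = self.Y_hat.data if rows is None else self.Y_hat.data[rows]
        return SoftAssignment(Y)

    def posterior(self, rows=None) -> PosteriorParams:
        if rows is None:
            return PosteriorParams(self.mu_post.data, self.sigma_post.data)
        return PosteriorParams(self.mu_post.data[rows], self.sigma_post.data[rows])


def _batch_edges(batch: MiniBatch) -> tuple[np.ndarray, np.ndarray]:
    """Neighbor edges plus self-loops for every member, as (src, dst)."""
    n_members = len(batch.member_ids)
    nb = batch.local_edges()
    loops = np.arange(n_members)
    src = np.concatenate([nb[:, 0], loops])
    dst = np.concatenate([nb[:, 1], loops])
    return src, dst


def gat_encode(batch: MiniBatch, params: GATLayerParams, X: Tensor | None = None) -> Tensor:
    """Single-hop graph attention over the batch members.

    Per edge (u -> i): score = leaky_relu(a_src . W x_u + a_dst . W x_i),
    attention = softmax of scores over i's in-neighborhood (self-loop
    included), output_i = sum_u attention_ui * W x_u + bias.
    """
    Xt = Tensor(batch.local_X) if X is None else X
    n_members = Xt.shape[0]
    src, dst = _batch_edges(batch)
    h = Xt @ params.weight  # (M, d_out)
    score_src = (h * params.att_src.reshape(1, -1)).sum(axis=1)
    score_dst = (h * params.att_dst.reshape(1, -1)).sum(axis=1)
    e = (score_src.take_rows(src) + score_dst.take_rows(dst)).leaky_relu(
        params.negative_slope
    )
    alpha = e.segment_softmax(dst, n_members)  # (E,)
    weighted = h.take_rows(src) * alpha.reshape(-1, 1)
    return weighted.segment_sum(dst, n_members) + params.bias.reshape(1, -1)


def infer(batch: MiniBatch, state: MixtureModelState, X: Tensor | None = None) -> InferenceOutputs:
    """Encoder pass: soft assignments and per-component posteriors.

    The softmax head makes every Yhat row a probability vector by
    construction; posterior sigmas go through softplus plus the floor.
    """
    M = len(batch.member_ids)
    K, dz = state.n_clusters, state.latent_dim
    hidden = gat_encode(batch, state.gat, X=X).elu()
    logits = hidden @ state.params["head_y.W"] + state.params["head_y.b"].reshape(1, -1)
    Y_hat = logits.softmax(axis=1)
    mu_post = (
        hidden @ state.params["head_mu.W"] + state.params["head_mu.b"].reshape(1, -1)
    ).reshape(M, K, dz)
    sigma_post = (
        hidden @ state.params["head_sig.W"] + state.params["head_sig.b"].reshape(1, -1)
    ).reshape(M, K, dz).softplus() + state.sigma_floor
    return InferenceOutputs(hidden=hidden, Y_hat=Y_hat, mu_post=mu_post, sigma_post=sigma_post)


def sample_all_components(
    mu_post: Tensor, sigma_post: Tensor, seed: int, eps: np.ndarray | None = None
) -> Tensor:
    """Reparameterized z = mu + sigma * eps for every component, (n, K, dz).

    ``eps`` is a test hook; when given it replaces the seeded standard
    normal draw. Gradients flow through mu and sigma only.
    """
    if eps is None:
        rng = np.random.default_rng(seed)
        eps = rng.standard_normal(mu_post.shape)
    return mu_post + sigma_post * Tensor(eps)


def sample_latent(
    post: PosteriorParams, Y: SoftAssignment, seed: int, eps: np.ndarray | None = None
) -> np.ndarray:
    """One z per unit from its most probable component, (n, d_z)."""
    z_all = sample_all_components(
        Tensor(post.mu_post), Tensor(post.sigma_post), seed, eps=eps
    ).data
    active = Y.labels
    return z_all[np.arange(len(active)), active]


def decode(z: Tensor, state: MixtureModelState) -> tuple[Tensor, Tensor]:
    """Map latents to unit-wise Gaussian output parameters (mu_x, sigma_x).

    Accepts (n, dz) or (n, K, dz); leading shape is preserved, the last
    axis becomes n_features. sigma_x is positive by softplus + floor.
    """
    lead = z.shape[:-1]
    flat = z.reshape(-1, state.latent_dim)
    h = (flat @ state.params["dec.W1"] + state.params["dec.b1"].reshape(1, -1)).tanh()
    mu_x = h @ state.params["dec_mu.W"] + state.params["dec_mu.b"].reshape(1, -1)
    sigma_x = (
        h @ state.params["dec_sig.W"] + state.params["dec_sig.b"].reshape(1, -1)
    ).softplus() + state.sigma_floor
    out_shape = lead + (state.n_features,)
    return mu_x.reshape(*out_shape), sigma_x.reshape(*out_shape)


def gaussian_log_density(x: Tensor, mu: Tensor, sigma: Tensor) -> Tensor:
    """Sum over the last axis of elementwise normal log-densities."""
    diff = x - mu
    return (
        -0.5 * LOG_2PI - sigma.log() - (diff * diff) / (2.0 * (sigma * sigma))
    ).sum(axis=-1)


def prior_log_prob(z: np.ndarray | Tensor, state: MixtureModelState) -> np.ndarray:
    """log N(z_i; mu_prior_j, diag(sigma_prior_j^2)) for every (i, j).

    The uniform component weight p(y=j) = 1/n_clusters is a separate
    constant and is not included here.
    """
    zt = z if isinstance(z, Tensor) else Tensor(z)
    n = zt.shape[0]
    K = state.n_clusters
    z3 = zt.reshape(n, 1, state.latent_dim)
    mu = state.mu_prior.reshape(1, K, state.latent_dim)
    sig = state.sigma_prior.reshape(1, K, state.latent_dim)
    return gaussian_log_density(z3, mu, sig).data


def joint_log_prob(z: np.ndarray, x: np.ndarray, state: MixtureModelState) -> np.ndarray:
    """log p(y=j, z_i, x_i) as the sum of its three factors, (n, K)."""
    log_py = -np.log(state.n_clusters)
    log_pz = prior_log_prob(z, state)
    mu_x, sigma_x = decode(Tensor(z), state)
    log_px = gaussian_log_density(Tensor(x), mu_x, sigma_x).data  # (n,)
    return log_py + log_pz + log_px[:, None]


class Adam:
    """Adam with decoupled L2 weight decay (AdamW-style; decay skips the
    mixture prior parameters so component locations stay unshrunk)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay > 0 and not k.startswith("prior."):
                p.data = p.data - self.lr * self.weight_decay * p.data
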