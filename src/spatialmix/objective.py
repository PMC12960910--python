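"""Composite training objective: image loss + ELBO + spatial JS term.

Maximized objective per unit i:

    -L_image_i + log p(x_i) - JS_i

equivalently the minimized total is

    w_img * sum_i L_image_i  -  ELBO  +  w_js * sum_i JS_i

with the evidence lower bound standing in for the marginal
log-likelihood:

    ELBO = sum_i sum_j Yhat_i(j) [ log N(x_i; mu_x_ij, sigma_x_ij^2)
                                   - KL(q(z|., y=j) || p(z|y=j)) ]
           - sum_i KL(Yhat_i || uniform)

L_image_i sums -log(Yhat_i . Yhat_j) over unit i's k cosine image
neighbors inside the mini-batch; both rows being stochastic, every term
is non-negative, zero exactly when both are one-hot on the same
component. JS_i averages the base-2 Jensen-Shannon divergence between
Yhat_i and each spatial graph neighbor, bounded in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor
from .model import gaussian_log_density

LOG2 = float(np.log(2.0))


@dataclass(frozen=True)
class LossBreakdown:
    """Per-batch (or per-epoch) sums of the three objective parts."""

    image_loss: float
    marginal_ll: float  # ELBO surrogate for sum_i log p(x_i)
    js_term: float

    @property
    def total(self) -> float:
        return self.image_loss - self.marginal_ll + self.js_term


def image_loss(
    Y_batch: Tensor | np.ndarray, neighbor_idx: np.ndarray, eps: float = 1e-8
) -> Tensor:
    """Per-unit image loss L_i = sum_{j in nbrs(i)} -log(Yhat_i . Yhat_j).

    The dot product is clamped at ``eps`` before the log to survive
    exactly-disjoint one-hot labels.
    """
    Y = Y_batch if isinstance(Y_batch, Tensor) else Tensor(Y_batch)
    b, k = neighbor_idx.shape
    rows = np.repeat(np.arange(b), k)
    nbrs = neighbor_idx.ravel()
    dots = (Y.take_rows(rows) * Y.take_rows(nbrs)).sum(axis=1)  # (b*k,)
    per_pair = -(dots.clamp_min(eps).log())
    return per_pair.reshape(b, k).sum(axis=1)


def gaussian_kl(mu_q: Tensor, sigma_q: Tensor, mu_p: Tensor, sigma_p: Tensor) -> Tensor:
    """Closed-form KL(N(mu_q, sigma_q^2) || N(mu_p, sigma_p^2)), summed over
    the last axis."""
    var_q = sigma_q * sigma_q
    var_p = sigma_p * sigma_p
    diff = mu_q - mu_p
    return (
        sigma_p.log() - sigma_q.log()
        + (var_q + diff * diff) / (2.0 * var_p)
        - 0.5
    ).sum(axis=-1)


def elbo_terms(
    x: Tensor | np.ndarray,
    Y_hat: Tensor,
    mu_post: Tensor,
    sigma_post: Tensor,
    mu_x: Tensor,
    sigma_x: Tensor,
    mu_prior: Tensor,
    sigma_prior: Tensor,
    eps: float = 1e-12,
) -> tuple[Tensor, Tensor, Tensor]:
    """Responsibility-weighted ELBO terms (reconstruction, kl_z, kl_y).

    Shapes: x (b, m); Y_hat (b, K); mu/sigma_post (b, K, dz);
    mu/sigma_x (b, K, m) decoded from one z sample per component;
    mu/sigma_prior (K, dz). Each return is the scalar sum over units.
    ELBO = reconstruction - kl_z - kl_y.
    """
    xt = x if isinstance(x, Tensor) else Tensor(x)
    b, K = Y_hat.shape
    dz = mu_post.shape[-1]
    x3 = xt.reshape(b, 1, -1)
    log_px = gaussian_log_density(x3, mu_x, sigma_x)  # (b, K)
    reconstruction = (Y_hat * log_px).sum()
    kl_z_jk = gaussian_kl(
        mu_post, sigma_post, mu_prior.reshape(1, K, dz), sigma_prior.reshape(1, K, dz)
    )  # (b, K)
    kl_z = (Y_hat * kl_z_jk).sum()
    logY = Y_hat.clamp_min(eps).log()
    kl_y = (Y_hat * (logY + float(np.log(K)))).sum()
    return reconstruction, kl_z, kl_y


def _entropy2(p: Tensor, eps: float) -> Tensor:
    """Base-2 entropy along the last axis."""
    return -(p * (p.clamp_min(eps).log() * (1.0 / LOG2))).sum(axis=-1)


def js_divergence(p: Tensor | np.ndarray, q: Tensor | np.ndarray, eps: float = 1e-12) -> Tensor:
    """Base-2 Jensen-Shannon divergence between rows of p and q, in [0, 1].

    JS(p || q) = H2(m) - (H2(p) + H2(q)) / 2 with m = (p + q) / 2.
    """
    pt = p if isinstance(p, Tensor) else Tensor(p)
    qt = q if isinstance(q, Tensor) else Tensor(q)
    m = (pt + qt) * 0.5
    return _entropy2(m, eps) - (_entropy2(pt, eps) + _entropy2(qt, eps)) * 0.5


def js_neighbor_term(
    Y_targets: Tensor, Y_members: Tensor, local_neighbors: np.ndarray
) -> Tensor:
    """Per-unit mean JS divergence to the spatial graph neighbors.

    ``local_neighbors[t]`` indexes rows of ``Y_members`` (the batch
    closure); targets are the first rows of the member set.
    """
    b, k = local_neighbors.shape
    rows = np.repeat(np.arange(b), k)
    js = js_divergence(
        Y_targets.take_rows(rows), Y_members.take_rows(local_neighbors.ravel())
    )
    return js.reshape(b, k).mean(axis=1)


def total_loss(
    image_part: Tensor | float,
    elbo: Tensor | float,
    js_part: Tensor | float,
    w_image: float = 1.0,
    w_js: float = 1.0,
):
    """Minimized objective  w_img * image_loss - ELBO + w_js * JS.

    Setting ``w_image = 0`` recovers the image-free ablation exactly.
    Raises on non-finite parts, naming the offending term.
    """
    for name, part in (("image_loss", image_part), ("elbo", elbo), ("js_term", js_part)):
        val = part.data if isinstance(part, Tensor) else part
        if not np.all(np.isfinite(val)):
            raise FloatingPointError(f"non-finite loss component: {name}")
    return w_image * image_part - elbo + w_js * js_part
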