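"""The masked three-layer survival network and its penalty terms.

Architecture: gene layer → pathway layer → scalar output,

    f_W(x, M) = tanh( tanh( x · (W1 ⊙ M) ) · W2 ),

where W1 ∈ R_+^{G×P} holds gene→pathway weights constrained element-wise
non-negative (genes of a pathway act in a common direction on its activity)
and M is a binary incidence mask: prior connectivity during pre-training, the
all-ones matrix E when exploring beyond the prior sets.

Two penalties shape W1:

* a standard-deviation penalty over the prior (mask=1) entries, encouraging
  near-equal importance of the genes within the prior modules;
* an L1 penalty over the non-prior (mask=0) entries, selecting a sparse set of
  supplement gene→pathway links.

Everything here is plain NumPy; gradients of the loss are analytic (the model
is three matrix products and two tanh's) and exact sparsity comes from the
non-negativity projection / soft-thresholding, not from an autodiff graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import PathwayMask

__all__ = [
    "NetworkWeights",
    "init_weights",
    "forward",
    "std_penalty",
    "std_penalty_grad",
    "l1_penalty",
    "project_nonneg",
    "prox_l1_nonprior",
    "loss_gradients",
]


@dataclass
class NetworkWeights:
    """Learnable parameters: W1 (G×P, ≥ 0) and W2 (P×1)."""

    w1: np.ndarray
    w2: np.ndarray

    def __post_init__(self) -> None:
        self.w1 = np.asarray(self.w1, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float).reshape(-1, 1)
        if self.w1.ndim != 2 or self.w1.shape[1] != self.w2.shape[0]:
            raise ValueError("W1 (G×P) and W2 (P×1) shapes disagree")
        if not (np.isfinite(self.w1).all() and np.isfinite(self.w2).all()):
            raise ValueError("non-finite weight")
        if (self.w1 < 0).any():
            raise ValueError("W1 must be element-wise non-negative")

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(self.w1.copy(), self.w2.copy())


def init_weights(mask: PathwayMask, rng: np.random.Generator) -> NetworkWeights:
    """Non-negative start: masked W1 entries ~ U(0, 0.1), others exactly 0;
    W2 ~ U(0, 1/√P).

    W2 starts positive on purpose: with W1 constrained non-negative, a pathway
    whose output weight initializes negative has its whole W1 column pushed to
    zero, after which the unit is dead (zero activity, zero gradient). A
    positive start lets every pathway unit engage; W2 may still change sign
    during training.
    """
    g, p = mask.shape
    w1 = rng.uniform(0.0, 0.1, size=(g, p)) * mask.values
    w2 = rng.uniform(0.0, 1.0 / np.sqrt(p), size=(p, 1))
    return NetworkWeights(w1, w2)


def forward(
    X: np.ndarray, weights: NetworkWeights, mask_values: np.ndarray
) -> np.ndarray:
    """Per-sample log-risk scores tanh(tanh(X·(W1⊙M))·W2), in (−1, 1)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != weights.w1.shape[0]:
        raise ValueError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} genes, "
            f"W1 expects {weights.w1.shape[0]}"
        )
    if mask_values.shape != weights.w1.shape:
        raise ValueError("mask and W1 shapes disagree")
    hidden = np.tanh(X @ (weights.w1 * mask_values))
    return np.tanh(hidden @ weights.w2).ravel()


def std_penalty(weights: NetworkWeights, mask_values: np.ndarray) -> float:
    """Population standard deviation of the W1 entries at mask=1 positions,
    pooled across pathways. Fewer than two prior entries → 0."""
    entries = weights.w1[mask_values == 1]
    if entries.size < 2:
        return 0.0
    return float(np.sqrt(np.mean((entries - entries.mean()) ** 2)))


def std_penalty_grad(weights: NetworkWeights, mask_values: np.ndarray) -> np.ndarray:
    """∂ Std(W1⊙M) / ∂ W1 — non-zero only at mask=1 positions.

    For s = sqrt(mean((w−m)²)) over the K masked entries,
    ∂s/∂w_k = (w_k − m) / (K·s); zero at s = 0 (a valid subgradient choice).
    """
    grad = np.zeros_like(weights.w1)
    sel = mask_values == 1
    entries = weights.w1[sel]
    if entries.size < 2:
        return grad
    s = np.sqrt(np.mean((entries - entries.mean()) ** 2))
    if s == 0.0:
        return grad
    grad[sel] = (entries - entries.mean()) / (entries.size * s)
    return grad


def l1_penalty(weights: NetworkWeights, mask_values: np.ndarray) -> float:
    """‖W1 ⊙ (1−M)‖₁ — absolute mass on the non-prior links only."""
    return float(np.abs(weights.w1[mask_values == 0]).sum())


def project_nonneg(weights: NetworkWeights) -> NetworkWeights:
    """Clamp W1 at zero element-wise; W2 is unconstrained."""
    return NetworkWeights(np.maximum(weights.w1, 0.0), weights.w2)


def prox_l1_nonprior(
    weights: NetworkWeights, mask_values: np.ndarray, threshold: float
) -> NetworkWeights:
    """Soft-threshold the non-prior entries of W1 by ``threshold``.

    w ← sign(w)·max(|w|−threshold, 0) where mask=0; prior entries untouched.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    w1 = weights.w1.copy()
    sel = mask_values == 0
    w1[sel] = np.sign(w1[sel]) * np.maximum(np.abs(w1[sel]) - threshold, 0.0)
    return NetworkWeights(w1, weights.w2)


def loss_gradients(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    weights: NetworkWeights,
    mask_values: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Negative log partial likelihood and its gradients w.r.t. W1 and W2.

    The gradient with respect to W1 is already masked (chain rule through
    W1 ⊙ M), so masked-out entries receive exactly zero gradient.

    Returns (loss, dW1, dW2).
    """
    events = np.flatnonzero(event == 1)
    if events.size == 0:
        raise ValueError("no events: the partial likelihood is undefined")

    a = weights.w1 * mask_values
    z1 = X @ a
    hidden = np.tanh(z1)
    z2 = hidden @ weights.w2
    f = np.tanh(z2).ravel()

    # risk-set structure: rows = events, columns = all samples
    at_risk = time[None, :] >= time[events, None]
    shift = f.max()
    expf = np.exp(f - shift)
    denoms = (expf[None, :] * at_risk).sum(axis=1)
    loss = -float(np.sum(f[events] - (shift + np.log(denoms))))

    # dL/df_j = -δ_j + Σ_{events i with T_j ≥ T_i} exp(f_j)/denom_i
    dl_df = (at_risk / denoms[:, None]).sum(axis=0) * expf
    dl_df[events] -= 1.0

    dz2 = (dl_df * (1.0 - f**2))[:, None]          # N×1
    dw2 = hidden.T @ dz2                            # P×1
    dhidden = dz2 @ weights.w2.T                    # N×P
    dz1 = dhidden * (1.0 - hidden**2)               # N×P
    dw1 = (X.T @ dz1) * mask_values                 # G×P, masked by chain rule
    return loss, dw1, dw2
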