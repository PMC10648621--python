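"""Two-phase training of the pathway-masked survival network.

The model optimizes the negative log Cox partial likelihood in two phases:

* **pre-training** — connectivity restricted to the prior pathway mask M, with
  a standard-deviation penalty λ·Std(W1⊙M) pulling the prior gene weights of
  the modules toward equal importance;
* **training (expansion)** — fully connected first layer E, with an L1
  penalty μ·‖W1⊙(1−M)‖₁ on the non-prior links so that only a few supplement
  genes enter the pathways.

Optimization is full-batch Adam with a fixed epoch budget per phase; after
every step W1 is projected onto the non-negative orthant, which is also what
makes "this link is absent" (W1 = 0 exactly) a realizable outcome. The L1
term enters through its one-sided subgradient (+μ on non-prior entries) by
default; a proximal variant (soft-thresholding by μ·lr after the Adam step)
is available via ``TrainConfig.l1_mode="proximal"``.

Two baselines bracket the method: a **prior net** (the phase-1 objective for
the full epoch budget) and a **fully connected net** (the phase-2 objective
from a random start).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datasets import PathwayMask, SurvivalDataset
from .network import (
    NetworkWeights,
    forward,
    init_weights,
    l1_penalty,
    loss_gradients,
    project_nonneg,
    prox_l1_nonprior,
    std_penalty,
    std_penalty_grad,
)
from .stats import concordance_index

__all__ = [
    "TrainConfig",
    "PathwaySurvivalNet",
    "SurvivalNetResults",
    "pretrain",
    "train_expand_phase",
    "run_two_phase",
    "train_prior_net",
    "train_fc_net",
    "cross_validate",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of the two-phase scheme.

    Defaults: full-batch Adam at learning rate 0.05, 100 epochs per phase,
    λ = μ = 1.
    """

    learning_rate: float = 0.05
    epochs_pretrain: int = 100
    epochs_train: int = 100
    lambda_std: float = 1.0
    mu_l1: float = 1.0
    seed: int = 0
    l1_mode: str = "subgradient"  # or "proximal"
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    track_cindex: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs_pretrain <= 0 or self.epochs_train <= 0:
            raise ValueError("epoch counts must be positive")
        if self.lambda_std < 0 or self.mu_l1 < 0:
            raise ValueError("penalty weights must be non-negative")
        if self.l1_mode not in ("subgradient", "proximal"):
            raise ValueError(f"unknown l1_mode {self.l1_mode!r}")


class _Adam:
    """Plain Adam with bias correction, one state per parameter array."""

    def __init__(self, shapes, lr, betas, eps):
        self.lr, (self.b1, self.b2), self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]

    def step(self, params, grads):
        self.t += 1
        out = []
        for k, (p, g) in enumerate(zip(params, grads)):
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            out.append(p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


def _run_phase(
    data: SurvivalDataset,
    mask: PathwayMask,
    weights: NetworkWeights,
    cfg: TrainConfig,
    epochs: int,
    phase: str,
    test_data: SurvivalDataset | None = None,
) -> tuple[NetworkWeights, pd.DataFrame]:
    """Run one training phase and return (final weights, per-epoch history).

    ``phase`` is ``"pretrain"`` (mask M + Std penalty) or ``"train"`` (mask E
    + L1 on non-prior links).
    """
    if data.n_events == 0:
        raise ValueError("dataset has no events")
    X = data.X()
    prior = mask.values
    if phase == "pretrain":
        mvals = prior
    elif phase == "train":
        mvals = np.ones_like(prior)
    else:
        raise ValueError(f"unknown phase {phase!r}")
    nonprior = 1.0 - prior

    adam = _Adam(
        [weights.w1.shape, weights.w2.shape],
        cfg.learning_rate,
        cfg.adam_betas,
        cfg.adam_eps,
    )
    w = weights.copy()
    rows = []
    Xt = test_data.X() if test_data is not None else None
    for epoch in range(epochs):
        loss, dw1, dw2 = loss_gradients(X, data.time, data.event, w, mvals)
        objective = loss
        if phase == "pretrain" and cfg.lambda_std > 0:
            objective += cfg.lambda_std * std_penalty(w, prior)
            dw1 = dw1 + cfg.lambda_std * std_penalty_grad(w, prior)
        if phase == "train":
            if cfg.l1_mode == "subgradient":
                # one-sided subgradient of |w| on the non-negative orthant
                dw1 = dw1 + cfg.mu_l1 * nonprior
            objective += cfg.mu_l1 * l1_penalty(w, prior)
        if not np.isfinite(objective):
            raise RuntimeError(f"non-finite loss at {phase} epoch {epoch}")

        if cfg.track_cindex:
            risk = forward(X, w, mvals)
            c_train = concordance_index(risk, data.time, data.event)
            c_test = np.nan
            if test_data is not None:
                c_test = concordance_index(
                    forward(Xt, w, mvals), test_data.time, test_data.event
                )
            rows.append((phase, objective, c_train, c_test))
        else:
            rows.append((phase, objective, np.nan, np.nan))

        w1, w2 = adam.step([w.w1, w.w2], [dw1, dw2])
        w = NetworkWeights(np.maximum(w1, 0.0), w2)
        if phase == "train" and cfg.l1_mode == "proximal":
            w = prox_l1_nonprior(w, prior, cfg.mu_l1 * cfg.learning_rate)
            w = project_nonneg(w)

    history = pd.DataFrame(rows, columns=["phase", "loss", "c_train", "c_test"])
    history.insert(0, "epoch", np.arange(len(history)))
    return w, history


def pretrain(
    data: SurvivalDataset,
    mask: PathwayMask,
    cfg: TrainConfig,
    test_data: SurvivalDataset | None = None,
    weights: NetworkWeights | None = None,
) -> tuple[NetworkWeights, pd.DataFrame]:
    """Phase 1: fit under the prior mask from a fresh non-negative start."""
    if weights is None:
        weights = init_weights(mask, np.random.default_rng(cfg.seed))
    return _run_phase(data, mask, weights, cfg, cfg.epochs_pretrain, "pretrain", test_data)


def train_expand_phase(
    data: SurvivalDataset,
    mask: PathwayMask,
    warm: NetworkWeights,
    cfg: TrainConfig,
    test_data: SurvivalDataset | None = None,
) -> tuple[NetworkWeights, pd.DataFrame]:
    """Phase 2: continue from pre-trained weights with full connectivity."""
    if (warm.w1 < 0).any():
        raise ValueError("warm-start W1 must be non-negative")
    return _run_phase(data, mask, warm, cfg, cfg.epochs_train, "train", test_data)


def run_two_phase(
    data: SurvivalDataset,
    mask: PathwayMask,
    cfg: TrainConfig,
    test_data: SurvivalDataset | None = None,
) -> tuple[NetworkWeights, pd.DataFrame]:
    """Pre-training then expansion training, with concatenated history."""
    w, hist1 = pretrain(data, mask, cfg, test_data)
    w, hist2 = train_expand_phase(data, mask, w, cfg, test_data)
    hist = pd.concat([hist1, hist2], ignore_index=True)
    hist["epoch"] = np.arange(len(hist))
    return w, hist


def train_prior_net(
    data: SurvivalDataset,
    mask: PathwayMask,
    cfg: TrainConfig,
    test_data: SurvivalDataset | None = None,
) -> tuple[NetworkWeights, pd.DataFrame]:
    """Baseline: the phase-1 objective for the full epoch budget."""
    total = cfg.epochs_pretrain + cfg.epochs_train
    weights = init_weights(mask, np.random.default_rng(cfg.seed))
    return _run_phase(data, mask, weights, cfg, total, "pretrain", test_data)


def train_fc_net(
    data: SurvivalDataset,
    mask: PathwayMask,
    cfg: TrainConfig,
    test_data: SurvivalDataset | None = None,
) -> tuple[NetworkWeights, pd.DataFrame]:
    """Baseline: the phase-2 (fully connected, L1) objective from random init."""
    total = cfg.epochs_pretrain + cfg.epochs_train
    weights = init_weights(mask.all_ones(), np.random.default_rng(cfg.seed))
    return _run_phase(data, mask, weights, cfg, total, "train", test_data)


_METHODS = {
    "two_phase": run_two_phase,
    "prior": train_prior_net,
    "fully_connected": train_fc_net,
}


class PathwaySurvivalNet:
    """Pathway-masked neural survival model (statsmodels-style).

    Parameters
    ----------
    data
        Preprocessed (z-scored) expression plus outcomes.
    mask
        Prior gene × pathway incidence; its gene order must match the data.
    config
        Training hyper-parameters; defaults follow the two-phase scheme.

    Examples
    --------
    >>> model = PathwaySurvivalNet(data, mask)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        data: SurvivalDataset,
        mask: PathwayMask,
        config: TrainConfig | None = None,
    ) -> None:
        if list(data.gene_ids) != list(mask.gene_ids):
            raise ValueError("gene order of data and mask disagree")
        self.data = data
        self.mask = mask
        self.config = config or TrainConfig()

    def fit(
        self,
        method: str = "two_phase",
        test_data: SurvivalDataset | None = None,
    ) -> "SurvivalNetResults":
        if method not in _METHODS:
            raise ValueError(f"unknown method {method!r}; one of {sorted(_METHODS)}")
        weights, history = _METHODS[method](
            self.data, self.mask, self.config, test_data
        )
        return SurvivalNetResults(self, method, weights, history)

    def fit_ensemble(self, runs: int = 100, subsample: float = 0.9):
        """Resampled two-phase fits for stability selection (see expansion)."""
        from .expansion import run_ensemble

        return run_ensemble(self.data, self.mask, self.config, runs, subsample)


@dataclass
class SurvivalNetResults:
    """Fitted weights plus the per-epoch training history.

    ``history`` columns: epoch, phase, loss (full objective), c_train, c_test
    (concordance on the 0–1 scale; summaries print percentages).
    """

    model: PathwaySurvivalNet
    method: str
    weights: NetworkWeights
    history: pd.DataFrame

    def predict(self, expression: pd.DataFrame | None = None) -> np.ndarray:
        """Log-risk scores; genes are aligned by label when a frame is given."""
        mask = self.model.mask
        if expression is None:
            X = self.model.data.X()
        else:
            missing = set(mask.gene_ids) - set(expression.columns)
            if missing:
                raise ValueError(f"expression lacks {len(missing)} model genes")
            X = expression[list(mask.gene_ids)].to_numpy(dtype=float)
        mvals = (
            mask.values if self.method == "prior" else np.ones_like(mask.values)
        )
        return forward(X, self.weights, mvals)

    def concordance(self, data: SurvivalDataset | None = None) -> float:
        data = data or self.model.data
        return concordance_index(
            self.predict(data.expression), data.time, data.event
        )

    def phase_final_cindex(self) -> dict[str, float]:
        """Last recorded train C-index of each phase present in the history."""
        out = {}
        for phase, grp in self.history.groupby("phase", sort=False):
            out[phase] = float(grp["c_train"].iloc[-1])
        return out

    def active_nonprior_pairs(self) -> int:
        """Number of non-prior gene→pathway links with strictly positive weight."""
        return int(((self.weights.w1 > 0) & (self.model.mask.values == 0)).sum())

    def summary(self) -> str:
        mask = self.model.mask
        lines = [
            "Pathway survival network results",
            "=" * 40,
            f"method:            {self.method}",
            f"samples / events:  {self.model.data.n_samples} / {self.model.data.n_events}",
            f"genes × pathways:  {mask.shape[0]} × {mask.shape[1]}",
            f"prior pairs (K):   {mask.n_pairs}",
            f"epochs trained:    {len(self.history)}",
        ]
        for phase, c in self.phase_final_cindex().items():
            if np.isfinite(c):
                lines.append(f"final train C-index [{phase}]: {100 * c:.2f}%")
        ct = self.history["c_test"].dropna()
        if len(ct):
            lines.append(f"final test C-index:  {100 * ct.iloc[-1]:.2f}%")
        lines.append(f"active non-prior links: {self.active_nonprior_pairs()}")
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Training-curve plot: objective and C-index per epoch, phases shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        ax.plot(self.history["epoch"], self.history["loss"], label="objective")
        ax.set_xlabel("epoch")
        ax.set_ylabel("objective")
        if self.history["c_train"].notna().any():
            ax2 = ax.twinx()
            ax2.plot(
                self.history["epoch"],
                self.history["c_train"],
                color="tab:orange",
                label="train C-index",
            )
            if self.history["c_test"].notna().any():
                ax2.plot(
                    self.history["epoch"],
                    self.history["c_test"],
                    color="tab:green",
                    label="test C-index",
                )
            ax2.set_ylabel("C-index")
        switch = (self.history["phase"] != self.history["phase"].shift()).to_numpy()
        for e in self.history["epoch"][switch][1:]:
            ax.axvline(e, color="grey", linestyle="--", linewidth=0.8)
        ax.legend(loc="upper right")
        return ax


def cross_validate(
    data: SurvivalDataset,
    mask: PathwayMask,
    cfg: TrainConfig,
    folds: int = 10,
    method: str = "two_phase",
) -> pd.DataFrame:
    """K-fold cross-validation; returns per-fold held-out concordance.

    Samples are partitioned by a seeded permutation (each sample is tested
    exactly once); with ``folds=10`` every training set holds ~90% of the
    samples. A fold whose training part has no events triggers one re-draw
    with a shifted seed, then an error.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if folds > data.n_samples:
        raise ValueError("more folds than samples")

    def _assign(seed):
        perm = np.random.default_rng(seed).permutation(data.n_samples)
        return np.array_split(perm, folds)

    parts = _assign(cfg.seed)
    for attempt in range(2):
        ok = all(
            data.event[np.setdiff1d(np.arange(data.n_samples), p)].sum() > 0
            for p in parts
        )
        if ok:
            break
        if attempt == 1:
            raise ValueError("a training fold has no events after one re-draw")
        parts = _assign(cfg.seed + 1)

    rows = []
    for k, test_idx in enumerate(parts):
        train_idx = np.setdiff1d(np.arange(data.n_samples), test_idx)
        d_train, d_test = data.subset(train_idx), data.subset(test_idx)
        fold_cfg = replace(cfg, seed=cfg.seed + 1000 + k, track_cindex=False)
        weights, _ = _METHODS[method](d_train, mask, fold_cfg)
        mvals = mask.values if method == "prior" else np.ones_like(mask.values)
        risk = forward(d_test.X(), weights, mvals)
        rows.append(
            (k, len(test_idx), concordance_index(risk, d_test.time, d_test.event))
        )
    return pd.DataFrame(rows, columns=["fold", "n_test", "c_index"])
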