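"""Validation analyses on top of a fitted expansion.

Two checks mirror how the expansion is validated in practice:

* **recoverability testing** — remove one prior gene from its pathway at a
  time, rerun the resampled two-phase pipeline, and ask how often the removed
  gene is re-selected (its "recovering probability"). True prior genes should
  be recovered far more often than arbitrary non-prior genes; the two
  probability distributions are compared with a two-sample KS test.
* **single-gene Kaplan–Meier analysis** — split the cohort at the median
  expression of one gene and compare the two survival curves with a log-rank
  test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datasets import PathwayMask, SurvivalDataset
from .expansion import occurrence_probability, run_ensemble
from .model import TrainConfig
from .stats import SurvivalCurve, kaplan_meier, logrank_test, median_split

logger = logging.getLogger(__name__)

__all__ = ["RecoveryReport", "recoverability_test", "ks_compare", "single_gene_km"]


@dataclass
class RecoveryReport:
    """Outcome of the leave-one-out recoverability test.

    ``left_out`` has one row per removed prior pair (gene, pathway,
    recover_prob, rank); ``nonprior_probs`` holds the per-pair mean occurrence
    probability of the true non-prior pairs over the same runs (the baseline
    distribution); ``ks_stat``/``ks_p`` compare the two distributions.
    """

    left_out: pd.DataFrame
    nonprior_probs: np.ndarray
    ks_stat: float
    ks_p: float

    def summary(self) -> str:
        lo = self.left_out["recover_prob"]
        return "\n".join(
            [
                "Recoverability test",
                "=" * 40,
                f"left-out prior pairs tested: {len(self.left_out)}",
                f"median recovering probability (left-out): {lo.median():.2f}",
                f"median recovering probability (non-prior): "
                f"{np.median(self.nonprior_probs):.2f}",
                f"KS statistic: {self.ks_stat:.3f}   p-value: {self.ks_p:.2e}",
            ]
        )


def recoverability_test(
    data: SurvivalDataset,
    mask: PathwayMask,
    cfg: TrainConfig,
    runs_per_gene: int = 20,
    pairs: list[tuple[int, int]] | None = None,
    subsample: float = 0.9,
) -> RecoveryReport:
    """Leave-one-out recoverability of the prior genes.

    For each prior pair (i, j) in ``pairs`` (default: all prior pairs): zero
    M[i, j], run the resampled two-phase ensemble ``runs_per_gene`` times, and
    record the fraction of runs in which W1[i, j] ended strictly positive,
    plus the rank of that occurrence probability among all candidate (masked
    out) pairs of pathway j. A pathway that removal would empty is skipped
    with a warning.
    """
    if runs_per_gene < 1:
        raise ValueError("runs_per_gene must be at least 1")
    if pairs is None:
        pairs = [tuple(ij) for ij in np.argwhere(mask.values == 1)]
    nonprior_sel = mask.values == 0
    nonprior_sum = np.zeros(int(nonprior_sel.sum()))
    rows = []
    n_done = 0
    for idx, (i, j) in enumerate(pairs):
        if mask.values[i, j] != 1:
            raise ValueError(f"pair ({i}, {j}) is not a prior pair")
        modified = mask.values.copy()
        modified[i, j] = 0.0
        if modified[:, j].sum() == 0:
            logger.warning(
                "recoverability: removing %s would empty pathway %s; skipped",
                mask.gene_ids[i],
                mask.pathway_names[j],
            )
            continue
        mod_mask = PathwayMask(modified, list(mask.gene_ids), list(mask.pathway_names))
        run_cfg = replace(cfg, seed=cfg.seed + 20000 * (idx + 1))
        ens = run_ensemble(data, mod_mask, run_cfg, runs=runs_per_gene, subsample=subsample)
        S = occurrence_probability(ens)
        prob = float(S[i, j])
        # candidate pool: pairs of pathway j absent from the modified mask
        pool = np.flatnonzero(modified[:, j] == 0)
        pool_probs = S[pool, j]
        rank = 1 + int((pool_probs > prob).sum())
        rows.append((mask.gene_ids[i], mask.pathway_names[j], prob, rank))
        nonprior_sum += S[nonprior_sel]
        n_done += 1
    if n_done == 0:
        raise ValueError("no testable prior pairs")
    left_out = pd.DataFrame(
        rows, columns=["gene", "pathway", "recover_prob", "rank"]
    )
    nonprior_probs = nonprior_sum / n_done
    ks_stat, ks_p = ks_compare(left_out["recover_prob"].to_numpy(), nonprior_probs)
    return RecoveryReport(left_out, nonprior_probs, ks_stat, ks_p)


def ks_compare(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov–Smirnov statistic and asymptotic p."""
    sample_a = np.asarray(sample_a, dtype=float).ravel()
    sample_b = np.asarray(sample_b, dtype=float).ravel()
    if sample_a.size == 0 or sample_b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(sample_a, sample_b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def single_gene_km(
    data: SurvivalDataset, gene: str
) -> tuple[SurvivalCurve, SurvivalCurve, float, float]:
    """Median-split survival analysis of one gene.

    Samples strictly above the median expression form the high group; returns
    (curve_high, curve_low, logrank_statistic, logrank_p).
    """
    if gene not in data.expression.columns:
        raise KeyError(f"gene {gene!r} not in the dataset")
    expr = data.expression[gene].to_numpy(dtype=float)
    high = median_split(expr)
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValueError("a group with fewer than 2 samples after the split")
    t_h, e_h = data.time[high], data.event[high]
    t_l, e_l = data.time[~high], data.event[~high]
    stat, p = logrank_test(t_h, e_h, t_l, e_l)
    return kaplan_meier(t_h, e_h), kaplan_meier(t_l, e_l), stat, p
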