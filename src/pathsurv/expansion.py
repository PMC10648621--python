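"""Pathway expansion by stability selection over resampled fits.

Pipeline: refit the two-phase model on random 90% subsamples of the cohort
(default 100 repeats); binarize each fitted first-layer weight matrix into an
occurrence matrix O^(k) = 1[W1^(k) > 0]; average the stack into an occurrence
probability matrix S; and keep the ⌊(1+α)K + 1/2⌋ gene–pathway pairs with the
highest occurrence probability, where K is the number of prior pairs and α
(default 0.2) controls how far beyond the prior sets the expansion reaches.
Selected pairs outside the prior mask are the **supplement genes** of each
pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datasets import PathwayMask, SurvivalDataset
from .model import TrainConfig, run_two_phase

logger = logging.getLogger(__name__)

__all__ = [
    "OccurrenceEnsemble",
    "ExpandedPathways",
    "run_ensemble",
    "occurrence_probability",
    "select_expanded",
    "supplement_genes",
    "ranked_gene_lists",
    "write_probability_tsv",
    "write_expanded_gmt",
    "write_supplement_tsv",
    "write_rnk",
]


@dataclass
class OccurrenceEnsemble:
    """Stack of binary occurrence matrices (and the fitted W1's) from
    resampled two-phase fits; axes are shared across runs."""

    occurrences: np.ndarray  # runs × G × P, in {0, 1}
    weights: np.ndarray      # runs × G × P, the fitted W1 per run
    run_seeds: list[int]
    gene_ids: list[str]
    pathway_names: list[str]

    def __post_init__(self) -> None:
        if self.occurrences.ndim != 3:
            raise ValueError("occurrences must be runs × genes × pathways")
        if self.occurrences.shape != self.weights.shape:
            raise ValueError("occurrence and weight stacks disagree in shape")
        if not np.isin(self.occurrences, (0, 1)).all():
            raise ValueError("occurrences must be binary")

    @property
    def n_runs(self) -> int:
        return self.occurrences.shape[0]

    def mean_weights(self) -> np.ndarray:
        """Mean fitted W1 across runs (G × P)."""
        return self.weights.mean(axis=0)


@dataclass
class ExpandedPathways:
    """Post-selection incidence R plus bookkeeping.

    ``values`` has exactly ``selected_count`` = ⌊(1+α)K + 1/2⌋ ones; pairs in
    R but not in the prior mask are the supplement gene–pathway pairs.
    """

    values: np.ndarray  # binary G × P
    gene_ids: list[str]
    pathway_names: list[str]
    alpha: float
    prior_pairs: int          # K
    selected_count: int
    probabilities: np.ndarray  # the S matrix used for selection

    def supplement_mask(self, prior: PathwayMask) -> np.ndarray:
        """Binary G×P of selected non-prior pairs: R ∧ ¬M."""
        return self.values * (1.0 - prior.values)

    def dropped_prior_pairs(self, prior: PathwayMask) -> list[tuple[str, str]]:
        """Prior pairs that fell below the selection threshold (diagnostics)."""
        out = []
        for i, j in zip(*np.where((prior.values == 1) & (self.values == 0))):
            out.append((self.gene_ids[i], self.pathway_names[j]))
        return out

    def to_collection(self):
        from .datasets import PathwayCollection

        members = []
        for j, name in enumerate(self.pathway_names):
            order = np.argsort(-self.probabilities[:, j], kind="stable")
            members.append(
                [self.gene_ids[i] for i in order if self.values[i, j] == 1]
            )
        return PathwayCollection(list(self.pathway_names), members)


def run_ensemble(
    data: SurvivalDataset,
    mask: PathwayMask,
    cfg: TrainConfig,
    runs: int = 100,
    subsample: float = 0.9,
    max_redraws: int = 10,
) -> OccurrenceEnsemble:
    """Two-phase fits on ``runs`` random subsamples (without replacement).

    Run k draws ⌊subsample·N⌋ samples with seed ``cfg.seed + k`` (re-drawing,
    up to ``max_redraws`` times, if the subsample holds no events) and records
    O^(k) = 1[W1^(k) > 0].
    """
    if not 0 < subsample <= 1:
        raise ValueError("subsample must be in (0, 1]")
    if runs < 1:
        raise ValueError("need at least one run")
    n_keep = int(np.floor(subsample * data.n_samples))
    if n_keep < 2:
        raise ValueError("subsample too small")
    g, p = mask.shape
    occ = np.zeros((runs, g, p))
    wts = np.zeros((runs, g, p))
    seeds = []
    for k in range(runs):
        seed = cfg.seed + k
        rng = np.random.default_rng(seed)
        for _ in range(max_redraws):
            idx = rng.choice(data.n_samples, size=n_keep, replace=False)
            if data.event[idx].sum() > 0:
                break
        else:
            raise RuntimeError(f"run {k}: no events in any subsample draw")
        sub = data.subset(np.sort(idx))
        run_cfg = replace(cfg, seed=seed, track_cindex=False)
        try:
            weights, _ = run_two_phase(sub, mask, run_cfg)
        except Exception as err:  # noqa: BLE001 - re-raise with run index
            raise RuntimeError(f"ensemble run {k} failed: {err}") from err
        occ[k] = (weights.w1 > 0).astype(float)
        wts[k] = weights.w1
        seeds.append(seed)
        logger.debug("ensemble run %d: seed %d, %d samples", k, seed, n_keep)
    return OccurrenceEnsemble(occ, wts, seeds, list(mask.gene_ids), list(mask.pathway_names))


def occurrence_probability(ensemble: OccurrenceEnsemble) -> np.ndarray:
    """S(i,j) — fraction of runs in which link (i,j) had positive weight."""
    return ensemble.occurrences.mean(axis=0)


def select_expanded(
    S: np.ndarray,
    mask: PathwayMask,
    alpha: float = 0.2,
    mean_weight: np.ndarray | None = None,
) -> ExpandedPathways:
    """Keep the n* = ⌊(1+α)K + 1/2⌋ pairs with the highest occurrence
    probability.

    Ties at the cut are broken deterministically: higher mean fitted weight
    (when ``mean_weight`` is given), then lower gene index, then lower pathway
    index — so exactly n* pairs are always selected.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    S = np.asarray(S, dtype=float)
    if S.shape != mask.shape:
        raise ValueError("S and mask shapes disagree")
    K = mask.n_pairs
    if K < 1:
        raise ValueError("prior mask has no pairs")
    n_star = int(np.floor((1 + alpha) * K + 0.5))
    g, p = S.shape
    if n_star > g * p:
        raise ValueError(f"cannot select {n_star} pairs from a {g}×{p} matrix")

    mw = np.zeros_like(S) if mean_weight is None else np.asarray(mean_weight, float)
    gene_idx, path_idx = np.meshgrid(np.arange(g), np.arange(p), indexing="ij")
    # lexicographic sort: S desc, mean weight desc, gene asc, pathway asc
    order = np.lexsort(
        (path_idx.ravel(), gene_idx.ravel(), -mw.ravel(), -S.ravel())
    )
    values = np.zeros(g * p)
    values[order[:n_star]] = 1.0
    return ExpandedPathways(
        values.reshape(g, p),
        list(mask.gene_ids),
        list(mask.pathway_names),
        alpha,
        K,
        n_star,
        S,
    )


def supplement_genes(
    expanded: ExpandedPathways, mask: PathwayMask
) -> dict[str, list[str]]:
    """Per-pathway supplement genes (selected but not prior), by S descending."""
    if expanded.values.shape != mask.shape:
        raise ValueError("axes disagree")
    supp = expanded.supplement_mask(mask)
    out: dict[str, list[str]] = {}
    for j, name in enumerate(expanded.pathway_names):
        idx = np.flatnonzero(supp[:, j])
        order = idx[np.argsort(-expanded.probabilities[idx, j], kind="stable")]
        out[name] = [expanded.gene_ids[i] for i in order]
    return out


def ranked_gene_lists(ensemble: OccurrenceEnsemble) -> dict[str, pd.DataFrame]:
    """Per-pathway gene ranking by mean fitted W1 across runs (descending).

    The rankings are meant for pre-ranked enrichment tools (RNK export).
    """
    mw = ensemble.mean_weights()
    out = {}
    for j, name in enumerate(ensemble.pathway_names):
        order = np.argsort(-mw[:, j], kind="stable")
        out[name] = pd.DataFrame(
            {
                "gene": [ensemble.gene_ids[i] for i in order],
                "score": mw[order, j],
            }
        )
    return out


# ---------------------------------------------------------------- exports


def write_probability_tsv(S, ensemble: OccurrenceEnsemble, path) -> None:
    pd.DataFrame(
        S, index=ensemble.gene_ids, columns=ensemble.pathway_names
    ).to_csv(path, sep="\t", index_label="gene")


def write_expanded_gmt(expanded: ExpandedPathways, path) -> None:
    coll = expanded.to_collection()
    with open(path, "w") as fh:
        for name, members in zip(coll.names, coll.members):
            fh.write("\t".join([name, "expanded"] + members) + "\n")


def write_supplement_tsv(
    expanded: ExpandedPathways,
    mask: PathwayMask,
    ensemble: OccurrenceEnsemble,
    path,
) -> None:
    mw = ensemble.mean_weights()
    gene_pos = {g: i for i, g in enumerate(expanded.gene_ids)}
    rows = []
    for j, name in enumerate(expanded.pathway_names):
        for gene in supplement_genes(expanded, mask)[name]:
            i = gene_pos[gene]
            rows.append((name, gene, expanded.probabilities[i, j], mw[i, j]))
    pd.DataFrame(
        rows, columns=["pathway", "gene", "occurrence_probability", "mean_weight"]
    ).to_csv(path, sep="\t", index=False)


def write_rnk(ranked: dict[str, pd.DataFrame], directory) -> list[str]:
    """One RNK file (gene<TAB>score, no header) per pathway; returns paths."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in ranked.items():
        safe = "".join(c if c.isalnum() or c in "-_" else "_" for c in name)
        p = directory / f"{safe}.rnk"
        df.to_csv(p, sep="\t", header=False, index=False)
        paths.append(str(p))
    return paths
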