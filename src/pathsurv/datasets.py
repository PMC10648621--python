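"""Core data containers: expression + survival outcomes, and pathway masks.

The canonical in-memory layout is samples as rows and genes as columns, so a
single patient's profile is a row vector x ∈ R^{1×G}. Pathway membership is a
binary G×P incidence matrix ("mask") whose column j marks the genes of
pathway j; the all-ones mask is the fully connected degenerate case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["SurvivalDataset", "PathwayCollection", "PathwayMask"]


@dataclass
class PathwayCollection:
    """Ordered prior gene sets, as read from a GMT file.

    ``members[k]`` is the ordered, de-duplicated member list of ``names[k]``.
    """

    names: list[str]
    members: list[list[str]]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.members):
            raise ValueError("names and members must have equal length")
        if len(self.names) == 0:
            raise ValueError("pathway collection is empty")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate pathway names")
        for name, mem in zip(self.names, self.members):
            if len(mem) == 0:
                raise ValueError(f"pathway {name!r} has no members")

    @property
    def n_pathways(self) -> int:
        return len(self.names)

    def sizes(self) -> dict[str, int]:
        return {n: len(m) for n, m in zip(self.names, self.members)}


@dataclass
class PathwayMask:
    """Binary gene × pathway incidence matrix M.

    Every column must contain at least one 1 (an empty pathway cannot drive a
    hidden unit). ``all_ones`` builds the fully connected counterpart E used in
    the expansion phase of training.
    """

    values: np.ndarray
    gene_ids: list[str]
    pathway_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-dimensional (genes × pathways)")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")
        self.values = self.values.astype(np.float64)
        g, p = self.values.shape
        if g != len(self.gene_ids) or p != len(self.pathway_names):
            raise ValueError("mask shape does not match axis labels")
        empty = np.flatnonzero(self.values.sum(axis=0) == 0)
        if empty.size:
            bad = ", ".join(self.pathway_names[j] for j in empty)
            raise ValueError(f"pathway with no member genes present: {bad}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_pairs(self) -> int:
        """K — number of prior gene-pathway pairs (ones of M)."""
        return int(self.values.sum())

    def pathway_sizes(self) -> dict[str, int]:
        return dict(zip(self.pathway_names, self.values.sum(axis=0).astype(int)))

    def all_ones(self) -> "PathwayMask":
        """The fully connected mask E over the same axes."""
        return PathwayMask(
            np.ones_like(self.values), list(self.gene_ids), list(self.pathway_names)
        )

    @classmethod
    def from_collection(
        cls, pathways: PathwayCollection, gene_ids: list[str]
    ) -> "PathwayMask":
        """Build M from prior gene sets restricted to an expression gene panel.

        Pathway members absent from ``gene_ids`` are dropped (their count is
        logged); a pathway left with zero present members is an error.
        """
        index = {g: i for i, g in enumerate(gene_ids)}
        values = np.zeros((len(gene_ids), pathways.n_pathways))
        n_dropped = 0
        for j, (name, mem) in enumerate(zip(pathways.names, pathways.members)):
            present = [g for g in mem if g in index]
            n_dropped += len(mem) - len(present)
            if not present:
                raise ValueError(
                    f"pathway {name!r} has no members in the expression matrix"
                )
            for g in present:
                values[index[g], j] = 1.0
        if n_dropped:
            logger.info(
                "build_mask: dropped %d pathway members absent from the gene panel",
                n_dropped,
            )
        return cls(values, list(gene_ids), list(pathways.names))


@dataclass
class SurvivalDataset:
    """Gene expression plus right-censored outcomes over a shared sample index.

    Parameters
    ----------
    expression
        Samples × genes DataFrame; the row index holds sample ids.
    time
        Positive follow-up time per sample (event or censoring time).
    event
        1 if the event was observed at ``time``, 0 if censored.
    """

    expression: pd.DataFrame
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=float)
        n = len(self.expression)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length must match the number of samples")
        if not np.isfinite(self.expression.to_numpy()).all():
            raise ValueError("expression contains non-finite values")
        if (self.time <= 0).any():
            raise ValueError("all survival times must be positive")
        if not np.isin(self.event, (0.0, 1.0)).all():
            raise ValueError("event indicator must be 0 or 1")
        if self.expression.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.expression.columns.has_duplicates:
            raise ValueError("duplicate gene ids")

    @property
    def n_samples(self) -> int:
        return len(self.expression)

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def X(self) -> np.ndarray:
        return self.expression.to_numpy(dtype=float)

    def subset(self, indices: np.ndarray) -> "SurvivalDataset":
        """Row subset (positional); used by CV folds and resampling."""
        indices = np.asarray(indices)
        return SurvivalDataset(
            self.expression.iloc[indices], self.time[indices], self.event[indices]
        )

    @classmethod
    def from_frames(
        cls,
        expression: pd.DataFrame,
        survival: pd.DataFrame,
    ) -> "SurvivalDataset":
        """Inner-join expression rows with a (sample, time, event) table."""
        if not {"sample", "time", "event"}.issubset(survival.columns):
            raise ValueError("survival table needs columns: sample, time, event")
        surv = survival.set_index("sample")
        common = expression.index.intersection(surv.index)
        if len(common) == 0:
            raise ValueError("no samples shared between expression and survival")
        dropped = len(expression) - len(common)
        if dropped:
            logger.info("from_frames: dropped %d samples without outcomes", dropped)
        expr = expression.loc[common]
        surv = surv.loc[common]
        return cls(expr, surv["time"].to_numpy(), surv["event"].to_numpy())
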