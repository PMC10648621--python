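"""Readers for the tab-separated input formats and the preprocessing chain.

Expression and survival tables are plain TSV; prior pathways use the standard
GMT dialect (name, description, members..., tab-separated). Preprocessing
follows the usual chain for count-scale expression ahead of a neural survival
model: log2(x+1), a standard-deviation filter keeping high-variance genes, and
per-gene z-scoring.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import PathwayCollection

logger = logging.getLogger(__name__)

__all__ = ["read_expression", "read_survival", "read_gmt", "preprocess"]


def read_expression(
    path: str | Path, orientation: str = "samples_by_genes"
) -> pd.DataFrame:
    """Read a TSV expression matrix into the samples × genes layout.

    Parameters
    ----------
    path
        TSV file with labelled rows and columns (first row / first column).
    orientation
        ``"samples_by_genes"`` if rows are samples (the canonical layout), or
        ``"genes_by_samples"`` for the transposed file; the returned frame is
        always samples × genes.
    """
    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup = {h for h in header if header.count(h) > 1}
    if dup:
        raise ValueError(f"duplicate column label(s): {sorted(dup)}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "genes_by_samples":
        df = df.T
    df.index.name = None
    df.columns.name = None
    for axis, what in ((df.index, "sample"), (df.columns, "gene")):
        if axis.has_duplicates:
            dup = axis[axis.duplicated()].unique().tolist()
            raise ValueError(f"duplicate {what} id(s): {dup}")
    bad = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValueError(f"non-numeric expression value at row {row!r}, column {col!r}")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError("expression contains non-finite values")
    return df.astype(float)


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read a survival TSV with header columns ``sample``, ``time``, ``event``."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"survival file missing column(s): {sorted(missing)}")
    return df


def read_gmt(path: str | Path) -> PathwayCollection:
    """Parse a GMT gene-set file (name, description, members...).

    Duplicate members within a set are dropped with a warning; the description
    field is discarded. Lines with fewer than three fields are an error.
    """
    names: list[str] = []
    members: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected ≥3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ValueError(f"{path}: line {lineno}: pathway {name!r} is empty")
            seen: dict[str, None] = {}
            for g in genes:
                if g in seen:
                    logger.warning(
                        "read_gmt: duplicated member %r in pathway %r", g, name
                    )
                seen[g] = None
            names.append(name)
            members.append(list(seen))
    return PathwayCollection(names, members)


def preprocess(
    expression: pd.DataFrame,
    log_transform: bool = True,
    sd_threshold: float = 1.0,
) -> pd.DataFrame:
    """log2(x+1) → variance filter → per-gene z-scoring.

    Genes are kept when their across-sample standard deviation (sample sd,
    ddof=1) is strictly greater than ``sd_threshold``, then each retained gene
    is standardized to mean 0 and sd 1.
    """
    if sd_threshold < 0:
        raise ValueError("sd_threshold must be non-negative")
    df = expression.astype(float)
    if log_transform:
        if (df.to_numpy() < 0).any():
            raise ValueError("log transform requires non-negative values")
        df = np.log2(df + 1.0)
    sds = df.std(axis=0, ddof=1)
    keep = sds > sd_threshold
    if not keep.any():
        raise ValueError(
            f"no gene passes the sd > {sd_threshold} filter; nothing to model"
        )
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("preprocess: dropped %d low-variance genes", n_drop)
    df = df.loc[:, keep]
    return (df - df.mean(axis=0)) / df.std(axis=0, ddof=1)
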