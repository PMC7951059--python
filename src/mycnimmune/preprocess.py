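"""Expression preprocessing and driver-gene correlation ranking.

The preprocessing chain mirrors standard microarray practice: quantile
normalization across arrays, averaging of replicate probes sharing a gene
label, then per-gene z-scaling.  Ranking against a driver gene (MYCN or
MYC) is plain Pearson correlation, sorted descending with a stable
gene-label tie-break so ranked lists are deterministic.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("mycnimmune")

__all__ = [
    "quantile_normalize",
    "average_duplicate_genes",
    "scale_genes",
    "preprocess",
    "correlate_with_gene",
]


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Force every column (sample) onto the mean empirical distribution.

    Missing values are not supported here; genes with any missing value
    are dropped (with a logged count) before normalization.
    """
    if df.isna().any().any():
        n = int(df.isna().any(axis=1).sum())
        logger.warning("dropping %d genes with missing values", n)
        df = df.dropna(axis=0)
    x = df.to_numpy(dtype=float)
    ref = np.sort(x, axis=0).mean(axis=1)
    n = x.shape[0]
    out = np.empty_like(x)
    # mean rank handles ties the way limma's normalizeQuantiles does
    ranks = pd.DataFrame(x).rank(axis=0, method="average").to_numpy()
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(x.shape[1]):
        out[:, j] = np.interp(ranks[:, j], grid, ref)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def average_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Replace replicate probe rows sharing a gene label by their average."""
    if not df.index.duplicated().any():
        return df
    order = df.index[~df.index.duplicated()].tolist()
    out = df.groupby(level=0, sort=False).mean()
    return out.loc[order]


def scale_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene row; zero-variance rows become 0 with a warning."""
    x = df.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flat = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    if flat.any():
        logger.warning("%d zero-variance genes scaled to 0", int(flat.sum()))
    sd[flat] = 1.0
    z = (x - mu) / sd
    z[flat] = 0.0
    return pd.DataFrame(z, index=df.index, columns=df.columns)


def preprocess(raw: pd.DataFrame, scale: bool = True) -> pd.DataFrame:
    """Quantile-normalize, average duplicate probes and (optionally) z-scale."""
    df = quantile_normalize(raw)
    df = average_duplicate_genes(df)
    if scale:
        df = scale_genes(df)
    return df


def correlate_with_gene(expr: pd.DataFrame, driver: str) -> pd.Series:
    """Pearson correlation of every other gene with the driver gene.

    Returns a descending-sorted Series (the preranked list for enrichment);
    ties broken by gene label.  Zero-variance genes are excluded with a
    warning; the driver itself is excluded.
    """
    if driver not in expr.index:
        raise KeyError(f"driver gene {driver!r} not in expression matrix")
    if expr.shape[1] < 3:
        raise ValueError("at least 3 samples are required for correlation")
    x = expr.to_numpy(dtype=float)
    d = expr.loc[driver].to_numpy(dtype=float)
    if d.std() == 0:
        raise ValueError(f"driver gene {driver!r} has zero variance")
    xc = x - x.mean(axis=1, keepdims=True)
    dc = d - d.mean()
    sd = np.sqrt((xc**2).sum(axis=1))
    flat = sd == 0
    if flat.any():
        logger.warning("%d zero-variance genes excluded from ranking", int(flat.sum()))
    sd[flat] = np.nan
    r = (xc @ dc) / (sd * np.sqrt((dc**2).sum()))
    out = pd.Series(r, index=expr.index).drop(index=driver).dropna()
    frame = out.rename("r").reset_index().rename(columns={"index": "gene"})
    frame = frame.sort_values(["r", "gene"], ascending=[False, True], kind="mergesort")
    return pd.Series(frame["r"].to_numpy(), index=frame["gene"].to_numpy(), name="r")
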