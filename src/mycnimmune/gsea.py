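"""Preranked gene-set enrichment with a gene-label permutation null.

The enrichment score is the signed maximum deviation of the weighted
Kolmogorov-Smirnov running statistic (hit increments proportional to
|ranking statistic|^exponent, default exponent 1).  Significance comes
from random same-size gene sets: NES rescales the observed ES by the mean
same-sign null |ES|, the nominal p is one-sided against the same-sign
null, and the FDR q follows the positive/negative pooled-null procedure.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import GeneSetCollection

logger = logging.getLogger("mycnimmune")

__all__ = ["enrichment_score", "preranked_gsea"]


def enrichment_score(
    ranked: pd.Series, gene_set, exponent: float = 1.0
) -> tuple[float, np.ndarray]:
    """ES of one gene set against a descending ranked list.

    Returns ``(es, running)`` with the full running sum (length of the
    ranked list) for leading-edge extraction.
    """
    genes = ranked.index
    hits = genes.isin(set(gene_set))
    n_hit = int(hits.sum())
    if n_hit == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if n_hit == len(genes):
        raise ValueError("gene set covers the whole ranked list")
    w = np.abs(ranked.to_numpy(dtype=float)) ** exponent
    wh = np.where(hits, w, 0.0)
    total = wh.sum()
    if total == 0:
        wh = hits.astype(float)
        total = wh.sum()
    p_hit = np.cumsum(wh) / total
    p_miss = np.cumsum(~hits) / (len(genes) - n_hit)
    running = p_hit - p_miss
    # ties in |running| (e.g. symmetric +x/-x peaks) break to the earliest
    # position, robust to float accumulation order
    m = np.abs(running)
    peak = int(np.flatnonzero(m >= m.max() - 1e-12)[0])
    es = float(running[peak])
    return es, running


def _es_from_positions(pos: np.ndarray, w: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES for many same-size hit-position vectors.

    ``pos``: (n_rows, set_size) hit positions (0-based) into a ranked list
    of length ``n`` with hit weights ``w`` (already |stat|^exponent).  The
    running sum is piecewise linear between hits, so its extremum over all
    positions is attained either at a hit or immediately before one.
    """
    pos = np.sort(pos, axis=1)
    s = pos.shape[1]
    hw = np.take(w, pos)
    tot = hw.sum(axis=1, keepdims=True)
    flat = tot[:, 0] == 0
    if flat.any():
        hw[flat] = 1.0
        tot[flat] = s
    cum = np.cumsum(hw, axis=1) / tot
    miss = (pos - np.arange(s)) / (n - s)          # misses before each hit
    at_hit = cum - miss
    before = np.concatenate([np.zeros((pos.shape[0], 1)), cum[:, :-1]], axis=1) - miss
    cand = np.concatenate([at_hit, before], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(len(cand)), idx]


def preranked_gsea(
    ranked: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    exponent: float = 1.0,
    min_size: int = 15,
    max_size: int = 500,
) -> pd.DataFrame:
    """Preranked GSEA over a gene-set collection.

    Sets are restricted to members present in the ranked list; sets
    outside [min_size, max_size] are skipped with a log message.  Returns
    a DataFrame (one row per tested set) with columns ``size``, ``ES``,
    ``NES``, ``p``, ``q``, ``leading_edge``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    genes = ranked.index
    n = len(genes)
    w = np.abs(ranked.to_numpy(dtype=float)) ** exponent

    rows = []
    null_nes_pool: list[np.ndarray] = []
    obs_nes = []
    for name, members in collection.items():
        present = [g for g in dict.fromkeys(members) if g in genes]
        size = len(present)
        if size < min_size or size > max_size or size == n:
            logger.info("gene set %s skipped (size %d)", name, size)
            continue
        es, running = enrichment_score(ranked, present, exponent)
        # null: random same-size position sets
        u = rng.random((n_perm, n))
        null_pos = np.argpartition(u, size - 1, axis=1)[:, :size]
        null_es = _es_from_positions(null_pos, w, n)

        pos_null = null_es[null_es >= 0]
        neg_null = null_es[null_es < 0]
        same = pos_null if es >= 0 else neg_null
        mean_same = np.abs(same).mean() if len(same) else np.nan
        nes = es / mean_same if mean_same and np.isfinite(mean_same) else np.nan
        p = float(np.mean(np.abs(same) >= abs(es))) if len(same) else 1.0

        # per-set null NES for the pooled FDR
        null_nes = np.empty_like(null_es)
        mp = np.abs(pos_null).mean() if len(pos_null) else np.nan
        mn = np.abs(neg_null).mean() if len(neg_null) else np.nan
        null_nes[null_es >= 0] = null_es[null_es >= 0] / mp if mp else np.nan
        null_nes[null_es < 0] = null_es[null_es < 0] / mn if mn else np.nan
        null_nes_pool.append(null_nes[np.isfinite(null_nes)])

        hit_mask = genes.isin(set(present))
        mabs = np.abs(running)
        peak = int(np.flatnonzero(mabs >= mabs.max() - 1e-12)[0])
        if es >= 0:
            lead = [g for i, g in enumerate(genes) if hit_mask[i] and i <= peak]
        else:
            lead = [g for i, g in enumerate(genes) if hit_mask[i] and i >= peak]
        rows.append(
            {"set": name, "size": size, "ES": es, "NES": nes, "p": p,
             "leading_edge": ",".join(lead)}
        )
        obs_nes.append(nes)

    if not rows:
        return pd.DataFrame(
            columns=["set", "size", "ES", "NES", "p", "q", "leading_edge"]
        ).set_index("set")

    pooled = np.concatenate(null_nes_pool)
    obs = np.asarray(obs_nes, dtype=float)
    q = np.empty(len(obs))
    n_pos_null = max(int((pooled >= 0).sum()), 1)
    n_neg_null = max(int((pooled < 0).sum()), 1)
    n_pos_obs = max(int((obs >= 0).sum()), 1)
    n_neg_obs = max(int((obs < 0).sum()), 1)
    for i, v in enumerate(obs):
        if not np.isfinite(v):
            q[i] = np.nan
        elif v >= 0:
            num = (pooled >= v).sum() / n_pos_null
            den = max((obs >= v).sum() / n_pos_obs, 1e-12)
            q[i] = min(num / den, 1.0)
        else:
            num = (pooled <= v).sum() / n_neg_null
            den = max((obs <= v).sum() / n_neg_obs, 1e-12)
            q[i] = min(num / den, 1.0)

    out = pd.DataFrame(rows).set_index("set")
    out["q"] = q
    return out[["size", "ES", "NES", "p", "q", "leading_edge"]]
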