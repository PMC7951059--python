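"""Transcriptional regulators of the immune co-expression modules.

Regulators are inferred by module-wise hypergeometric over-representation
of each TF's target set against a user-supplied TF -> target prior (the
prior is an explicit input so richer inference can be swapped in).
Regulon activity is the mean z-scored expression of the targets per
sample; regulons and patients are then clustered hierarchically on
Euclidean distance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("mycnimmune")

__all__ = [
    "infer_module_regulators",
    "regulon_activity",
    "cluster_regulons",
    "consensus_regulons",
    "cluster_patients_by_regulon",
]


def infer_module_regulators(
    assignment: pd.Series,
    prior: dict[str, set[str]],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Select TFs whose targets are over-represented in >= 1 module.

    The gene universe is every gene in the assignment (assigned or not).
    Returns all tested (TF, module) pairs with overlap, hypergeometric p
    and BH q, plus a ``selected`` flag on the TF level.
    """
    if not prior:
        raise ValueError("empty regulon prior")
    universe = set(assignment.index)
    M = len(universe)
    modules = sorted(m for m in assignment.unique() if m != 0)
    rows = []
    for tf, targets in prior.items():
        t = set(targets) & universe
        if not t:
            logger.info("TF %s has no targets in the universe; skipped", tf)
            continue
        for m in modules:
            mod = set(assignment.index[assignment == m])
            k = len(mod & t)
            p = float(hypergeom.sf(k - 1, M, len(t), len(mod)))
            rows.append({"tf": tf, "module": m, "overlap": k,
                         "n_targets": len(t), "module_size": len(mod), "p": p})
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no TF has targets in the gene universe")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    sig_tfs = set(out.loc[out["q"] < q_threshold, "tf"])
    out["selected"] = out["tf"].isin(sig_tfs)
    return out


def regulon_activity(
    expr: pd.DataFrame, regulons: dict[str, set[str]], min_targets: int = 3
) -> pd.DataFrame:
    """Per-sample regulon activity: mean target z-score, row-z-scored.

    Regulons with fewer than ``min_targets`` genes present in the
    expression matrix are dropped with a log message.
    """
    x = expr.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = pd.DataFrame((x - mu) / sd, index=expr.index, columns=expr.columns)
    rows = {}
    for tf, targets in regulons.items():
        present = [g for g in targets if g in z.index]
        if len(present) < min_targets:
            logger.warning("regulon %s: only %d targets present; dropped",
                           tf, len(present))
            continue
        act = z.loc[present].mean(axis=0).to_numpy()
        s = act.std(ddof=1)
        rows[tf] = (act - act.mean()) / (s if s > 0 else 1.0)
    if not rows:
        raise ValueError("no regulon has enough targets in the expression matrix")
    return pd.DataFrame(rows, index=expr.columns).T


def cluster_regulons(activity: pd.DataFrame, k: int = 3) -> pd.Series:
    """Cut the average-linkage Euclidean dendrogram of regulons at k clusters."""
    if activity.shape[0] < k:
        raise ValueError(f"need >= {k} regulons, have {activity.shape[0]}")
    link = hierarchy.linkage(pdist(activity.to_numpy(dtype=float)), method="average")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return pd.Series(labels, index=activity.index, name="cluster")


def consensus_regulons(regulons_a: pd.DataFrame, regulons_b: pd.DataFrame) -> pd.DataFrame:
    """TFs selected in both cohorts, with each cohort's best (module, q) kept."""

    def best(df: pd.DataFrame) -> pd.DataFrame:
        sel = df[df["selected"]]
        return sel.sort_values("q").groupby("tf").first()

    a, b = best(regulons_a), best(regulons_b)
    common = sorted(set(a.index) & set(b.index))
    return pd.DataFrame(
        {
            "module_a": a.loc[common, "module"], "q_a": a.loc[common, "q"],
            "module_b": b.loc[common, "module"], "q_b": b.loc[common, "q"],
        }
    )


def cluster_patients_by_regulon(activity: pd.DataFrame, k: int = 2) -> tuple[pd.Series, list]:
    """Cluster samples on their regulon-activity columns.

    Returns per-sample cluster labels (k-cut) and the dendrogram leaf
    order for heatmap export.
    """
    cols = activity.columns
    x = activity.to_numpy(dtype=float).T
    link = hierarchy.linkage(pdist(x), method="average")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    order = [cols[i] for i in hierarchy.leaves_list(link)]
    return pd.Series(labels, index=cols, name="cluster"), order
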