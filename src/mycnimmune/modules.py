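"""Signed weighted co-expression modules on the immune-gene subset.

Signed adjacency a_ij = ((1 + cor)/2)^beta at beta = 8, topological
overlap dissimilarity, average-linkage clustering with a height cut and a
minimum module size of 20; module eigengenes (first principal component
of the standardized module expression), eigengene similarity, z-scored
module-trait profiles, immune-population composition, and hypergeometric
set enrichment per module.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

logger = logging.getLogger("mycnimmune")

__all__ = [
    "signed_adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigengenes",
    "module_similarity",
    "module_trait_profile",
    "module_population_composition",
    "module_enrichment",
    "CoexpressionNetwork",
]


def signed_adjacency(expr: pd.DataFrame, beta: float = 8.0) -> pd.DataFrame:
    """Signed adjacency ((1 + Pearson cor)/2)^beta; diagonal 1."""
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = list(expr.index[sd == 0])
        raise ValueError(f"zero-variance gene(s): {bad[:10]}")
    cor = np.corrcoef(x)
    a = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """TOM dissimilarity 1 - (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)."""
    a = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a                      # l_ij over u != i, j (diagonal is 0)
    kmin = np.minimum.outer(k, k)
    tom = (shared + a) / (kmin + 1.0 - a)
    dis = 1.0 - tom
    np.fill_diagonal(dis, 0.0)
    return pd.DataFrame(dis, index=adjacency.index, columns=adjacency.columns)


def detect_modules(
    dissimilarity: pd.DataFrame, min_size: int = 20, cut_height: float = 0.9
) -> pd.Series:
    """Assign genes to modules by cutting the average-linkage dendrogram.

    Branches below ``cut_height`` form candidate clusters; clusters
    smaller than ``min_size`` are left unassigned (module 0).  Modules are
    numbered 1.. by decreasing size.  Returns gene -> module id.
    """
    genes = dissimilarity.index
    if len(genes) < 2 * min_size:
        logger.warning("fewer than 2 x min_size genes; module detection degenerate")
    d = squareform(dissimilarity.to_numpy(dtype=float), checks=False)
    link = hierarchy.linkage(d, method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_size]
    # stable numbering: by decreasing size, ties by first-gene order
    order = sorted(
        keep.index, key=lambda c: (-keep[c], int(np.argmax(raw == c)))
    )
    relabel = {c: i + 1 for i, c in enumerate(order)}
    labels = np.array([relabel.get(c, 0) for c in raw])
    return pd.Series(labels, index=genes, name="module")


def module_eigengenes(expr: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    """First-principal-component sample profile of every module.

    Each eigengene has unit variance and is sign-oriented so that its
    correlation with the module's mean standardized expression is >= 0.
    Single-gene modules degenerate to that gene's z-scores.
    """
    modules = sorted(m for m in assignment.unique() if m != 0)
    if not modules:
        raise ValueError("no modules to summarize")
    rows = {}
    for m in modules:
        genes = assignment.index[assignment == m]
        x = expr.loc[genes].to_numpy(dtype=float)
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (x - mu) / sd
        if len(genes) == 1:
            eig = z[0]
        else:
            _, _, vt = np.linalg.svd(z, full_matrices=False)
            eig = vt[0]
        s = eig.std(ddof=1)
        if s > 0:
            eig = eig / s
        mean_profile = z.mean(axis=0)
        if np.corrcoef(eig, mean_profile)[0, 1] < 0:
            eig = -eig
        rows[f"ME{m}"] = eig
    return pd.DataFrame(rows, index=expr.columns).T


def module_similarity(
    eigengenes: pd.DataFrame, display_threshold: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation between module eigengenes plus a thresholded edge list.

    Edges with |r| above the display threshold are exported with a sign
    label for chord/graph rendering.
    """
    if eigengenes.shape[0] < 2:
        raise ValueError("at least 2 modules are required")
    r = np.corrcoef(eigengenes.to_numpy(dtype=float))
    sim = pd.DataFrame(r, index=eigengenes.index, columns=eigengenes.index)
    rows = []
    mods = list(eigengenes.index)
    for i, a in enumerate(mods):
        for b in mods[i + 1:]:
            v = sim.loc[a, b]
            if abs(v) >= display_threshold:
                rows.append({"module_a": a, "module_b": b, "r": v,
                             "sign": "positive" if v >= 0 else "negative"})
    edges = pd.DataFrame(rows, columns=["module_a", "module_b", "r", "sign"])
    return sim, edges


def module_trait_profile(eigengenes: pd.DataFrame, group_labels) -> pd.DataFrame:
    """Group means of each eigengene, z-scored across groups (per module)."""
    labels = pd.Series(np.asarray(group_labels), index=eigengenes.columns)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("at least 2 groups are required")
    means = pd.DataFrame(
        {g: eigengenes.loc[:, labels[labels == g].index].mean(axis=1) for g in groups}
    )
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=1).replace(0, 1.0)
    return means.sub(mu, axis=0).div(sd, axis=0)


def module_population_composition(
    assignment: pd.Series, population_sets: dict[str, set[str]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts of each population's proteins per module, with per-row z-scores."""
    modules = sorted(m for m in assignment.unique() if m != 0)
    counts = pd.DataFrame(0, index=sorted(population_sets), columns=modules)
    for pop, members in population_sets.items():
        for m in modules:
            genes = set(assignment.index[assignment == m])
            counts.loc[pop, m] = len(genes & members)
    z = counts.astype(float).copy()
    for pop in z.index:
        row = counts.loc[pop].to_numpy(dtype=float)
        sd = row.std(ddof=1) if len(row) > 1 else 0.0
        if sd == 0:
            logger.warning("population %s: flat module counts; z set to 0", pop)
            z.loc[pop] = 0.0
        else:
            z.loc[pop] = (row - row.mean()) / sd
    return counts, z


def module_enrichment(
    assignment: pd.Series,
    collection: GeneSetCollection,
    background=None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in each module.

    The background defaults to every gene that entered clustering
    (assigned or not).  p = P(X >= k) for overlap k; BH-adjusted across
    all (module, set) pairs.
    """
    if background is None:
        background = list(assignment.index)
    bg = set(background)
    M = len(bg)
    rows = []
    for name, members in collection.items():
        in_bg = set(members) & bg
        if not in_bg:
            continue
        for m in sorted(x for x in assignment.unique() if x != 0):
            mod_genes = set(assignment.index[assignment == m]) & bg
            k = len(mod_genes & in_bg)
            p = float(hypergeom.sf(k - 1, M, len(in_bg), len(mod_genes)))
            rows.append({"module": m, "set": name, "overlap": k,
                         "set_size": len(in_bg), "module_size": len(mod_genes),
                         "p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


class CoexpressionNetwork(BaseEstimator):
    """Estimator wrapper for the module-detection chain.

    ``fit`` runs adjacency -> TOM -> clustering and exposes ``labels_``
    (gene -> module) and ``eigengenes_`` (modules x samples).
    """

    def __init__(self, beta=8.0, min_size=20, cut_height=0.9):
        self.beta = beta
        self.min_size = min_size
        self.cut_height = cut_height

    def fit(self, expr: pd.DataFrame, y=None):
        adj = signed_adjacency(expr, beta=self.beta)
        dis = topological_overlap(adj)
        self.labels_ = detect_modules(dis, min_size=self.min_size,
                                      cut_height=self.cut_height)
        if (self.labels_ != 0).any():
            self.eigengenes_ = module_eigengenes(expr, self.labels_)
        else:
            self.eigengenes_ = pd.DataFrame(columns=expr.columns)
        return self
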