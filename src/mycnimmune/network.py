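"""Surface-protein tumor-immune interaction networks.

The filter cascade: proteins count as cell-surface only with a reliable
(approved/supported) annotation to plasma membrane, cell junctions or
focal adhesion sites; a protein counts as expressed in an immune
population only with a normalized score strictly above 1.5 (and only if
surface); interactions are kept strictly above a combined score of 400.
Tumor-side genes come from MNA vs non-MNA differential expression at
|logFC| >= 0.5, or from knockdown-derived regulated lists at |logFC| >= 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io import AnnotationTable
from .simulate import RELIABLE_STATUSES, SURFACE_TERMS

logger = logging.getLogger("mycnimmune")

__all__ = [
    "ImmuneNetwork",
    "surface_proteins",
    "population_surface_sets",
    "group_de_genes",
    "knockdown_gene_lists",
    "build_bipartite_network",
    "network_summary",
]


@dataclass
class ImmuneNetwork:
    """Bipartite tumor-gene <-> immune-population surface-protein edges."""

    edges: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["tumor_gene", "immune_protein", "population", "score"]
        )
    )

    def __len__(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[str, str, str]]:
        return {
            (r.tumor_gene, r.immune_protein, r.population)
            for r in self.edges.itertuples(index=False)
        }


def surface_proteins(annotation: AnnotationTable) -> set[str]:
    """Proteins with >=1 reliable annotation to a cell-surface location term."""
    loc = annotation.locations
    if loc.empty:
        raise ValueError("empty annotation table")
    ok = loc["location"].isin(SURFACE_TERMS) & loc["status"].isin(RELIABLE_STATUSES)
    return set(loc.loc[ok, "protein"])


def population_surface_sets(
    annotation: AnnotationTable,
    score_threshold: float = 1.5,
    populations=None,
) -> dict[str, set[str]]:
    """Per immune population, the surface proteins expressed in it.

    Expression means a normalized score strictly greater than the
    threshold; non-surface proteins are excluded regardless of score.
    """
    surface = surface_proteins(annotation)
    if populations is None:
        populations = annotation.populations
    unknown = [p for p in populations if p not in annotation.scores.columns]
    if unknown:
        raise KeyError(f"unknown population label(s): {unknown}")
    out = {}
    for pop in populations:
        s = annotation.scores[pop]
        out[pop] = {p for p in s.index[s > score_threshold] if p in surface}
    return out


def group_de_genes(
    de: pd.DataFrame, lfc_threshold: float = 0.5
) -> tuple[set[str], set[str]]:
    """Assign DE genes to the MNA (logFC >= +thr) or non-MNA (<= -thr) side."""
    mna = set(de.index[de["logFC"] >= lfc_threshold])
    nonmna = set(de.index[de["logFC"] <= -lfc_threshold])
    return mna, nonmna


def knockdown_gene_lists(
    knock_de: pd.DataFrame, surface: set[str], lfc_threshold: float = 1.0
) -> tuple[set[str], set[str]]:
    """Surface genes positively / negatively regulated by the knocked-down TF.

    ``knock_de`` has signed logFC of knockdown vs control: genes that go
    down on knockdown (logFC <= -threshold) are positively regulated by
    the TF; genes that go up are negatively regulated.  Both lists are
    intersected with the surface set.
    """
    pos = set(knock_de.index[knock_de["logFC"] <= -lfc_threshold]) & surface
    neg = set(knock_de.index[knock_de["logFC"] >= lfc_threshold]) & surface
    return pos, neg


def build_bipartite_network(
    tumor_set: set[str],
    population_sets: dict[str, set[str]],
    edges: pd.DataFrame,
    min_score: int = 400,
) -> ImmuneNetwork:
    """Keep interactions strictly above ``min_score`` that bridge a tumor
    gene and a population's expressed surface protein.

    Edges are undirected; each (unordered protein pair, population) is
    counted once.  A pair qualifying in both orientations contributes one
    edge per orientation per population.
    """
    rows = []
    seen = set()
    for r in edges.itertuples(index=False):
        a, b, s = r.protein1, r.protein2, r.combined_score
        if a == b or s <= min_score:
            continue
        for pop, members in population_sets.items():
            if a in tumor_set and b in members:
                key = (a, b, pop)
                if key not in seen:
                    seen.add(key)
                    rows.append({"tumor_gene": a, "immune_protein": b,
                                 "population": pop, "score": s})
            if b in tumor_set and a in members:
                key = (b, a, pop)
                if key not in seen:
                    seen.add(key)
                    rows.append({"tumor_gene": b, "immune_protein": a,
                                 "population": pop, "score": s})
    if not rows:
        logger.warning("no interactions survive the filter cascade")
        return ImmuneNetwork()
    return ImmuneNetwork(edges=pd.DataFrame(rows))


def network_summary(net: ImmuneNetwork) -> dict[str, pd.DataFrame | int]:
    """Connection counts for circular-plot export.

    Returns per-population edge counts, per (tumor gene, population)
    counts, shared-pair counts between populations (distinct tumor-immune
    pairs annotated to both), the total edge count and the number of
    populations touched.
    """
    e = net.edges
    if e.empty:
        return {
            "population_counts": pd.Series(dtype=int),
            "tumor_population_counts": pd.DataFrame(
                columns=["tumor_gene", "population", "n_edges"]
            ),
            "population_pair_counts": pd.DataFrame(
                columns=["population_a", "population_b", "n_shared_pairs"]
            ),
            "total_edges": 0,
            "n_populations": 0,
        }
    pop_counts = e.groupby("population").size().sort_index()
    tp = (
        e.groupby(["tumor_gene", "population"]).size().rename("n_edges").reset_index()
    )
    pairs_by_pop = {
        pop: {(r.tumor_gene, r.immune_protein) for r in grp.itertuples(index=False)}
        for pop, grp in e.groupby("population")
    }
    pops = sorted(pairs_by_pop)
    pair_rows = [
        {"population_a": p1, "population_b": p2,
         "n_shared_pairs": len(pairs_by_pop[p1] & pairs_by_pop[p2])}
        for i, p1 in enumerate(pops)
        for p2 in pops[i + 1:]
    ]
    return {
        "population_counts": pop_counts,
        "tumor_population_counts": tp,
        "population_pair_counts": pd.DataFrame(
            pair_rows, columns=["population_a", "population_b", "n_shared_pairs"]
        ),
        "total_edges": int(len(e)),
        "n_populations": int(e["population"].nunique()),
    }
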