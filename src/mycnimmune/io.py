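"""Readers and writers for the pipeline's text formats.

All tabular formats are UTF-8 tab-separated values with a header line and
"." decimals; gene sets use the GMT dialect (name, description, members).
Gene identifiers are matched exactly (case-sensitive) after stripping
surrounding whitespace; no alias resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("mycnimmune")

__all__ = [
    "GeneSetCollection",
    "AnnotationTable",
    "read_expression_table",
    "write_expression_table",
    "read_gmt",
    "write_gmt",
    "read_clinical_table",
    "write_clinical_table",
    "read_annotation_table",
    "write_annotation_table",
    "read_edge_table",
    "write_edge_table",
    "read_gene_list",
    "write_gene_list",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, ordered members."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()

    def add(self, name: str, members, description: str = "") -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene-set name: {name!r}")
        deduped = list(dict.fromkeys(members))
        if len(deduped) < len(list(members)):
            logger.warning("gene set %s: duplicate members removed", name)
        if not deduped:
            raise ValueError(f"gene set {name!r} has no members")
        self.sets[name] = deduped
        self.descriptions[name] = description


@dataclass
class AnnotationTable:
    """Protein subcellular locations plus per-immune-population scores.

    ``locations``: long table (protein, location, status) where status is
    the annotation reliability (approved / supported / other).
    ``scores``: proteins x populations normalized expression scores.
    """

    locations: pd.DataFrame
    scores: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"protein", "location", "status"}
        missing = need - set(self.locations.columns)
        if missing:
            raise ValueError(f"annotation locations missing columns: {sorted(missing)}")
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValueError("annotation scores must be finite")

    @property
    def populations(self) -> list[str]:
        return list(self.scores.columns)


def read_expression_table(path) -> pd.DataFrame:
    """Load a genes x samples expression TSV (first column = gene labels).

    Duplicate gene labels are retained (the preprocessing stage averages
    them); "NA"/empty cells parse as missing and are counted in the log.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.empty:
        raise ValueError(f"empty expression table: {path}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric expression value in column {col!r}, row {row!r}"
            )
    df.index = df.index.astype(str).str.strip()
    df.columns = [str(c).strip() for c in df.columns]
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.warning("expression table %s: %d missing values", path, n_missing)
    dup = df.index[df.index.duplicated(keep=False)].unique()
    if len(dup):
        logger.warning("expression table %s: %d duplicated gene labels", path, len(dup))
    return df


def write_expression_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, tab-separated name/description/members."""
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = fields
            members = [m.strip() for m in members if m.strip()]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            coll.add(name.strip(), members, desc)
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in coll.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_clinical_table(path) -> pd.DataFrame:
    """Load per-sample clinical annotations.

    Required columns: ``sample``, ``mna_status``, ``surv_time``,
    ``surv_event``; extra columns (stage, histology, ...) are preserved.
    Events are coerced to {0, 1}; non-positive survival times are an error.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["sample", "mna_status", "surv_time", "surv_event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing required column(s): {missing}")
    df = df.set_index("sample")
    df.index = df.index.astype(str).str.strip()
    df["mna_status"] = df["mna_status"].astype(int)
    df["surv_event"] = (df["surv_event"].astype(float) != 0).astype(int)
    df["surv_time"] = df["surv_time"].astype(float)
    if (df["surv_time"] <= 0).any():
        bad = df.index[df["surv_time"] <= 0][0]
        raise ValueError(f"non-positive survival time for sample {bad!r}")
    return df


def write_clinical_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample")


def read_annotation_table(path) -> AnnotationTable:
    """Load a protein annotation TSV.

    Columns: ``protein``, ``locations`` (semicolon-separated
    ``term:status`` pairs; may be empty) and one score column per immune
    population.  Rows with a status outside approved/supported are kept
    but treated as non-reliable by the surface filter.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein": str})
    if "protein" not in df.columns or "locations" not in df.columns:
        raise ValueError("annotation table requires 'protein' and 'locations' columns")
    loc_rows = []
    for protein, locs in zip(df["protein"], df["locations"].fillna("")):
        for item in str(locs).split(";"):
            item = item.strip()
            if not item:
                continue
            term, _, status = item.rpartition(":")
            loc_rows.append((protein.strip(), term.strip(), status.strip()))
    locations = pd.DataFrame(loc_rows, columns=["protein", "location", "status"])
    score_cols = [c for c in df.columns if c not in ("protein", "locations")]
    scores = df.set_index("protein")[score_cols].astype(float)
    scores.index = scores.index.astype(str).str.strip()
    return AnnotationTable(locations=locations, scores=scores)


def write_annotation_table(ann: AnnotationTable, path) -> None:
    locs = {
        p: ";".join(f"{t}:{s}" for _, t, s in grp.itertuples(index=False))
        for p, grp in ann.locations.groupby("protein", sort=False)
    }
    out = ann.scores.copy()
    out.insert(0, "locations", [locs.get(p, "") for p in out.index])
    out.to_csv(path, sep="\t", index_label="protein")


def read_edge_table(path) -> pd.DataFrame:
    """Load a STRING-style interaction table (protein1, protein2, combined_score).

    Self-loops are dropped and bidirectional duplicates collapsed to one
    undirected edge (keeping the maximum score); scores must be integers
    in [0, 1000].
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein1": str, "protein2": str})
    required = ["protein1", "protein2", "combined_score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"edge table missing required column(s): {missing}")
    df["protein1"] = df["protein1"].str.strip()
    df["protein2"] = df["protein2"].str.strip()
    df["combined_score"] = df["combined_score"].astype(int)
    if ((df["combined_score"] < 0) | (df["combined_score"] > 1000)).any():
        raise ValueError("combined_score outside [0, 1000]")
    df = df[df["protein1"] != df["protein2"]].copy()
    key = df.apply(lambda r: tuple(sorted((r["protein1"], r["protein2"]))), axis=1)
    df = df.assign(_key=key).sort_values("combined_score", ascending=False)
    df = df.drop_duplicates("_key").drop(columns="_key").reset_index(drop=True)
    return df


def write_edge_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    """One gene label per line; blank lines ignored, order preserved."""
    with open(path, encoding="utf-8") as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")
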