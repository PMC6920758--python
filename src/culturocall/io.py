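"""Readers, writers and cross-reference validation for pipeline file formats.

The pipeline exchanges five kinds of artifacts, all plain text:

* OTU count tables — tab-separated, samples in columns, ``#OTU_ID`` as the
  top-left header cell (BIOM-TSV convention);
* sample metadata — tab-separated with columns ``sample_id``, ``role``,
  ``experiment_id``, ``condition``, ``category``;
* taxonomy — tab-separated ``otu_id`` + semicolon-joined lineage, truncated
  at the deepest annotated rank (phylum → genus);
* rooted newick trees whose tips are OTU ids;
* FASTA sequence files.

Loading validates aggressively and fails with named offenders: downstream
stages assume ids are unique, counts are non-negative integers and every
sample column carries reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

__all__ = [
    "RANKS",
    "CATEGORIES",
    "ROLES",
    "OTU_HEADER",
    "ValidationError",
    "AbundanceTable",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "validate_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "read_tree",
    "reconcile_tips",
    "read_fasta",
    "write_fasta",
    "write_report",
]

#: Taxonomic ranks carried by lineage annotations, shallow to deep.
RANKS: tuple[str, ...] = ("phylum", "class", "order", "family", "genus")

#: Condition categories for culture samples (media-supplement vocabulary),
#: plus the reserved category of inoculum samples.
CATEGORIES: frozenset[str] = frozenset(
    {
        "non_supplemented",
        "complex_substrate",
        "simple_substrate",
        "carbohydrate",
        "fruit",
        "herb",
        "antibiotic",
        "miscellaneous",
        "inoculum",
    }
)

ROLES: tuple[str, str] = ("inoculum", "culture")

OTU_HEADER = "#OTU_ID"

METADATA_COLUMNS = ("sample_id", "role", "experiment_id", "condition", "category")


class ValidationError(ValueError):
    """Raised when an input fails a structural or cross-reference check."""


def _find_duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for item in items:
        if item in seen and item not in dups:
            dups.append(item)
        seen.add(item)
    return dups


@dataclass
class AbundanceTable:
    """An OTU × sample matrix of non-negative integer read counts.

    ``counts`` is indexed by OTU id (rows) and sample id (columns). Ids are
    case-sensitive and whitespace-trimmed; duplicate ids and zero-depth
    sample columns are rejected on construction.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        df.index = df.index.astype(str).str.strip()
        df.columns = df.columns.astype(str).str.strip()
        dup_otus = _find_duplicates(df.index)
        if dup_otus:
            raise ValidationError(f"duplicate OTU id(s): {', '.join(dup_otus)}")
        dup_samples = _find_duplicates(df.columns)
        if dup_samples:
            raise ValidationError(f"duplicate sample id(s): {', '.join(dup_samples)}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(values < 0):
            row, col = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at OTU {df.index[row]!r}, sample {df.columns[col]!r}"
            )
        if not np.allclose(values, np.round(values)):
            row, col = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise ValidationError(
                f"non-integer count at OTU {df.index[row]!r}, sample {df.columns[col]!r}"
            )
        self.counts = df.astype(np.int64)
        zero = self.counts.sum(axis=0) == 0
        if zero.any():
            bad = ", ".join(self.counts.columns[zero])
            raise ValidationError(f"zero-depth sample column(s): {bad}")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def read_otu_table(path: str | Path, format: str = "tsv") -> AbundanceTable:
    """Load a tab-separated OTU count table (samples in columns)."""
    if format != "tsv":
        raise ValueError(f"unsupported format {format!r}; only 'tsv' is supported")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment=None)
    df.index.name = OTU_HEADER
    try:
        numeric = df.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for j, col in enumerate(df.columns):
            converted = pd.to_numeric(df[col], errors="coerce")
            if converted.isna().any():
                i = int(np.argmax(converted.isna().to_numpy()))
                raise ValidationError(
                    f"{path.name}: non-numeric count at row {i + 2}, column {j + 2} "
                    f"(OTU {df.index[i]!r}, sample {col!r}): {df[col].iloc[i]!r}"
                ) from None
        raise
    return AbundanceTable(numeric)


def write_otu_table(table: AbundanceTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.index.name = OTU_HEADER
    df.to_csv(path, sep="\t")


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a metadata frame; returns it indexed by ``sample_id``."""
    missing = [c for c in METADATA_COLUMNS if c not in df.columns and df.index.name != c]
    if missing:
        raise ValidationError(f"metadata missing column(s): {', '.join(missing)}")
    if df.index.name != "sample_id":
        df = df.set_index("sample_id")
    df.index = df.index.astype(str).str.strip()
    dups = _find_duplicates(df.index)
    if dups:
        raise ValidationError(f"duplicate sample id(s): {', '.join(dups)}")
    bad_roles = sorted(set(df["role"]) - set(ROLES))
    if bad_roles:
        raise ValidationError(
            f"unknown role(s) {bad_roles}; allowed roles: {list(ROLES)}"
        )
    bad_cats = sorted(set(df["category"]) - CATEGORIES)
    if bad_cats:
        raise ValidationError(
            f"unknown category(s) {bad_cats}; allowed: {sorted(CATEGORIES)}"
        )
    df["experiment_id"] = df["experiment_id"].astype(str)
    n_inocula = df[df["role"] == "inoculum"].groupby("experiment_id").size()
    for exp in df["experiment_id"].unique():
        n = int(n_inocula.get(exp, 0))
        if n != 1:
            raise ValidationError(
                f"experiment {exp!r} has {n} inoculum samples; exactly one is required"
            )
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(df)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=True, index_label="sample_id")


def _parse_lineage(lineage: str) -> dict[str, str | None]:
    parts = [p.strip() for p in str(lineage).split(";") if p.strip()]
    if len(parts) > len(RANKS):
        raise ValidationError(
            f"lineage {lineage!r} has {len(parts)} ranks; at most {len(RANKS)} allowed"
        )
    out: dict[str, str | None] = {rank: None for rank in RANKS}
    for rank, name in zip(RANKS, parts):
        out[rank] = name
    return out


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Load rank-truncated lineage annotations.

    Returns a frame indexed by OTU id with one column per rank; absent ranks
    are NaN. The truncation (prefix) property holds by construction because
    lineages are parsed left to right.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "otu_id" not in df.columns or "lineage" not in df.columns:
        raise ValidationError("taxonomy file requires columns 'otu_id' and 'lineage'")
    df["otu_id"] = df["otu_id"].str.strip()
    dups = _find_duplicates(df["otu_id"])
    if dups:
        raise ValidationError(f"duplicate OTU id(s) in taxonomy: {', '.join(dups)}")
    rows = [_parse_lineage(lin) for lin in df["lineage"].fillna("")]
    out = pd.DataFrame(rows, index=df["otu_id"])
    out.index.name = "otu_id"
    return out


def write_taxonomy(taxonomy: pd.DataFrame, path: str | Path) -> None:
    lineages = taxonomy[list(RANKS)].apply(
        lambda row: ";".join(str(v) for v in row.dropna()), axis=1
    )
    pd.DataFrame({"otu_id": taxonomy.index, "lineage": lineages.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def deepest_rank(taxonomy_row: pd.Series) -> str | None:
    """Name of the deepest annotated rank in a taxonomy row (None if none)."""
    deepest = None
    for rank in RANKS:
        if pd.notna(taxonomy_row.get(rank)):
            deepest = rank
    return deepest


def read_tree(path: str | Path, otu_ids: Sequence[str] | None = None) -> dendropy.Tree:
    """Load a rooted newick tree; optionally reconcile tips against a table.

    Unmatched tips (present in the tree but absent from ``otu_ids``) trigger
    a warning, never a silent drop: reference isolates merged into the tree
    legitimately lack table counterparts.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise ValidationError(f"malformed newick in {path}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    dups = _find_duplicates(labels)
    if dups:
        raise ValidationError(f"duplicate tip label(s): {', '.join(dups)}")
    if otu_ids is not None:
        matched, unmatched = reconcile_tips(tree, otu_ids)
        if unmatched:
            warnings.warn(
                f"{len(unmatched)} tree tip(s) absent from the abundance table "
                f"(e.g. {unmatched[:5]}); treated as reference-only",
                stacklevel=2,
            )
    return tree


def reconcile_tips(
    tree: dendropy.Tree, otu_ids: Sequence[str]
) -> tuple[list[str], list[str]]:
    """Split tip labels into (matched, unmatched) against a set of OTU ids."""
    known = set(otu_ids)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    matched = [t for t in labels if t in known]
    unmatched = [t for t in labels if t not in known]
    return matched, unmatched


def read_fasta(path: str | Path) -> list[SeqRecord]:
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:
        raise ValidationError(f"malformed FASTA in {path}: {exc}") from exc
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SeqRecord], path: str | Path) -> None:
    SeqIO.write(records, str(path), "fasta")


def write_report(records: pd.DataFrame, path: str | Path) -> None:
    """Write a tab-separated report with a header row."""
    records.to_csv(path, sep="\t", index=False)
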