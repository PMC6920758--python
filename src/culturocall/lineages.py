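"""Detection of culture-resistant lineages on a growth-labelled phylogeny.

A culture-resistant lineage is a maximal clade of the OTU tree dominated by
non-growing tips: by default an entirely non-growing clade of at least four
tips (``max_growing_fraction=0``, ``min_size=4``). Reference-only tips —
previously obtained pure-culture isolates merged into the tree, with no
abundance-table counterpart — count as growing, since they are culturable
by construction. Only maximal qualifying clades are reported, so a lineage
is never nested inside another reported lineage.

Isolated non-growing tips and pairs below ``min_size`` are deliberately not
reported: a rare OTU may fail culture simply for being rare, whereas a whole
clade of non-growers points to shared, unmet growth requirements.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import pandas as pd

from .io import RANKS, ValidationError, deepest_rank

__all__ = [
    "LineageReport",
    "annotate_tips",
    "find_unculturable_lineages",
    "annotation_depth_profile",
    "lineage_table",
]


@dataclass
class LineageReport:
    """One detected culture-resistant lineage."""

    lineage_id: str
    tip_ids: list[str]
    n_growing: int
    common_annotation: str | None = None
    depth_histogram: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.tip_ids)


def annotate_tips(
    tree: dendropy.Tree,
    calls,
    reference_ids: Iterable[str] = (),
) -> dendropy.Tree:
    """Attach a boolean ``growing`` annotation to every tip.

    Tips must either match a growth-call record or belong to
    ``reference_ids`` (pure-culture isolates, labelled growing). Any other
    tip is an orphan and raises a validation error.
    """
    call_frame = calls.calls if hasattr(calls, "calls") else calls
    growing = call_frame["growing"]
    refs = set(reference_ids)
    orphans = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else None
        if label in refs:
            leaf.growing = True
        elif label is not None and label in growing.index:
            leaf.growing = bool(growing[label])
        else:
            orphans.append(label)
    if orphans:
        raise ValidationError(
            f"{len(orphans)} tree tip(s) match neither growth calls nor the "
            f"reference set: {orphans[:10]}"
        )
    return tree


def find_unculturable_lineages(
    tree: dendropy.Tree,
    min_size: int = 4,
    max_growing_fraction: float = 0.0,
) -> list[LineageReport]:
    """Maximal clades of size >= min_size whose growing fraction is
    <= max_growing_fraction, sorted by size descending.

    The tree must have been labelled by :func:`annotate_tips`. Reported
    lineages are disjoint by construction (a qualifying clade inside a
    qualifying ancestor is absorbed by the ancestor).
    """
    # post-order pass: per-node tip and growing-tip counts
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            if not hasattr(node, "growing"):
                raise ValidationError("tree tips lack growth labels; run annotate_tips")
            node._n_tips = 1
            node._n_growing = int(node.growing)
        else:
            node._n_tips = sum(c._n_tips for c in node.child_nodes())
            node._n_growing = sum(c._n_growing for c in node.child_nodes())

    def qualifies(node) -> bool:
        return (
            node._n_tips >= min_size
            and node._n_growing / node._n_tips <= max_growing_fraction
        )

    # pre-order pass keeping only maximal qualifying nodes
    reports: list[LineageReport] = []
    stack = [tree.seed_node]
    while stack:
        node = stack.pop()
        if qualifies(node):
            tips = sorted(
                leaf.taxon.label for leaf in node.leaf_iter() if leaf.taxon
            )
            reports.append(
                LineageReport(
                    lineage_id="",  # assigned after sorting
                    tip_ids=tips,
                    n_growing=node._n_growing,
                )
            )
        else:
            stack.extend(node.child_nodes())
    reports.sort(key=lambda r: (-r.size, r.tip_ids))
    for i, rep in enumerate(reports, start=1):
        rep.lineage_id = f"L{i}"
    return reports


def _deepest_common_annotation(
    tip_ids: Sequence[str], taxonomy: pd.DataFrame
) -> str | None:
    """Deepest rank value shared by all annotated tips of a lineage."""
    common: str | None = None
    for rank in RANKS:
        values = {
            str(taxonomy.loc[t, rank])
            for t in tip_ids
            if t in taxonomy.index and pd.notna(taxonomy.loc[t, rank])
        }
        missing = any(
            t not in taxonomy.index or pd.isna(taxonomy.loc[t, rank]) for t in tip_ids
        )
        if len(values) == 1 and not missing:
            common = values.pop()
        else:
            break
    return common


def annotation_depth_profile(
    report: LineageReport, taxonomy: pd.DataFrame
) -> dict[str, int]:
    """Histogram of lineage tips by deepest annotated rank.

    Tips with no annotation at all are counted under ``"unannotated"``.
    """
    counts: Counter[str] = Counter()
    for tip in report.tip_ids:
        if tip in taxonomy.index:
            rank = deepest_rank(taxonomy.loc[tip])
        else:
            rank = None
        counts[rank if rank is not None else "unannotated"] += 1
    return dict(counts)


def lineage_table(
    reports: Sequence[LineageReport], taxonomy: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Flatten lineage reports to a writable frame (one row per lineage)."""
    rows = []
    for rep in reports:
        if taxonomy is not None:
            rep.common_annotation = _deepest_common_annotation(rep.tip_ids, taxonomy)
            rep.depth_histogram = annotation_depth_profile(rep, taxonomy)
        hist = ";".join(f"{k}={v}" for k, v in sorted(rep.depth_histogram.items()))
        rows.append(
            {
                "lineage_id": rep.lineage_id,
                "size": rep.size,
                "n_growing": rep.n_growing,
                "common_annotation": rep.common_annotation,
                "annotation_depths": hist,
                "tip_ids": ",".join(rep.tip_ids),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "lineage_id",
            "size",
            "n_growing",
            "common_annotation",
            "annotation_depths",
            "tip_ids",
        ],
    )
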