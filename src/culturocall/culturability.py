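"""Culturability calling: OTU selection, growth verdicts and taxon summaries.

The central question of a culturomics screen is which members of the source
community grew in any of the tested media. Because the cultured bacterial
mass is washed off plates carrying on the order of a thousand colonies, a
single colony represents roughly 0.1% of the sequenced community — so both
the selection of "common" OTUs in the inoculum and the growth verdict in a
culture use a relative-abundance threshold, 0.001 by default.

An OTU is *selected* when it reaches the threshold in at least one inoculum
sample, and a selected OTU is *growing* when it reaches the threshold in at
least one culture sample. The comparison is inclusive (>=) by default; the
strict (>) reading is available via ``inclusive=False``. Growth calls pool
culture samples across experiments by default; ``scope="same_experiment"``
restricts an OTU's eligible cultures to experiments whose inoculum actually
contained it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import AbundanceTable, ValidationError

__all__ = [
    "GrowthCallSet",
    "relative_abundance",
    "select_common_otus",
    "call_growth",
    "phylum_summary",
    "pct_growing",
    "rank_culturability_curve",
    "detection_limit",
]

DEFAULT_THRESHOLD = 0.001

UNCLASSIFIED = "Unclassified Bacteria"


@dataclass
class GrowthCallSet:
    """Per-OTU culturability verdicts.

    ``calls`` is indexed by OTU id with columns:

    selected
        reached the selection threshold in >=1 inoculum sample
    growing
        selected and reached the growth threshold in >=1 culture sample
    max_inoculum_ra, max_culture_ra
        maximal relative abundance across inoculum / eligible culture samples
    best_condition
        condition label of the culture sample with the highest relative
        abundance (ties broken lexicographically); None when the OTU was
        never observed in culture
    """

    calls: pd.DataFrame
    threshold: float = DEFAULT_THRESHOLD
    inclusive: bool = True
    scope: str = "pooled"

    def __post_init__(self) -> None:
        bad = self.calls["growing"] & ~self.calls["selected"]
        if bad.any():
            raise ValidationError(
                f"growing OTU(s) not selected: {list(self.calls.index[bad])}"
            )

    @property
    def otu_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def selected_ids(self) -> list[str]:
        return list(self.calls.index[self.calls["selected"]])

    @property
    def growing_ids(self) -> list[str]:
        return list(self.calls.index[self.calls["growing"]])

    def to_frame(self) -> pd.DataFrame:
        out = self.calls.reset_index().rename(columns={"index": "otu_id"})
        out.columns = ["otu_id", *self.calls.columns]
        return out


def relative_abundance(table: AbundanceTable) -> pd.DataFrame:
    """Convert counts to within-sample proportions (columns sum to 1)."""
    sums = table.counts.sum(axis=0)
    if (sums == 0).any():
        bad = ", ".join(sums.index[sums == 0])
        raise ValidationError(f"zero-depth sample column(s): {bad}")
    return table.counts / sums


def _passes(values: pd.DataFrame | pd.Series, threshold: float, inclusive: bool):
    return values >= threshold if inclusive else values > threshold


def _check_samples(ra: pd.DataFrame, sample_ids: Iterable[str]) -> list[str]:
    missing = [s for s in sample_ids if s not in ra.columns]
    if missing:
        raise ValidationError(f"metadata sample(s) absent from table: {missing}")
    return list(sample_ids)


def select_common_otus(
    ra: pd.DataFrame,
    metadata: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    inclusive: bool = True,
) -> list[str]:
    """OTUs reaching ``threshold`` in at least one inoculum sample.

    Returns ids in table row order.
    """
    inocula = metadata.index[metadata["role"] == "inoculum"]
    inocula = [s for s in inocula if s in ra.columns]
    if not inocula:
        raise ValidationError("no inoculum samples present in the table")
    hit = _passes(ra[inocula], threshold, inclusive).any(axis=1)
    return list(ra.index[hit])


def call_growth(
    ra: pd.DataFrame,
    metadata: pd.DataFrame,
    selected: Sequence[str],
    threshold: float = DEFAULT_THRESHOLD,
    scope: str = "pooled",
    inclusive: bool = True,
) -> GrowthCallSet:
    """Call in-vitro growth for every OTU in the table.

    An OTU grows when it is selected and its relative abundance reaches
    ``threshold`` in at least one eligible culture sample. With
    ``scope="pooled"`` every culture sample is eligible; with
    ``scope="same_experiment"`` only cultures from experiments whose
    inoculum contained the OTU (abundance > 0) are.
    """
    if scope not in ("pooled", "same_experiment"):
        raise ValueError(f"unknown scope {scope!r}")
    cultures = [s for s in metadata.index[metadata["role"] == "culture"] if s in ra.columns]
    if not cultures:
        raise ValidationError("no culture samples present in the table")
    inocula = [s for s in metadata.index[metadata["role"] == "inoculum"] if s in ra.columns]
    selected_set = set(selected)
    if not selected_set:
        warnings.warn("empty selected OTU set; all growth calls are negative", stacklevel=2)

    condition_of = metadata.loc[cultures, "condition"]
    experiment_of = metadata.loc[cultures, "experiment_id"]
    inoculum_of_exp = {
        metadata.loc[s, "experiment_id"]: s for s in inocula
    }

    culture_ra = ra[cultures]
    if scope == "same_experiment":
        # eligibility mask: culture sample c eligible for OTU o iff the
        # inoculum of c's experiment contained o above zero
        inoc_cols = [inoculum_of_exp[e] for e in experiment_of]
        eligible = (ra[inoc_cols] > 0).to_numpy()
        culture_ra = culture_ra.where(pd.DataFrame(eligible, index=ra.index, columns=cultures))

    max_culture = culture_ra.max(axis=1).fillna(0.0)
    max_inoc = ra[inocula].max(axis=1) if inocula else pd.Series(0.0, index=ra.index)

    # best condition: maximal culture RA, ties lexicographic by condition label
    order = sorted(cultures, key=lambda s: condition_of[s])
    ordered = culture_ra[order].fillna(-1.0)
    best_sample = ordered.idxmax(axis=1)
    best_condition = best_sample.map(condition_of)
    best_condition = best_condition.where(max_culture > 0, other=None)

    sel = pd.Series(ra.index.isin(selected_set), index=ra.index)
    growing = sel & _passes(max_culture, threshold, inclusive)
    calls = pd.DataFrame(
        {
            "selected": sel,
            "growing": growing,
            "max_inoculum_ra": max_inoc,
            "max_culture_ra": max_culture,
            "best_condition": best_condition,
        },
        index=ra.index,
    )
    calls.index.name = "otu_id"
    return GrowthCallSet(calls, threshold=threshold, inclusive=inclusive, scope=scope)


def pct_growing(n_growing: int, n_total: int) -> float:
    """Percentage of growing OTUs, rounded half-up to two decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    pct = Decimal(100 * n_growing) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def phylum_summary(calls: GrowthCallSet, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Per-phylum growth counts among selected OTUs, with a Total row.

    OTUs without a phylum annotation are binned as "Unclassified Bacteria".
    Percentages are rounded half-up to two decimals.
    """
    selected = calls.calls[calls.calls["selected"]]
    phyla = []
    for otu in selected.index:
        if otu in taxonomy.index and pd.notna(taxonomy.loc[otu, "phylum"]):
            phyla.append(str(taxonomy.loc[otu, "phylum"]))
        else:
            phyla.append(UNCLASSIFIED)
    df = pd.DataFrame({"phylum": phyla, "growing": selected["growing"].to_numpy()})
    grouped = df.groupby("phylum", sort=True)
    rows = []
    for phylum, grp in grouped:
        n_total = len(grp)
        n_growing = int(grp["growing"].sum())
        rows.append(
            {
                "phylum": phylum,
                "n_total": n_total,
                "n_non_growing": n_total - n_growing,
                "n_growing": n_growing,
                "pct_growing": pct_growing(n_growing, n_total),
            }
        )
    total = len(df)
    growing = int(df["growing"].sum())
    rows.append(
        {
            "phylum": "Total",
            "n_total": total,
            "n_non_growing": total - growing,
            "n_growing": growing,
            "pct_growing": pct_growing(growing, total) if total else 0.0,
        }
    )
    return pd.DataFrame(rows)


def rank_culturability_curve(
    calls: GrowthCallSet, ra: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Cumulative non-growing fraction among the top-k most abundant OTUs.

    Selected OTUs are ranked by maximal inoculum relative abundance,
    descending (ties broken lexicographically by OTU id); the value at rank
    k is the fraction of non-growing OTUs among the top k.
    """
    inocula = [s for s in metadata.index[metadata["role"] == "inoculum"] if s in ra.columns]
    if not inocula:
        raise ValidationError("no inoculum samples present in the table")
    selected = calls.calls[calls.calls["selected"]]
    key = ra.loc[selected.index, inocula].max(axis=1)
    order = sorted(selected.index, key=lambda o: (-key[o], o))
    non_growing = (~selected.loc[order, "growing"]).to_numpy().astype(float)
    k = np.arange(1, len(order) + 1)
    frac = np.cumsum(non_growing) / k
    return pd.DataFrame(
        {
            "rank": k,
            "otu_id": order,
            "max_inoculum_ra": key[order].to_numpy(),
            "frac_non_growing": frac,
        }
    )


def detection_limit(colony_count: int) -> float:
    """Minimal relative abundance a single colony can represent.

    With roughly ``colony_count`` colonies washed from a plate, one colony
    contributes 1/colony_count of the sequenced mass — the rationale for
    the 0.1% growth threshold at ~1000 colonies.
    """
    if not isinstance(colony_count, (int, np.integer)) or colony_count < 1:
        raise ValueError("colony_count must be a positive integer")
    return 1.0 / colony_count
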