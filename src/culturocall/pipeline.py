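"""End-to-end pipeline: io -> culturability -> selectivity -> lineages -> chimera.

Given a count table, metadata and taxonomy (plus optionally a tree and
query/reference FASTA files), runs every analysis stage and writes one
tab-separated report per stage. Optional inputs that are absent simply skip
their stage with a logged notice. For the lineage stage the tree is
restricted to selected OTUs — the tree a culturomics study actually draws —
while tips with no table counterpart are kept as reference-only (growing)
isolates.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import chimera as chimera_mod
from . import culturability, io as ccio, lineages as lineages_mod, selectivity

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("culturocall")


@dataclass
class PipelineConfig:
    """Paths and parameters for a full pipeline run."""

    table: str | Path
    metadata: str | Path
    taxonomy: str | Path
    out: str | Path
    tree: str | Path | None = None
    queries: str | Path | None = None
    refs: str | Path | None = None
    selection_threshold: float = culturability.DEFAULT_THRESHOLD
    growth_threshold: float = culturability.DEFAULT_THRESHOLD
    inclusive: bool = True
    scope: str = "pooled"
    top_k: int = 15
    min_size: int = 4
    max_growing_fraction: float = 0.0
    end_length: int = 80
    min_high_identity: float = 97.0
    min_gap: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("selection_threshold", "growth_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ccio.ValidationError(f"{name}={v} outside (0, 1]")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat key=value config file; keyword overrides win."""
        values: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            values[key.strip()] = value.strip()
        kwargs: dict = {}
        for f in cls.__dataclass_fields__.values():
            if f.name in values:
                raw = values[f.name]
                if f.type in ("float", float):
                    kwargs[f.name] = float(raw)
                elif f.type in ("int", int):
                    kwargs[f.name] = int(raw)
                elif f.type == "bool" or f.type is bool:
                    kwargs[f.name] = raw.lower() in ("1", "true", "yes")
                else:
                    kwargs[f.name] = raw
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)


def _stage(name: str, started: float, n: int) -> None:
    log.info("stage=%s wall_s=%.2f records=%d", name, time.perf_counter() - started, n)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write reports under ``config.out``.

    Returns the output directory. Raises a ``ValidationError`` naming the
    stage and offending entity on any input problem.
    """
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run_log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> Path:
    t0 = time.perf_counter()
    table = ccio.read_otu_table(config.table)
    metadata = ccio.read_metadata(config.metadata)
    taxonomy = ccio.read_taxonomy(config.taxonomy)
    _stage("io", t0, table.shape[0])

    # culturability
    t0 = time.perf_counter()
    ra = culturability.relative_abundance(table)
    selected = culturability.select_common_otus(
        ra, metadata, threshold=config.selection_threshold, inclusive=config.inclusive
    )
    calls = culturability.call_growth(
        ra,
        metadata,
        selected,
        threshold=config.growth_threshold,
        scope=config.scope,
        inclusive=config.inclusive,
    )
    ccio.write_report(calls.to_frame(), outdir / "calls.tsv")
    summary = culturability.phylum_summary(calls, taxonomy)
    ccio.write_report(summary, outdir / "phylum_summary.tsv")
    curve = culturability.rank_culturability_curve(calls, ra, metadata)
    ccio.write_report(curve, outdir / "rank_curve.tsv")
    _stage("culturability", t0, len(selected))

    # selectivity
    t0 = time.perf_counter()
    matrix = selectivity.family_abundance(ra, taxonomy, metadata)
    matrix.reset_index().to_csv(outdir / "family_matrix.tsv", sep="\t", index=False)
    tops = []
    for family in matrix.index:
        top = selectivity.rank_conditions(matrix, family, config.top_k)
        top.insert(0, "family", family)
        tops.append(top)
    ccio.write_report(pd.concat(tops, ignore_index=True), outdir / "top_conditions.tsv")
    divergence = selectivity.condition_divergence(ra, metadata)
    ccio.write_report(divergence, outdir / "divergence.tsv")
    distances = selectivity.bray_curtis(ra)
    ordination = selectivity.pcoa(distances, n_axes=2)
    coords = ordination.coordinates.reset_index(names="sample_id")
    ccio.write_report(coords, outdir / "pcoa.tsv")
    _stage("selectivity", t0, len(divergence))

    # lineages (optional)
    if config.tree is not None and Path(config.tree).exists():
        t0 = time.perf_counter()
        tree = ccio.read_tree(config.tree)
        matched, unmatched = ccio.reconcile_tips(tree, table.otu_ids)
        keep = set(calls.selected_ids) | set(unmatched)
        tips_to_keep = [t for t in matched + unmatched if t in keep]
        if len(tips_to_keep) >= 2:
            tree.retain_taxa_with_labels(tips_to_keep)
            lineages_mod.annotate_tips(tree, calls, reference_ids=unmatched)
            reports = lineages_mod.find_unculturable_lineages(
                tree,
                min_size=config.min_size,
                max_growing_fraction=config.max_growing_fraction,
            )
        else:
            reports = []
        ccio.write_report(
            lineages_mod.lineage_table(reports, taxonomy), outdir / "lineages.tsv"
        )
        _stage("lineages", t0, len(reports))
    else:
        log.info("stage=lineages skipped (no tree provided)")

    # chimera screen (optional)
    if (
        config.queries is not None
        and config.refs is not None
        and Path(config.queries).exists()
        and Path(config.refs).exists()
    ):
        t0 = time.perf_counter()
        queries = ccio.read_fasta(config.queries)
        refs = ccio.read_fasta(config.refs)
        verdicts = chimera_mod.screen(
            queries,
            refs,
            min_high_identity=config.min_high_identity,
            min_gap=config.min_gap,
            end_length=config.end_length,
        )
        ccio.write_report(verdicts, outdir / "verdicts.tsv")
        _stage("chimera", t0, len(verdicts))
    else:
        log.info("stage=chimera skipped (queries/refs not provided)")

    return outdir
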