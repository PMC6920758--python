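"""Synthetic culturomics communities with full ground truth.

The generator emulates the structure of a caecal culturomics screen: a
log-normal species-abundance distribution (steep rank-abundance decline:
top species above 1%, a long tail of rare ones), six donor inocula with
inter-bird variation, and on the order of 174 culture conditions spread
unevenly over the experiments. Unculturability is planted as contiguous
clades of the species tree (defaults 11, 11 and 32 members) whose members
are common in the inocula but never grow, plus optional scattered
unculturable singletons. Media selectivity is planted as family-by-category
abundance multipliers applied to culture expectations before multinomial
resampling, and a split-end chimera benchmark is built by splicing species
sequences.

Every downstream stage can therefore be scored against exact truth:
growth calls against planted culturability flags, lineage detection
against planted clades, enrichment rankings against planted multipliers,
and chimera verdicts against recorded splice parents.

All randomness flows from one ``numpy.random.Generator`` seeded by
``SimulationConfig.seed``; identical configs produce bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import io as ccio
from .io import AbundanceTable, RANKS, ValidationError

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "Community",
    "Dataset",
    "DEFAULT_SELECTIVITY",
    "generate_community",
    "simulate_cultures",
    "generate_sequences",
    "generate_chimeras",
    "generate_dataset",
]

#: Conditions per experiment in a six-experiment screen (scaled to fit the
#: requested total); the totals 60/12/14/40/33/15 sum to 174.
EXPERIMENT_CONDITION_PATTERN = (60, 12, 14, 40, 33, 15)

#: How many media/supplement entries each category contributes, used as
#: sampling weights for condition categories.
CATEGORY_WEIGHTS = {
    "non_supplemented": 11,
    "complex_substrate": 14,
    "simple_substrate": 21,
    "carbohydrate": 6,
    "fruit": 3,
    "herb": 15,
    "antibiotic": 7,
    "miscellaneous": 3,
}

BASE_MEDIA = ("BHI", "WCHA", "WCHB", "YCFA", "YCFB", "TSA", "TGA", "LB", "BloodAgar", "Brucella")

#: (phylum, class, order, family, genus stem, sampling weight)
FAMILY_SCAFFOLD = (
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Blautia", 22),
    ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Faecalibacterium", 20),
    ("Firmicutes", "Erysipelotrichia", "Erysipelotrichales", "Erysipelotrichaceae", "Erysipelatoclostridium", 6),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus", 5),
    ("Firmicutes", "Negativicutes", "Selenomonadales", "Veillonellaceae", "Megamonas", 6),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides", 14),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella", 8),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Porphyromonadaceae", "Parabacteroides", 6),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Escherichia", 5),
    ("Proteobacteria", "Deltaproteobacteria", "Desulfovibrionales", "Desulfovibrionaceae", "Desulfovibrio", 3),
    ("Actinobacteria", "Actinobacteria", "Bifidobacteriales", "Bifidobacteriaceae", "Bifidobacterium", 3),
    ("Fusobacteria", "Fusobacteriia", "Fusobacteriales", "Fusobacteriaceae", "Fusobacterium", 2),
)

#: Planted family-by-category enrichment, mirroring the kinds of selection a
#: culturomics screen exhibits (saccharide/fruit media for lactobacilli,
#: antibiotics for erysipelotrichs, bile salts for veillonellas and
#: enterobacteria, plain YCF media for sulphate reducers).
DEFAULT_SELECTIVITY: dict[str, dict[str, float]] = {
    "Lactobacillaceae": {"carbohydrate": 8.0, "fruit": 8.0, "miscellaneous": 4.0},
    "Veillonellaceae": {"miscellaneous": 6.0, "antibiotic": 4.0},
    "Erysipelotrichaceae": {"antibiotic": 8.0},
    "Desulfovibrionaceae": {"non_supplemented": 5.0},
    "Enterobacteriaceae": {"miscellaneous": 5.0},
    "Prevotellaceae": {"complex_substrate": 4.0},
}


@dataclass
class SimulationConfig:
    """Parameters of a synthetic culturomics screen.

    Defaults follow the emulated study design: 6 inocula, 174 culture
    conditions, log-normal(0, 2) species abundances, read depth near the
    study's median per-sample coverage, and three planted unculturable
    clades of 11, 11 and 32 species.
    """

    n_species: int = 300
    n_inocula: int = 6
    n_conditions: int = 174
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 2.0
    depth: int = 50_000
    frac_unculturable: float = 0.18
    n_unculturable_clades: int = 3
    clade_sizes: tuple[int, ...] = (11, 11, 32)
    selectivity_multipliers: Mapping[str, Mapping[str, float]] | None = None
    chimera_rate: float = 0.1
    n_chimera_queries: int = 200
    chimera_noise: float = 0.02
    seq_length: int = 250
    inoculum_sigma: float = 0.7
    common_clade_mu_shift: float = 2.5
    common_clade_sigma: float = 0.8
    common_clade_floor: float = 7.0
    phylum_truncation_frac: float = 19 / 32
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_unculturable", "chimera_rate", "chimera_noise", "phylum_truncation_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        if self.n_species < 1 or self.n_inocula < 1 or self.n_conditions < 1:
            raise ValidationError("n_species, n_inocula and n_conditions must be >= 1")
        self.clade_sizes = tuple(int(s) for s in self.clade_sizes)
        if len(self.clade_sizes) != self.n_unculturable_clades:
            raise ValidationError(
                f"{len(self.clade_sizes)} clade sizes for "
                f"{self.n_unculturable_clades} clades"
            )
        if any(s < 1 for s in self.clade_sizes):
            raise ValidationError("clade sizes must be positive")
        if sum(self.clade_sizes) > self.frac_unculturable * self.n_species + 1e-9:
            raise ValidationError(
                "sum of clade_sizes exceeds frac_unculturable * n_species"
            )
        if self.seq_length < 160:
            raise ValidationError("seq_length must be >= 160 for the split-end screen")

    @property
    def multipliers(self) -> Mapping[str, Mapping[str, float]]:
        table = (
            DEFAULT_SELECTIVITY
            if self.selectivity_multipliers is None
            else self.selectivity_multipliers
        )
        for fam, per_cat in table.items():
            if any(m <= 0 for m in per_cat.values()):
                raise ValidationError(f"non-positive multiplier for family {fam!r}")
        return table


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated dataset."""

    culturable: pd.Series  # bool per OTU
    lineage_id: pd.Series  # clade label per OTU, or None
    expected_ra: pd.DataFrame | None = None  # OTU x sample expected proportions
    chimeras: pd.DataFrame | None = None  # per-query splice records


@dataclass
class Community:
    """A generated species pool: taxonomy, tree, abundances and truth."""

    otu_ids: list[str]
    taxonomy: pd.DataFrame
    tree: dendropy.Tree
    base_abundance: np.ndarray
    inoculum_expected: pd.DataFrame  # OTU x inoculum-sample expected proportions
    truth: SyntheticTruth


def _allocate_conditions(n_conditions: int, n_inocula: int) -> list[int]:
    """Split conditions over experiments, largest-remainder, each >= 1."""
    if n_conditions < n_inocula:
        raise ValidationError("need at least one condition per experiment")
    pattern = [
        EXPERIMENT_CONDITION_PATTERN[i % len(EXPERIMENT_CONDITION_PATTERN)]
        for i in range(n_inocula)
    ]
    total = sum(pattern)
    raw = [n_conditions * p / total for p in pattern]
    counts = [max(1, math.floor(r)) for r in raw]
    remainders = sorted(
        range(n_inocula), key=lambda i: raw[i] - math.floor(raw[i]), reverse=True
    )
    i = 0
    while sum(counts) < n_conditions:
        counts[remainders[i % n_inocula]] += 1
        i += 1
    while sum(counts) > n_conditions:
        j = max(range(n_inocula), key=lambda k: counts[k])
        counts[j] -= 1
    return counts


def _build_subtree(labels: Sequence[str], tns: dendropy.TaxonNamespace, rng) -> dendropy.Node:
    """Random sequential coalescence over a set of tip labels."""
    nodes = []
    for label in labels:
        leaf = dendropy.Node()
        leaf.taxon = tns.require_taxon(label=label)
        leaf.edge.length = float(rng.exponential(0.05))
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        parent.edge.length = float(rng.exponential(0.05))
        nodes = [n for k, n in enumerate(nodes) if k not in (int(i), int(j))]
        nodes.append(parent)
    return nodes[0]


def _plant_clades(
    background: Sequence[str],
    clades: Sequence[Sequence[str]],
    tns: dendropy.TaxonNamespace,
    rng,
    anchors: Sequence[str] | None = None,
) -> dendropy.Tree:
    """Backbone over background species with clade subtrees grafted onto
    backbone edges, so planted clades are monophyletic and mutually
    exclusive. Each clade is grafted directly above its anchor tip — an
    abundant background species — which keeps neighbouring clades
    separated even in trees later restricted to common species."""
    if clades and len(background) < max(2, len(clades)):
        raise ValidationError(
            "not enough background species to place unculturable clades; "
            "use smaller clades or more species"
        )
    root = _build_subtree(background, tns, rng)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    if anchors is None:
        anchors = [background[int(k)] for k in rng.choice(len(background), size=len(clades), replace=False)]
    leaf_of = {
        leaf.taxon.label: leaf for leaf in root.leaf_iter() if leaf.taxon is not None
    }
    for clade_labels, anchor in zip(clades, anchors):
        clade_root = _build_subtree(clade_labels, tns, rng)
        target = leaf_of[anchor]
        parent = target.parent_node
        joint = dendropy.Node()
        length = target.edge.length or 0.1
        parent.remove_child(target)
        parent.add_child(joint)
        joint.add_child(target)
        joint.add_child(clade_root)
        joint.edge.length = length / 2
        target.edge.length = length / 2
    tree.is_rooted = True
    return tree


def generate_community(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> Community:
    """Generate taxonomy, tree, base abundances and culturability truth."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_species
    otu_ids = [f"OTU_{i + 1:04d}" for i in range(n)]

    # --- culturability flags and clade membership -------------------------
    n_unculturable = int(round(config.frac_unculturable * n))
    clade_sizes = list(config.clade_sizes)
    order = rng.permutation(n)
    cursor = 0
    clade_members: list[list[int]] = []
    for size in clade_sizes:
        clade_members.append(sorted(int(k) for k in order[cursor : cursor + size]))
        cursor += size
    n_extra = n_unculturable - sum(clade_sizes)
    extras = sorted(int(k) for k in order[cursor : cursor + n_extra])

    culturable = np.ones(n, dtype=bool)
    lineage = np.array([None] * n, dtype=object)
    for c, members in enumerate(clade_members):
        for k in members:
            culturable[k] = False
            lineage[k] = f"clade_{c + 1}"
    for k in extras:
        culturable[k] = False

    # --- taxonomy ---------------------------------------------------------
    weights = np.array([f[5] for f in FAMILY_SCAFFOLD], dtype=float)
    fam_draw = rng.choice(len(FAMILY_SCAFFOLD), size=n, p=weights / weights.sum())
    rows = []
    for i in range(n):
        phylum, cls, order_name, family, genus_stem, _ = FAMILY_SCAFFOLD[fam_draw[i]]
        rows.append(
            {
                "phylum": phylum,
                "class": cls,
                "order": order_name,
                "family": family,
                "genus": f"{genus_stem}{i + 1}",
            }
        )
    taxonomy = pd.DataFrame(rows, index=otu_ids)
    taxonomy.index.name = "otu_id"

    # planted clades override scaffold taxonomy: two rank-truncated patterns
    # (novel Clostridiales families; a deep novel Bacteroidetes lineage with
    # mostly phylum-only annotation). The largest clade takes the deep one.
    if clade_members:
        deep = max(range(len(clade_members)), key=lambda c: (len(clade_members[c]), c))
        for c, members in enumerate(clade_members):
            for k in members:
                otu = otu_ids[k]
                if c == deep and len(clade_members) > 1:
                    if rng.random() < config.phylum_truncation_frac:
                        taxonomy.loc[otu] = ["Bacteroidetes", None, None, None, None]
                    else:
                        taxonomy.loc[otu] = [
                            "Bacteroidetes", "Bacteroidia", "Bacteroidales", None, None,
                        ]
                else:
                    taxonomy.loc[otu] = [
                        "Firmicutes", "Clostridia", "Clostridiales", None, None,
                    ]

    # --- abundances -------------------------------------------------------
    base = rng.lognormal(config.lognormal_mu, config.lognormal_sigma, n)
    # planted-clade members are common community members (the emulated
    # lineages were abundant in the caecum): drawn from the upper tail,
    # with a floor at several times the community median so every clade
    # member is detectable in the inocula
    for members in clade_members:
        for k in members:
            draw = rng.lognormal(
                config.lognormal_mu + config.common_clade_mu_shift,
                config.common_clade_sigma,
            )
            base[k] = max(draw, config.common_clade_floor)
    inoc_cols = {}
    for e in range(config.n_inocula):
        jitter = rng.lognormal(0.0, config.inoculum_sigma, n)
        expected = base * jitter
        inoc_cols[f"I{e + 1}"] = expected / expected.sum()
    inoculum_expected = pd.DataFrame(inoc_cols, index=otu_ids)

    # --- tree -------------------------------------------------------------
    tns = dendropy.TaxonNamespace()
    clade_labels = [[otu_ids[k] for k in members] for members in clade_members]
    in_clade = {k for members in clade_members for k in members}
    background = [otu_ids[k] for k in range(n) if k not in in_clade]
    # clade anchors: the most abundant background species, so clades stay
    # separated even in trees restricted to common OTUs
    anchors = sorted(background, key=lambda o: -base[otu_ids.index(o)])[: len(clade_labels)]
    tree = _plant_clades(background, clade_labels, tns, rng, anchors=anchors)

    truth = SyntheticTruth(
        culturable=pd.Series(culturable, index=otu_ids, name="culturable"),
        lineage_id=pd.Series(lineage, index=otu_ids, name="lineage_id"),
    )
    return Community(otu_ids, taxonomy, tree, base, inoculum_expected, truth)


def simulate_cultures(
    community: Community,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Multinomially sample inoculum and culture communities.

    Per culture sample, expected proportions are the experiment's inoculum
    expectation times the culturability flag times the family-by-category
    selectivity multiplier, renormalized; unculturable species have expected
    culture abundance exactly zero. Expected per-sample proportions are
    stored in ``community.truth.expected_ra``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = len(community.otu_ids)
    multipliers = config.multipliers
    family = np.array(
        [
            community.taxonomy.loc[o, "family"]
            if pd.notna(community.taxonomy.loc[o, "family"])
            else ""
            for o in community.otu_ids
        ],
        dtype=object,
    )
    culturable = community.truth.culturable.to_numpy()
    per_experiment = _allocate_conditions(config.n_conditions, config.n_inocula)

    categories = sorted(CATEGORY_WEIGHTS)
    cat_p = np.array([CATEGORY_WEIGHTS[c] for c in categories], dtype=float)
    cat_p /= cat_p.sum()

    counts: dict[str, np.ndarray] = {}
    expected: dict[str, np.ndarray] = {}
    meta_rows = []
    cond_counter = 0
    for e in range(config.n_inocula):
        inoc_id = f"I{e + 1}"
        p_inoc = community.inoculum_expected[inoc_id].to_numpy()
        counts[inoc_id] = rng.multinomial(config.depth, p_inoc)
        expected[inoc_id] = p_inoc
        meta_rows.append(
            {
                "sample_id": inoc_id,
                "role": "inoculum",
                "experiment_id": str(e + 1),
                "condition": f"caecal_content_E{e + 1}",
                "category": "inoculum",
            }
        )
        for _ in range(per_experiment[e]):
            cond_counter += 1
            category = categories[int(rng.choice(len(categories), p=cat_p))]
            base_medium = BASE_MEDIA[int(rng.integers(len(BASE_MEDIA)))]
            condition = f"C{cond_counter:03d}:{base_medium}+{category}"
            mult = np.array(
                [multipliers.get(f, {}).get(category, 1.0) for f in family]
            )
            p = p_inoc * culturable * mult
            total = p.sum()
            if total == 0:
                raise ValidationError(
                    f"all species unculturable for condition {condition!r}: "
                    "expected community is empty"
                )
            p = p / total
            sample_id = f"S{cond_counter:03d}"
            counts[sample_id] = rng.multinomial(config.depth, p)
            expected[sample_id] = p
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "role": "culture",
                    "experiment_id": str(e + 1),
                    "condition": condition,
                    "category": category,
                }
            )
    table = AbundanceTable(pd.DataFrame(counts, index=community.otu_ids))
    metadata = ccio.validate_metadata(pd.DataFrame(meta_rows))
    community.truth.expected_ra = pd.DataFrame(expected, index=community.otu_ids)
    return table, metadata


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for k in hits:
        choices = _BASES[_BASES != arr[k]]
        arr[k] = choices[int(rng.integers(3))]
    return bytes(arr).decode("ascii")


def generate_sequences(
    community: Community, config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[SeqRecord]:
    """One random reference sequence per species; the FASTA description
    carries the genus token used as the reference taxon."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    records = []
    for otu in community.otu_ids:
        genus = community.taxonomy.loc[otu, "genus"]
        if pd.isna(genus):
            genus = f"UnculturedTaxon{otu.split('_')[-1]}"
        records.append(
            SeqRecord(
                Seq(_random_seq(rng, config.seq_length)),
                id=otu,
                description=f"{otu} {genus} caecicola",
            )
        )
    return records


def generate_chimeras(
    references: list[SeqRecord],
    rate: float,
    rng: np.random.Generator | int | None = None,
    n_queries: int | None = None,
    noise: float = 0.02,
    five_prime_pool: Sequence[int] | None = None,
    three_prime_pool: Sequence[int] | None = None,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Splice chimeric queries from reference sequences.

    A chimera joins a prefix of one parent to the suffix of another at a
    uniform breakpoint at least 80 nt from both ends; non-chimeric queries
    are references with independent per-base substitution noise. Pools
    restrict which references may serve as 5'/3' parents (and as sources of
    non-chimeric queries, drawn from the 5' pool).
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(0 if rng is None else int(rng))
    if not 0.0 <= rate <= 1.0:
        raise ValidationError(f"rate={rate} outside [0, 1]")
    for rec in references:
        if len(rec.seq) < 160:
            raise ValidationError(
                f"reference {rec.id!r} shorter than 160 nt; cannot splice"
            )
    if rate > 0 and len(references) < 2:
        raise ValidationError("chimera generation requires at least 2 references")
    five_pool = list(five_prime_pool) if five_prime_pool is not None else list(range(len(references)))
    three_pool = list(three_prime_pool) if three_prime_pool is not None else list(range(len(references)))
    if rate > 0 and not (set(five_pool) | set(three_pool) and five_pool and three_pool):
        raise ValidationError("empty parent pool")
    if n_queries is None:
        n_queries = len(references)

    queries: list[SeqRecord] = []
    rows = []
    for q in range(n_queries):
        qid = f"Q{q + 1:04d}"
        if rng.random() < rate:
            p5 = references[five_pool[int(rng.integers(len(five_pool)))]]
            while True:
                p3 = references[three_pool[int(rng.integers(len(three_pool)))]]
                if p3.id != p5.id:
                    break
            limit = min(len(p5.seq), len(p3.seq))
            breakpoint_ = int(rng.integers(80, limit - 80, endpoint=True))
            seq = str(p5.seq)[:breakpoint_] + str(p3.seq)[breakpoint_:]
            rows.append(
                {
                    "query_id": qid,
                    "is_chimera": True,
                    "parent5": p5.id,
                    "parent3": p3.id,
                    "breakpoint": breakpoint_,
                }
            )
        else:
            src = references[five_pool[int(rng.integers(len(five_pool)))]]
            seq = _mutate(str(src.seq), noise, rng)
            rows.append(
                {
                    "query_id": qid,
                    "is_chimera": False,
                    "parent5": src.id,
                    "parent3": src.id,
                    "breakpoint": pd.NA,
                }
            )
        queries.append(SeqRecord(Seq(seq), id=qid, description=qid))
    truth = pd.DataFrame(rows)
    return queries, truth


@dataclass
class Dataset:
    """A complete synthetic fixture with ground truth."""

    config: SimulationConfig
    community: Community
    table: AbundanceTable
    metadata: pd.DataFrame
    references: list[SeqRecord]  # screening database (culturable species)
    queries: list[SeqRecord]
    all_sequences: list[SeqRecord] = field(default_factory=list)

    @property
    def truth(self) -> SyntheticTruth:
        return self.community.truth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ccio.write_otu_table(self.table, outdir / "table.tsv")
        ccio.write_metadata(self.metadata, outdir / "metadata.tsv")
        ccio.write_taxonomy(self.community.taxonomy, outdir / "taxonomy.tsv")
        self.community.tree.write(
            path=str(outdir / "tree.nwk"), schema="newick", unquoted_underscores=True
        )
        ccio.write_fasta(self.references, outdir / "refs.fasta")
        if self.queries:
            ccio.write_fasta(self.queries, outdir / "queries.fasta")
        truth = pd.DataFrame(
            {
                "otu_id": self.community.otu_ids,
                "culturable": self.truth.culturable.to_numpy(),
                "lineage_id": [
                    x if x is not None else "" for x in self.truth.lineage_id
                ],
            }
        )
        ccio.write_report(truth, outdir / "truth.tsv")
        if self.truth.chimeras is not None:
            ccio.write_report(self.truth.chimeras, outdir / "chimera_truth.tsv")


def generate_dataset(config: SimulationConfig) -> Dataset:
    """Generate the full fixture set from one seed.

    The chimera screening database holds the culturable species only —
    mirroring a reference collection of previously cultured isolates —
    and chimeric queries take their 3' parent from species missing from
    that database, the situation in which a split-end screen is
    informative.
    """
    rng = np.random.default_rng(config.seed)
    community = generate_community(config, rng)
    table, metadata = simulate_cultures(community, config, rng)
    sequences = generate_sequences(community, config, rng)
    culturable = community.truth.culturable
    db_idx = [i for i, o in enumerate(community.otu_ids) if culturable[o]]
    out_idx = [i for i, o in enumerate(community.otu_ids) if not culturable[o]]
    references = [sequences[i] for i in db_idx]
    if config.chimera_rate > 0 and out_idx:
        queries, chim_truth = generate_chimeras(
            sequences,
            config.chimera_rate,
            rng,
            n_queries=config.n_chimera_queries,
            noise=config.chimera_noise,
            five_prime_pool=db_idx,
            three_prime_pool=out_idx,
        )
    else:
        queries, chim_truth = generate_chimeras(
            sequences,
            config.chimera_rate,
            rng,
            n_queries=config.n_chimera_queries,
            noise=config.chimera_noise,
        )
    community.truth.chimeras = chim_truth
    return Dataset(config, community, table, metadata, references, queries, sequences)
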