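# Methods

## Threshold-based culturability calling

The pipeline's central inference is deliberately simple: relative
abundance within a sample is the only signal, and one threshold governs
both steps.

* **Selection.** OTU *o* is a common community member if its relative
  abundance reaches the selection threshold (default 0.001) in at least
  one inoculum sample. Restricting growth analysis to selected OTUs
  avoids calling absence of growth for species the inocula barely
  contained.
* **Growth.** A selected OTU grows in vitro if it reaches the growth
  threshold (default 0.001) in at least one culture sample.

The 0.001 default is not arbitrary: cultured bacterial mass is harvested
from plates (or dilution-matched broths) carrying on the order of 1000
colonies, so a single colony contributes about 0.1 % of the sequenced
community. `detection_limit(colony_count)` exposes this rationale as
1/colony_count.

Both comparisons are inclusive (≥) by default. Source descriptions of
such screens use "more than" and "at least" interchangeably, so the
strict reading (>) is available via `inclusive=False`; at realistic
depths the two differ only when a count sits exactly on the threshold.

Growth calls pool culture samples across experiments by default: a screen
asks whether *any* tested condition supported growth. Because inocula
differ between experiments, the stricter `scope="same_experiment"`
restricts an OTU's eligible cultures to experiments whose inoculum
actually contained it (abundance > 0). With deep sequencing the two
scopes rarely disagree; the option exists because the pooled reading
credits an OTU with growth in an experiment it may never have entered.

Percentages in the phylum summary are rounded half-up to two decimals
(decimal arithmetic, not binary float rounding), so 74/175 → 42.29 and
53/115 → 46.09. Ties in the best-condition assignment and in all rankings
break lexicographically; every output is deterministic under re-runs.

## Rank–culturability curve

Selected OTUs are ranked by their maximal inoculum relative abundance
(descending, ties lexicographic by OTU id); the curve value at rank *k*
is the fraction of non-growing OTUs among the top *k*. Its endpoint is
the overall non-growing fraction, and a declining-abundance community
typically shows the curve rising with *k*: rare members fail culture more
often, partly because a rare OTU can miss the 0.1 % detection limit even
when it grows.

## Media selectivity

Family-level resolution is used throughout because enrichment effects in
culture screens are reported and interpreted at family rank. OTUs without
a family annotation are pooled into `unassigned_<deepest annotated
taxon>` bins so that rank-truncated lineages remain visible rather than
vanishing into a single "unassigned" mass.

Divergence of a cultured community is measured against **its own
experiment's inoculum** only. Inocula from different donor birds differ
substantially; comparing a culture to another experiment's inoculum would
conflate donor and medium effects.

The distance is abundance-weighted Bray–Curtis on proportions,
d(i,j) = 1 − Σₖ min(pₖᵢ, pₖⱼ) — computed via
`scipy.spatial.distance.pdist(..., "braycurtis")`, which reduces to this
form when columns sum to one. The choice of metric is an assumption, not
a constraint inherited from the data; presence/absence variants would
weight rare OTUs far more heavily.

PCoA is classical metric scaling: eigendecomposition of −½·J·D²·J with J
the centering matrix, axes ordered by descending eigenvalue and scaled by
√λ. Negative eigenvalues (possible for non-Euclidean distances such as
Bray–Curtis) are truncated to zero for coordinates and reported
separately. On Euclidean input distances the embedding reproduces the
distances to numerical precision (tested to < 1e-8); scikit-bio's `pcoa`
serves as an independent cross-check in the test suite only.

## Culture-resistant lineages

A lineage is a **maximal** clade whose tip count is ≥ `min_size`
(default 4) and whose growing fraction is ≤ `max_growing_fraction`
(default 0). A post-order pass counts tips and growing tips per node; a
pre-order pass reports qualifying nodes and skips their subtrees, so
reported lineages are disjoint by construction.

Defaults encode two judgements. Purity (fraction 0) reflects that
convincing culture-resistant lineages are entirely non-growing; the
fraction is tunable for noisier data. `min_size=4` suppresses singletons
and pairs: an isolated non-growing OTU is as likely a rare species that
missed the detection limit as a genuinely unculturable one, whereas a
whole clade of non-growers points to shared, unmet growth requirements.
There is no canonical quantitative rule for "resistant lineage" — the
knobs are documented as implementation-defined.

Tips present in the tree but absent from the abundance table are treated
as **reference-only**: previously obtained pure-culture isolates merged
into the phylogeny. They count as growing (they are culturable by
construction), which makes them breakers of non-growing clades — exactly
their role. In the full pipeline the tree is first restricted to selected
OTUs plus reference tips, mirroring how such trees are actually built
(from the common OTUs' sequences, not all of them).

## Split-end chimera screen

A PCR chimera splices the 5′ part of one template onto the 3′ part of
another. Against a reference database that contains one parent's species
but not the other's, the query's two 80-nt ends behave very differently:
one matches a known taxon near-perfectly, the other matches only
distantly. The screen therefore calls a query chimeric when

1. the best references of the two ends carry different taxa, **and**
2. max(identity₅′, identity₃′) ≥ 97 %, **and**
3. |identity₅′ − identity₃′| ≥ 8 points.

Rule 2 anchors one end to a known sequence; rule 3 separates the
split-end signature (e.g. 100 vs 86.6 → gap 13.4) from genuinely novel
sequences whose two ends are comparably and only moderately similar to
database entries (≈90 vs ≈90 → gap ≈0). Both thresholds are configurable.

The aligner is a semi-global dynamic program: the query segment aligns
end-to-end, reference overhangs are free; match +1, mismatch −1, linear
gap −2; both strands of every reference are searched. Identity is
100 × matches / aligned columns over the segment's aligned span,
counting internal gap columns. Co-optimal alignments are resolved
deterministically (leftmost end point; diagonal over reference-gap over
segment-gap during traceback), making identity a well-defined function
of the input — a property the tests exploit by comparing against an
independent plain-Python DP and a recursive scorer. A BLAST-style tool
would use different scoring, so absolute identity values are not
comparable to BLAST output; the screen depends only on the contrast
between the two ends, which is robust to the scoring scheme.

Limitation: if **both** parents of a chimera are well represented in the
reference set, both ends match near-perfectly and the identity gap is
~0 — the split-end signature vanishes and the screen cannot fire. This is
inherent to the method, not an implementation defect; such chimeras need
abundance-aware approaches (out of scope here).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with full ground truth.

* **Species abundances**: log-normal(μ=0, σ=2), reproducing a steep
  rank-abundance decline (top species >1 %, long rare tail). Each
  inoculum multiplies the base abundances by log-normal(0, 0.7) noise —
  inter-donor variation — and renormalizes.
* **Design**: 6 inocula and 174 culture conditions by default, allocated
  over experiments in the proportions 60/12/14/40/33/15 and assigned
  supplement categories (non-supplemented, complex/simple substrates,
  carbohydrates, fruit, herbs, antibiotics, miscellaneous) with weights
  proportional to the size of each category's media vocabulary. Default
  read depth is 50,000 per sample, near a realistic median coverage.
* **Unculturability**: planted as contiguous clades (defaults 11, 11 and
  32 species — two rank-truncated novel "Clostridiales families" and one
  deep Bacteroidetes lineage with mostly phylum-only annotation, the
  largest clade taking the deep pattern), plus scattered unculturable
  singletons up to `frac_unculturable`. The default fraction 0.18 covers
  the clades exactly; at finite depth the *observed* non-growing fraction
  is higher because rare culturable species miss the detection limit —
  an emergent property, not planted truth.
* **Tree**: random sequential coalescence over background species, with
  each unculturable clade (itself a random subtree) grafted directly
  above an *anchor* — one of the most abundant background species.
  Anchoring guarantees monophyly and keeps neighbouring clades separated
  even in trees later restricted to common OTUs; clade members' base
  abundances are drawn from the upper tail with a floor of 7× the
  community median, making every planted lineage "common" and hence
  selectable, as befits lineages identifiable across multiple inocula.
* **Cultures**: expected proportions = inoculum expectation × culturable
  flag × family-by-category multiplier, renormalized; counts are
  multinomial at the configured depth. Unculturable species have expected
  culture abundance exactly zero, so growth-call specificity on planted
  truth is structurally 100 % — the corresponding test verifies the
  pipeline plumbing, not a statistical accident. Default multipliers
  plant the kinds of selectivity such screens report (saccharide/fruit
  media → Lactobacillaceae, antibiotics → Erysipelotrichaceae, bile-salt
  "miscellaneous" media → Veillonellaceae and Enterobacteriaceae, plain
  YCF media → Desulfovibrionaceae, complex substrates → Prevotellaceae).
* **Chimera benchmark**: the screening database contains the culturable
  species only — a reference collection of cultured isolates — and
  planted splices take their 3′ parent from non-database species, the
  regime in which a split-end screen is informative (see the limitation
  above). Non-chimeric queries are database sequences with 2 %
  independent substitution noise; breakpoints are uniform at least 80 nt
  from both ends. Reference sequences are independent random 250-mers,
  so any two "parents" are far more than 10 % divergent.
* **Determinism**: one `numpy.random.Generator` seeded from the config
  drives every draw; identical configs yield bit-identical files.

What the generator does **not** emulate: read-level sequencing error and
chimera formation during PCR, compositional correlations between taxa,
phylogenetic signal in the sequences (they are random, so alignment
identities between distinct species are lower than between real 16S
genes), and medium effects below family rank. Passing tests therefore
demonstrate correctness of the inference machinery under the stated
model, not performance on real amplicon data.

## Problem sizes and numerical choices

* Parameter-recovery runs use 300 species, 6 inocula, 40 conditions and
  depth 10⁶ — deep enough that multinomial noise at the 0.1 % threshold
  is negligible (expected ≥1000 reads, σ≈32), which is what makes exact
  clade recovery and 100 % specificity the correct expectation.
* The chimera operating-characteristics benchmark uses 200 queries
  against a ~40-sequence database.
* Proportions are validated to 1e-9; PCoA symmetry to 1e-12; all
  alignment scores are exact integer arithmetic.
* Degenerate inputs fail loudly: zero-depth samples, duplicate ids,
  experiments without an inoculum, empty reference sets, all-unculturable
  communities, and sequences shorter than 40 nt are errors; sequences
  shorter than two end-lengths fall back to half-length ends with a
  warning.
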