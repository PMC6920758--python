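"""Split-end chimera screen against a local reference set.

A PCR chimera splices the 5' part of one template to the 3' part of
another. When the two ends of a query are compared separately against a
reference database, a chimera betrays itself by discordant hits: one end
matches a known taxon nearly perfectly while the other end matches only a
different taxon, and distantly. The screen therefore extracts the terminal
80 nt of each end, aligns each against every reference (both strands), and
calls a query chimeric when

* the two ends' best references carry different taxa, and
* the better end identity is high (>= 97% by default), and
* the identity gap between the ends is large (>= 8 points by default).

Two ends that are comparably and only moderately similar to (even
different) references indicate a genuinely novel sequence, not a chimera.

Alignment is semi-global — the query segment must be aligned end to end,
while reference overhangs are free — with match +1, mismatch -1, gap -2
(linear) scoring. Identity is 100 x matches / aligned columns, counting
internal gap columns, over the segment's aligned span. Ambiguity among
co-optimal alignments is resolved deterministically: leftmost end point,
then diagonal > segment-gap > reference-gap during traceback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MATCH",
    "MISMATCH",
    "GAP",
    "EndHit",
    "ChimeraVerdict",
    "extract_ends",
    "align_identity",
    "best_identity",
    "reference_taxon",
    "chimera_call",
    "screen",
]

MATCH = 1
MISMATCH = -1
GAP = -2

_RC = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class EndHit:
    """Best reference hit for one 80-nt end segment."""

    end: str  # "five_prime" | "three_prime"
    reference_id: str
    identity: float  # percent, [0, 100]
    alignment_length: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity {self.identity} outside [0, 100]")


@dataclass
class ChimeraVerdict:
    """Split-end screening verdict for one query sequence."""

    query_id: str
    hit5: EndHit
    hit3: EndHit
    taxon5: str
    taxon3: str
    same_reference_taxon: bool
    identity_gap: float
    verdict: str  # "chimeric" | "non_chimeric"


def extract_ends(sequence: str, end_length: int = 80) -> tuple[str, str]:
    """First and last ``end_length`` bases of a sequence, original orientation.

    Sequences shorter than twice the end length fall back to half-length
    ends with a warning; sequences shorter than 40 nt are rejected.
    """
    n = len(sequence)
    if n < 40:
        raise ValueError(f"sequence of length {n} too short for a split-end screen")
    if n < 2 * end_length:
        end_length = n // 2
        warnings.warn(
            f"sequence length {n} < 2 x end length; falling back to "
            f"{end_length}-nt ends",
            stacklevel=2,
        )
    return sequence[:end_length], sequence[n - end_length :]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def align_identity(segment: str, reference: str) -> tuple[float, int, int]:
    """Semi-global alignment of ``segment`` within ``reference``.

    Reference end overhangs are gap-free; the segment is aligned in full.
    Returns (percent identity over the aligned span, aligned columns,
    alignment score). Deterministic under co-optimal ties.
    """
    s = _encode(segment)
    r = _encode(reference)
    n, m = len(s), len(r)
    if n == 0 or m == 0:
        raise ValueError("empty sequence in alignment")
    F = np.empty((n + 1, m + 1), dtype=np.int32)
    F[0, :] = 0  # leading reference overhang is free
    col_pen = GAP * np.arange(0, m + 1, dtype=np.int32)  # note GAP < 0
    twoj = -col_pen  # +|GAP| * j, used in the running-max trick
    for i in range(1, n + 1):
        sub = np.where(r == s[i - 1], MATCH, MISMATCH).astype(np.int32)
        a = np.empty(m + 1, dtype=np.int32)
        a[0] = GAP * i  # leading gaps in the reference are penalized
        a[1:] = np.maximum(F[i - 1, :-1] + sub, F[i - 1, 1:] + GAP)
        # resolve the horizontal (segment-gap) chain:
        # F[i, j] = max_{k <= j} a[k] + GAP * (j - k)
        F[i, :] = np.maximum.accumulate(a + twoj) - twoj
    j = int(np.argmax(F[n, :]))  # leftmost best end point
    score = int(F[n, j])
    # traceback; preference: diagonal > segment consumes (ref gap) > ref consumes
    i = n
    matches = columns = 0
    while i > 0:
        here = F[i, j]
        if j > 0 and here == F[i - 1, j - 1] + (MATCH if s[i - 1] == r[j - 1] else MISMATCH):
            matches += int(s[i - 1] == r[j - 1])
            columns += 1
            i -= 1
            j -= 1
        elif here == F[i - 1, j] + GAP:
            columns += 1
            i -= 1
        elif j > 0 and here == F[i, j - 1] + GAP:
            columns += 1
            j -= 1
        else:  # pragma: no cover - would indicate a DP defect
            raise RuntimeError("alignment traceback failed")
    identity = 100.0 * matches / columns if columns else 0.0
    return identity, columns, score


def best_identity(
    segment: str, references: list[SeqRecord], end: str = "five_prime"
) -> EndHit:
    """Best reference hit for a segment, over both strands of every reference.

    Hits are ranked by identity; ties go to the lexicographically smallest
    reference id, then to the forward strand.
    """
    if not references:
        raise ValueError("empty reference set")
    best: EndHit | None = None
    for rec in sorted(references, key=lambda r: r.id):
        for strand, ref_seq in (("+", str(rec.seq)), ("-", reverse_complement(str(rec.seq)))):
            identity, columns, _ = align_identity(segment, ref_seq)
            if best is None or identity > best.identity:
                best = EndHit(end, rec.id, identity, columns, strand)
    assert best is not None
    return best


def reference_taxon(record: SeqRecord) -> str:
    """Taxon of a reference: the genus token from its FASTA description
    (first word after the id), falling back to the record id."""
    tokens = record.description.split()
    if len(tokens) >= 2:
        return tokens[1]
    return record.id


def chimera_call(
    query: SeqRecord,
    references: list[SeqRecord],
    min_high_identity: float = 97.0,
    min_gap: float = 8.0,
    end_length: int = 80,
) -> ChimeraVerdict:
    """Screen one query: chimeric iff the two ends' best hits carry
    different taxa, the better end is highly similar, and the identity gap
    is large."""
    five, three = extract_ends(str(query.seq), end_length=end_length)
    hit5 = best_identity(five, references, end="five_prime")
    hit3 = best_identity(three, references, end="three_prime")
    taxa = {rec.id: reference_taxon(rec) for rec in references}
    taxon5, taxon3 = taxa[hit5.reference_id], taxa[hit3.reference_id]
    same_taxon = taxon5 == taxon3
    gap = abs(hit5.identity - hit3.identity)
    chimeric = (
        not same_taxon
        and max(hit5.identity, hit3.identity) >= min_high_identity
        and gap >= min_gap
    )
    return ChimeraVerdict(
        query_id=query.id,
        hit5=hit5,
        hit3=hit3,
        taxon5=taxon5,
        taxon3=taxon3,
        same_reference_taxon=same_taxon,
        identity_gap=gap,
        verdict="chimeric" if chimeric else "non_chimeric",
    )


def screen(
    queries: list[SeqRecord],
    references: list[SeqRecord],
    min_high_identity: float = 97.0,
    min_gap: float = 8.0,
    end_length: int = 80,
) -> pd.DataFrame:
    """Screen a batch of queries; one verdict row per query."""
    rows = []
    for query in queries:
        v = chimera_call(
            query,
            references,
            min_high_identity=min_high_identity,
            min_gap=min_gap,
            end_length=end_length,
        )
        rows.append(
            {
                "query_id": v.query_id,
                "ref5": v.hit5.reference_id,
                "identity5": round(v.hit5.identity, 2),
                "taxon5": v.taxon5,
                "ref3": v.hit3.reference_id,
                "identity3": round(v.hit3.identity, 2),
                "taxon3": v.taxon3,
                "same_reference_taxon": v.same_reference_taxon,
                "identity_gap": round(v.identity_gap, 2),
                "verdict": v.verdict,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "query_id",
            "ref5",
            "identity5",
            "taxon5",
            "ref3",
            "identity3",
            "taxon3",
            "same_reference_taxon",
            "identity_gap",
            "verdict",
        ],
    )
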