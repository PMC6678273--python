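"""The additive gene-scoring rubric: overlap/operon context, length
penalties, score summation, keep/discard verdicts, and coding-gap /
false-positive triage.

Five components are summed per putative gene: number of programs calling
it, coding-potential class (0-3), similarity class (0-4), overlap score
(-4..+1) and length score (-4..0). Totals at or above the keep threshold
(default 3) are kept, at or below the discard threshold (default 0)
discarded, and anything in between is flagged for case-by-case review.
Requiring positive evidence (programs, coding potential, or similarity)
means a long, non-overlapping ORF alone can never reach the keep threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .evidence_model import EvidenceBundle, ProgramCall
from .sequence_core import FORWARD, GenomeSequence, Orf

KEEP = "Keep"
DISCARD = "Discard"
BORDERLINE = "Borderline"

DEFAULT_OVERLAP_BINS = (10, 40, 70, 100)
DEFAULT_LENGTH_BINS = (90, 120, 150, 200)
DEFAULT_OPERON_OVERLAPS = frozenset({1, 4, 8})
DIVERGENT_GAP_BP = 50


@dataclass(frozen=True)
class OverlapContext:
    """How a putative gene collides with its strong-call neighborhood."""

    orf_key: tuple[int, str]
    worst_overlap_bp: int
    operon_overlap: bool
    divergent_deficit_bp: int = 0


@dataclass(frozen=True)
class GeneDecision:
    orf_key: tuple[int, str]
    program_score: int
    coding_score: int
    similarity_score: int
    overlap_score: int
    length_score: int
    total: int
    verdict: str

    def __post_init__(self) -> None:
        expected = (
            self.program_score
            + self.coding_score
            + self.similarity_score
            + self.overlap_score
            + self.length_score
        )
        if self.total != expected:
            raise ValueError("total must equal the sum of the five components")


def overlap_bp(a, b) -> int:
    """Shared bases between two closed intervals (Orf or (left, right))."""
    a_left, a_right = (a.left, a.right) if hasattr(a, "left") else (a[0], a[1])
    b_left, b_right = (b.left, b.right) if hasattr(b, "left") else (b[0], b[1])
    return max(0, min(a_right, b_right) - max(a_left, b_left) + 1)


def _bin_penalty(ov: int, bins: Sequence[int]) -> int:
    """Overlap penalty bins, half-open on the left: [0,10) -> 0, [10,40) -> -1,
    [40,70) -> -2, [70,100) -> -3, [100,inf) -> -4 with the default edges."""
    penalty = 0
    for edge in bins:
        if ov >= edge:
            penalty -= 1
    return penalty


def _is_upstream_operon_junction(orf: Orf, other: Orf, ov: int) -> bool:
    """True when ``other`` is a same-strand neighbor whose stop codon overlaps
    this gene's start region, i.e. other's 3' end intrudes at the 5' end."""
    if other.strand != orf.strand:
        return False
    if orf.strand == FORWARD:
        return other.right < orf.right and other.left < orf.left
    return other.left > orf.left and other.right > orf.right


def divergent_deficit_bp(
    orf: Orf, other: Orf, required_gap: int = DIVERGENT_GAP_BP
) -> int:
    """Shortfall below the required promoter gap for a head-to-head pair.

    A forward gene downstream of a reverse gene needs ``required_gap`` bases
    between the two facing 5' ends; returns how many bases are missing
    (0 when satisfied or when the pair is not head-to-head).
    """
    if orf.strand == other.strand:
        return 0
    fwd, rev = (orf, other) if orf.strand == FORWARD else (other, orf)
    gap = fwd.left - rev.right - 1
    if gap < 0:  # real overlap; handled by the overlap bins instead
        return 0
    return max(0, required_gap - gap)


def score_overlap(
    orf: Orf,
    strong_calls: Sequence[Orf],
    overlap_bins: Sequence[int] = DEFAULT_OVERLAP_BINS,
    operon_overlaps: frozenset = DEFAULT_OPERON_OVERLAPS,
    divergent_gap_bp: int = DIVERGENT_GAP_BP,
) -> tuple[int, OverlapContext]:
    """Overlap component of the rubric, in -4..+1.

    Only collisions with *strong calls* (genes called by both anchor
    programs) are scored; overlap among putative genes in the same coding
    gap contributes nothing. The worst (maximum) overlap across all strong
    calls is binned into a penalty, a head-to-head promoter-gap shortfall is
    binned as if it were overlap, and an exact 1/4/8 bp stop/start overlap
    with a same-strand strong call earns +1 instead of any penalty.
    """
    worst = 0
    deficit = 0
    operon = False
    for other in strong_calls:
        if other.stop_anchor == orf.stop_anchor:
            continue
        ov = overlap_bp(orf, other)
        worst = max(worst, ov)
        deficit = max(deficit, divergent_deficit_bp(orf, other, divergent_gap_bp))
        if ov in operon_overlaps and _is_upstream_operon_junction(orf, other, ov):
            operon = True
    ctx = OverlapContext(
        orf_key=orf.stop_anchor,
        worst_overlap_bp=worst,
        operon_overlap=operon,
        divergent_deficit_bp=deficit,
    )
    if operon:
        return 1, ctx
    return _bin_penalty(max(worst, deficit), overlap_bins), ctx


def score_length(length_bp: int, bins: Sequence[int] = DEFAULT_LENGTH_BINS) -> int:
    """Length component, -4..0; bins half-open on the right:
    (200,inf) -> 0, (150,200] -> -1, (120,150] -> -2, (90,120] -> -3,
    (0,90] -> -4 with the default edges."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    penalty = -len(bins)
    for edge in bins:
        if length_bp > edge:
            penalty += 1
    return penalty


def total_score(
    bundle: EvidenceBundle,
    overlap_score: int,
    length_score: int,
    keep_thresh: int = 3,
    discard_thresh: int = 0,
) -> GeneDecision:
    """Sum the five components and apply the keep/discard thresholds."""
    total = (
        bundle.program_count
        + bundle.coding_class
        + bundle.similarity_class
        + overlap_score
        + length_score
    )
    if total >= keep_thresh:
        verdict = KEEP
    elif total <= discard_thresh:
        verdict = DISCARD
    else:
        verdict = BORDERLINE
    return GeneDecision(
        orf_key=bundle.orf_key,
        program_score=bundle.program_count,
        coding_score=bundle.coding_class,
        similarity_score=bundle.similarity_class,
        overlap_score=overlap_score,
        length_score=length_score,
        total=total,
        verdict=verdict,
    )


def find_coding_gaps(
    genome: GenomeSequence, anchor_calls: Iterable[ProgramCall | Orf]
) -> list[tuple[int, int]]:
    """Maximal intervals of the genome not covered by any anchor-program call.

    Candidate missed genes are the >75 bp ORFs intersecting these gaps.
    """
    L = len(genome)
    intervals = sorted((c.left, c.right) for c in anchor_calls)
    gaps = []
    cursor = 1
    for left, right in intervals:
        if left > cursor:
            gaps.append((cursor, left - 1))
        cursor = max(cursor, right + 1)
    if cursor <= L:
        gaps.append((cursor, L))
    return gaps


def orfs_in_gaps(
    orfs: Iterable[Orf], gaps: Sequence[tuple[int, int]]
) -> list[Orf]:
    """ORFs intersecting at least one coding gap."""
    return [o for o in orfs if any(overlap_bp(o, g) > 0 for g in gaps)]


def triage_potential_false_positives(
    calls: Iterable[ProgramCall],
    short_len_bp: int = 120,
) -> list[tuple[int, str]]:
    """Stop anchors of called genes that warrant full rubric evaluation:
    called by exactly one program, or called by several but with a very
    short extent (< ``short_len_bp``, judged on the longest call)."""
    by_anchor: dict[tuple[int, str], list[ProgramCall]] = {}
    for c in calls:
        by_anchor.setdefault(c.stop_anchor, []).append(c)
    flagged = []
    for anchor, group in sorted(by_anchor.items()):
        n_programs = len({c.program for c in group})
        longest = max(c.right - c.left + 1 for c in group)
        if n_programs == 1 or longest < short_len_bp:
            flagged.append(anchor)
    return flagged
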