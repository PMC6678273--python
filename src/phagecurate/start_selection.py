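"""Ordered start-codon selection.

Six criteria are applied as strict lexicographic filters, in decreasing
order of importance:

1. the start must produce a gene covering all of the coding-potential
   plateau (failures are the first eliminated);
2. starts producing an unusually large overlap (> 100 bp by default) are
   dropped when alternatives exist, and a start forming an operon junction
   (exact 1/4/8 bp stop/start overlap) is preferred over ones that do not;
3. most auto-annotation programs voting for the start;
4. most significant similarity matches aligning at the start;
5. best Shine-Dalgarno score (negative; closer to zero is better) — skipped
   when the surviving starts form operon junctions, for which the SD score
   is irrelevant;
6. tie-break: the longest resulting gene without more than 10 bp overlap.

Overlap/gap arithmetic between a candidate start and the neighboring stop
follows signed-offset bookkeeping: subtract, then add 1 for overlaps and
subtract 1 for gaps, so positive numbers are overlaps and negative gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .evidence_model import CodingPotentialTrack
from .sequence_core import FORWARD, REVERSE, Orf, StartCandidate

LARGE_OVERLAP_THRESH = 100
SD_TIE_TOL = 0.1
TIEBREAK_MAX_OVERLAP = 10
OPERON_OVERLAPS = frozenset({1, 4, 8})


@dataclass(frozen=True)
class PlateauRegion:
    """Maximal high-posterior run inside an ORF (genome coordinates)."""

    strand: str
    frame: int
    left: int
    right: int

    @property
    def five_prime(self) -> int:
        return self.left if self.strand == FORWARD else self.right


@dataclass(frozen=True)
class StartEvidenceRow:
    """Per-candidate evidence feeding the elimination procedure."""

    candidate: StartCandidate
    covers_coding_potential: bool
    overlap_or_gap: int
    operon: bool
    program_votes: int
    similarity_start_matches: int
    sd_score: Optional[float]
    resulting_length_bp: int

    def __post_init__(self) -> None:
        if self.operon and self.overlap_or_gap not in OPERON_OVERLAPS:
            raise ValueError(
                "operon flag requires a stop/start overlap of exactly 1, 4, or 8 bp"
            )


@dataclass
class SelectionResult:
    chosen: StartEvidenceRow
    eliminated: dict[int, str] = field(default_factory=dict)  # coordinate -> rule

    @property
    def coordinate(self) -> int:
        return self.chosen.candidate.coordinate


def coding_plateau(
    track: CodingPotentialTrack, orf: Orf, high_thresh: float = 0.75
) -> Optional[PlateauRegion]:
    """Longest run of positions above ``high_thresh`` in the ORF's frame.

    Ties are broken toward the 5' end of the gene. Returns None when no
    position in the ORF exceeds the threshold.
    """
    vals = track.orf_values(orf) > high_thresh
    if not vals.any():
        return None
    best_len, best_start = 0, -1
    run_start = None
    padded = np.concatenate([vals, [False]])
    for i, v in enumerate(padded):
        if v and run_start is None:
            run_start = i
        elif not v and run_start is not None:
            run_len = i - run_start
            better = run_len > best_len
            if run_len == best_len:
                # 5'-most tie-break: leftmost run forward, rightmost reverse
                better = orf.strand == REVERSE
            if better:
                best_len, best_start = run_len, run_start
            run_start = None
    left = orf.left + best_start
    right = left + best_len - 1
    return PlateauRegion(strand=orf.strand, frame=orf.frame, left=left, right=right)


def covers_all_coding_potential(
    candidate: StartCandidate, plateau: Optional[PlateauRegion]
) -> bool:
    """True when the start lies at or 5' of the plateau's 5' edge (vacuously
    true when there is no plateau)."""
    if plateau is None:
        return True
    if plateau.strand == FORWARD:
        return candidate.coordinate <= plateau.left
    return candidate.coordinate >= plateau.right


def start_overlap_or_gap(
    start_coordinate: int, neighbor_stop_coordinate: int, orientation: str
) -> int:
    """Signed overlap (+) or gap (-) between a candidate start and the stop
    of the adjacent gene: upstream gene for forward genes, downstream gene
    for reverse genes. The raw subtraction is shifted away from zero by one
    (add 1 for overlaps, subtract 1 for gaps), so +1 denotes a 1 bp
    stop/start overlap and there is no zero value."""
    if orientation == FORWARD:
        r = neighbor_stop_coordinate - start_coordinate
    elif orientation == REVERSE:
        r = start_coordinate - neighbor_stop_coordinate
    else:
        raise ValueError(f"orientation must be '+' or '-', got {orientation!r}")
    return r + 1 if r >= 0 else r - 1


@dataclass
class DivergentPairTable:
    """Promoter-room bookkeeping for a head-to-head gene pair.

    ``formula`` holds the published subtraction (forward start - reverse
    start + 50); ``gap5to5`` the plain count of bases between the two facing
    5' ends; ``ok`` whether that gap leaves at least ``required_gap`` bases
    for the two promoters.
    """

    forward_starts: list[int]
    reverse_starts: list[int]
    formula: list[list[int]]
    gap5to5: list[list[int]]
    ok: list[list[bool]]


def divergent_pair_table(
    forward_starts: Sequence[int],
    reverse_starts: Sequence[int],
    required_gap: int = 50,
) -> DivergentPairTable:
    formula = []
    gaps = []
    ok = []
    for f in forward_starts:
        formula.append([f - r + required_gap for r in reverse_starts])
        gaps.append([f - r - 1 for r in reverse_starts])
        ok.append([g >= required_gap for g in gaps[-1]])
    return DivergentPairTable(
        forward_starts=list(forward_starts),
        reverse_starts=list(reverse_starts),
        formula=formula,
        gap5to5=gaps,
        ok=ok,
    )


RULE_COVERAGE = "coding_potential"
RULE_LARGE_OVERLAP = "large_overlap"
RULE_OPERON = "operon"
RULE_VOTES = "program_votes"
RULE_SIMILARITY = "similarity_matches"
RULE_SD = "sd_score"
RULE_LENGTH = "length"
RULE_TIE = "tie"


def select_start(
    rows: Sequence[StartEvidenceRow],
    large_overlap_thresh: int = LARGE_OVERLAP_THRESH,
    sd_tie_tol: float = SD_TIE_TOL,
    tiebreak_max_overlap: int = TIEBREAK_MAX_OVERLAP,
) -> SelectionResult:
    """Run the ordered elimination and return the chosen start plus an
    audit trail naming the rule that eliminated each other candidate."""
    if not rows:
        raise ValueError("select_start requires at least one candidate")
    # deterministic, order-independent working order
    alive = sorted(rows, key=lambda r: r.candidate.coordinate)
    eliminated: dict[int, str] = {}

    def drop(keep_pred, rule: str) -> None:
        nonlocal alive
        kept = [r for r in alive if keep_pred(r)]
        if kept and len(kept) < len(alive):
            for r in alive:
                if r not in kept:
                    eliminated[r.candidate.coordinate] = rule
            alive = kept

    # 1. coding-potential coverage
    drop(lambda r: r.covers_coding_potential, RULE_COVERAGE)
    # 2. unusually large overlap, then operon preference
    drop(lambda r: r.overlap_or_gap <= large_overlap_thresh, RULE_LARGE_OVERLAP)
    if any(r.operon for r in alive):
        drop(lambda r: r.operon, RULE_OPERON)
    # 3. program votes
    best_votes = max(r.program_votes for r in alive)
    drop(lambda r: r.program_votes == best_votes, RULE_VOTES)
    # 4. similarity matches at the start
    best_sim = max(r.similarity_start_matches for r in alive)
    drop(lambda r: r.similarity_start_matches == best_sim, RULE_SIMILARITY)
    # 5. SD score, irrelevant for operon-forming starts; missing scores worst
    if not all(r.operon for r in alive):
        best_sd = max(
            (r.sd_score for r in alive if r.sd_score is not None), default=None
        )
        if best_sd is not None:
            drop(
                lambda r: r.sd_score is not None and r.sd_score >= best_sd - sd_tie_tol,
                RULE_SD,
            )
    # 6. longest resulting gene without excessive overlap
    drop(lambda r: r.overlap_or_gap <= tiebreak_max_overlap, RULE_LENGTH)
    best_len = max(r.resulting_length_bp for r in alive)
    drop(lambda r: r.resulting_length_bp == best_len, RULE_LENGTH)
    # fully tied rows: deterministic 5'-most pick
    winner = alive[0] if alive[0].candidate.orf_key[1] == FORWARD else alive[-1]
    for r in alive:
        if r is not winner:
            eliminated[r.candidate.coordinate] = RULE_TIE
    return SelectionResult(chosen=winner, eliminated=eliminated)


def shortcut_applies(rows: Sequence[StartEvidenceRow], n_programs_called: int) -> bool:
    """Fast path: a single candidate, or the longest-gene candidate chosen
    unanimously by every program that called the gene (shorter starts can
    never score better on coding potential)."""
    if not rows:
        return False
    if len(rows) == 1:
        return True
    if n_programs_called <= 0:
        return False
    longest = max(rows, key=lambda r: r.resulting_length_bp)
    return longest.program_votes == n_programs_called
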