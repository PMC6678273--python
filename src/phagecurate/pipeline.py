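"""End-to-end curation pipeline: enumerate the ORF universe, score every
putative gene with the five-criterion rubric, select starts for kept genes.

All called stops plus every >75 bp ORF intersecting a coding gap are routed
through the rubric ("theoretically all putative genes should be evaluated
this way"); the keep threshold then separates coding from non-coding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .config import DEFAULT_CONFIG, RubricConfig
from .evidence_model import (
    CodingPotentialTrack,
    EvidenceBundle,
    ProgramCall,
    SimilarityMatch,
    classify_coding_potential,
    count_program_calls,
    group_matches_by_orf,
    score_similarity,
)
from .gene_scoring import (
    KEEP,
    GeneDecision,
    find_coding_gaps,
    orfs_in_gaps,
    score_length,
    score_overlap,
    total_score,
)
from .sequence_core import (
    FORWARD,
    GenomeSequence,
    Orf,
    StartCandidate,
    enumerate_start_candidates,
    find_orfs,
)
from .start_selection import (
    SelectionResult,
    StartEvidenceRow,
    coding_plateau,
    covers_all_coding_potential,
    select_start,
    start_overlap_or_gap,
)

logger = logging.getLogger(__name__)

_NO_NEIGHBOR_GAP = -(10**6)  # effectively "no upstream gene": a huge gap


@dataclass(frozen=True)
class PredictedGene:
    left: int
    right: int
    strand: str

    @property
    def five_prime(self) -> int:
        return self.left if self.strand == FORWARD else self.right

    @property
    def three_prime(self) -> int:
        return self.right if self.strand == FORWARD else self.left

    @property
    def stop_anchor(self) -> tuple[int, str]:
        return (self.three_prime, self.strand)


@dataclass
class AnnotationResult:
    universe: list[Orf]
    gaps: list[tuple[int, int]]
    strong_calls: list[ProgramCall]
    decisions: dict[tuple[int, str], GeneDecision] = field(default_factory=dict)
    selections: dict[tuple[int, str], SelectionResult] = field(default_factory=dict)
    predicted: list[PredictedGene] = field(default_factory=list)

    @property
    def kept_anchors(self) -> set[tuple[int, str]]:
        return {k for k, d in self.decisions.items() if d.verdict == KEEP}


def build_strong_calls(
    calls: Sequence[ProgramCall], anchor_programs: Sequence[str]
) -> list[ProgramCall]:
    """Genes called by *all* anchor programs (default: the first two loaded);
    the widest called extent represents each strong gene."""
    anchors_per_program: dict[str, set] = {p: set() for p in anchor_programs}
    for c in calls:
        if c.program in anchors_per_program:
            anchors_per_program[c.program].add(c.stop_anchor)
    if not anchors_per_program:
        return []
    strong_anchors = set.intersection(*anchors_per_program.values())
    best: dict[tuple[int, str], ProgramCall] = {}
    for c in calls:
        if c.program not in anchor_programs or c.stop_anchor not in strong_anchors:
            continue
        prev = best.get(c.stop_anchor)
        if prev is None or (c.right - c.left) > (prev.right - prev.left):
            best[c.stop_anchor] = c
    return sorted(best.values(), key=lambda c: (c.left, c.right))


def _upstream_neighbor_stop(
    orf: Orf, strong_calls: Sequence[ProgramCall]
) -> Optional[int]:
    """3'-end coordinate of the nearest same-strand strong call upstream."""
    if orf.strand == FORWARD:
        cands = [
            c.right
            for c in strong_calls
            if c.strand == FORWARD
            and c.right < orf.right
            and c.stop_anchor != orf.stop_anchor
        ]
        return max(cands) if cands else None
    cands = [
        c.left
        for c in strong_calls
        if c.strand != FORWARD
        and c.left > orf.left
        and c.stop_anchor != orf.stop_anchor
    ]
    return min(cands) if cands else None


def resulting_length_bp(orf: Orf, candidate: StartCandidate) -> int:
    if orf.strand == FORWARD:
        return orf.right - candidate.coordinate + 1
    return candidate.coordinate - orf.left + 1


def build_start_rows(
    orf: Orf,
    genome: GenomeSequence,
    calls: Sequence[ProgramCall],
    track: Optional[CodingPotentialTrack],
    matches: Sequence[SimilarityMatch],
    sd_scores: Optional[Mapping[int, float]] = None,
    strong_calls: Sequence[ProgramCall] = (),
    config: RubricConfig = DEFAULT_CONFIG,
) -> list[StartEvidenceRow]:
    """Assemble the per-candidate evidence table for one kept gene."""
    candidates = enumerate_start_candidates(orf, genome, config.start_codons)
    if not candidates:
        return []
    plateau = (
        coding_plateau(track, orf, config.coding_high_thresh)
        if track is not None
        else None
    )
    neighbor_stop = _upstream_neighbor_stop(orf, strong_calls)
    votes: dict[int, int] = {}
    for c in calls:
        if c.stop_anchor == orf.stop_anchor:
            votes[c.five_prime] = votes.get(c.five_prime, 0) + 1
    sig_matches = [
        m
        for m in matches
        if m.orf_key == orf.stop_anchor
        and m.e_value < config.sim_sig_thresh
        and m.subject_start_offset is not None
    ]
    longest_coord = candidates[0].coordinate
    rows = []
    for cand in candidates:
        offset_codons = abs(cand.coordinate - longest_coord) // 3
        if neighbor_stop is not None:
            ov = start_overlap_or_gap(cand.coordinate, neighbor_stop, orf.strand)
        else:
            ov = _NO_NEIGHBOR_GAP
        rows.append(
            StartEvidenceRow(
                candidate=cand,
                covers_coding_potential=covers_all_coding_potential(cand, plateau),
                overlap_or_gap=ov,
                operon=ov in config.operon_overlaps,
                program_votes=votes.get(cand.coordinate, 0),
                similarity_start_matches=sum(
                    1 for m in sig_matches if m.subject_start_offset == offset_codons
                ),
                sd_score=(sd_scores or {}).get(cand.coordinate),
                resulting_length_bp=resulting_length_bp(orf, cand),
            )
        )
    return rows


def annotate(
    genome: GenomeSequence,
    calls: Sequence[ProgramCall],
    track: Optional[CodingPotentialTrack] = None,
    matches: Sequence[SimilarityMatch] = (),
    sd_scores: Optional[Mapping[int, float]] = None,
    config: RubricConfig = DEFAULT_CONFIG,
) -> AnnotationResult:
    """Run the full curation pipeline and return decisions, start
    selections, and the final predicted gene set."""
    universe = find_orfs(genome, config.min_orf_len_bp, config.start_codons)
    by_anchor = {o.stop_anchor: o for o in universe}

    anchor_programs = [
        p for p in config.anchor_programs if any(c.program == p for c in calls)
    ]
    if len(anchor_programs) < len(config.anchor_programs):
        present = sorted({c.program for c in calls})
        anchor_programs = present[: len(config.anchor_programs)]
        logger.info("anchor programs defaulted to %s", anchor_programs)
    anchor_calls = [c for c in calls if c.program in anchor_programs]
    strong_calls = build_strong_calls(calls, anchor_programs)
    gaps = find_coding_gaps(genome, anchor_calls) if anchor_calls else [(1, len(genome))]

    candidate_anchors: set[tuple[int, str]] = set()
    for c in calls:
        if c.stop_anchor in by_anchor:
            candidate_anchors.add(c.stop_anchor)
        else:
            logger.warning(
                "call %s %s has no ORF in the universe; skipped", c.program, c.stop_anchor
            )
    candidate_anchors.update(o.stop_anchor for o in orfs_in_gaps(universe, gaps))

    grouped_matches = group_matches_by_orf(matches)
    result = AnnotationResult(universe=universe, gaps=gaps, strong_calls=strong_calls)

    for anchor in sorted(candidate_anchors):
        orf = by_anchor[anchor]
        bundle = EvidenceBundle(
            orf_key=anchor,
            program_count=count_program_calls(orf, calls),
            coding_class=(
                classify_coding_potential(
                    track,
                    orf,
                    config.coding_high_thresh,
                    config.coding_sustain_frac,
                    config.coding_low_thresh,
                )
                if track is not None
                else 0
            ),
            similarity_class=score_similarity(
                grouped_matches.get(anchor, []),
                config.sim_sig_thresh,
                config.sim_strong_thresh,
                config.sim_very_strong_thresh,
            ),
            length_bp=orf.length_bp,
        )
        ov_score, _ctx = score_overlap(
            orf,
            strong_calls,
            config.overlap_bins,
            frozenset(config.operon_overlaps),
            config.divergent_gap_bp,
        )
        decision = total_score(
            bundle,
            ov_score,
            score_length(orf.length_bp, config.length_bins),
            config.keep_thresh,
            config.discard_thresh,
        )
        result.decisions[anchor] = decision

    for anchor in sorted(result.kept_anchors):
        orf = by_anchor[anchor]
        rows = build_start_rows(
            orf, genome, calls, track, matches, sd_scores, strong_calls, config
        )
        if not rows:
            logger.warning("kept gene %s has no start candidates; skipped", anchor)
            continue
        sel = select_start(
            rows,
            config.large_overlap_thresh,
            config.sd_tie_tol,
            config.tiebreak_max_overlap,
        )
        result.selections[anchor] = sel
        coord = sel.coordinate
        if orf.strand == FORWARD:
            gene = PredictedGene(left=coord, right=orf.right, strand=orf.strand)
        else:
            gene = PredictedGene(left=orf.left, right=coord, strand=orf.strand)
        result.predicted.append(gene)
    result.predicted.sort(key=lambda g: (g.left, g.right))
    return result


# ---------------------------------------------------------------------------
# tabular views (decision spreadsheet / start spreadsheet)


def decisions_frame(result: AnnotationResult) -> pd.DataFrame:
    """Decision table mirroring the curation spreadsheet layout."""
    by_anchor = {o.stop_anchor: o for o in result.universe}
    rows = []
    for anchor, d in sorted(result.decisions.items()):
        orf = by_anchor[anchor]
        rows.append(
            {
                "reading_frame": f"{'F' if orf.strand == FORWARD else 'R'}{orf.frame}",
                "five_prime": orf.five_prime,
                "three_prime": orf.three_prime,
                "strand": orf.strand,
                "programs": d.program_score,
                "coding_potential": d.coding_score,
                "sequence_similarity": d.similarity_score,
                "overlap": d.overlap_score,
                "length_bp": orf.length_bp,
                "length_score": d.length_score,
                "points": d.total,
                "result": d.verdict,
            }
        )
    return pd.DataFrame(rows)


def starts_frame(result: AnnotationResult) -> pd.DataFrame:
    rows = []
    for anchor, sel in sorted(result.selections.items()):
        chosen = sel.chosen.candidate.coordinate
        rows.append(
            {
                "stop_anchor": anchor[0],
                "strand": anchor[1],
                "chosen_start": chosen,
                "eliminations": ";".join(
                    f"{coord}:{rule}" for coord, rule in sorted(sel.eliminated.items())
                ),
            }
        )
    return pd.DataFrame(rows)
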