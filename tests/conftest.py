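"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own algorithms: the ORF
oracle is a two-pass six-frame scanner, and the start-selection oracle is a
naive rule-by-rule list filter. They exist so the implementation can be
cross-checked rather than trusted.
"""

from __future__ import annotations

import pytest

from phagecurate.sequence_core import (
    DEFAULT_START_CODONS,
    STOP_CODONS,
    GenomeSequence,
    revcomp,
)
from phagecurate.synthetic_fixtures import (
    mock_coding_track,
    mock_program_calls,
    mock_similarity,
    plant_genome,
)


# ---------------------------------------------------------------------------
# independent ORF oracle


def orf_oracle(
    genome: GenomeSequence,
    min_len_bp: int = 76,
    start_codons=DEFAULT_START_CODONS,
) -> set[tuple[str, int, int]]:
    """Brute-force six-frame ORF scan; returns {(strand, left, right)}.

    Two-pass formulation: list all in-frame stop positions first, then for
    each stop search the preceding segment for the 5'-most start codon.
    """
    stops = set(STOP_CODONS)
    starts = set(start_codons)
    L = len(genome.seq)
    found = set()
    for strand, s in (("+", genome.seq), ("-", revcomp(genome.seq))):
        for f in range(3):
            stop_positions = [
                p for p in range(f, L - 2, 3) if s[p : p + 3] in stops
            ]
            prev_end = f - 3
            for stop in stop_positions:
                for p in range(prev_end + 3, stop, 3):
                    if s[p : p + 3] in starts:
                        length = stop + 3 - p
                        if length >= min_len_bp:
                            if strand == "+":
                                found.add(("+", p + 1, stop + 3))
                            else:
                                found.add(("-", L - stop - 2, L - p))
                        break
                prev_end = stop
    return found


# ---------------------------------------------------------------------------
# independent start-selection oracle


def select_start_oracle(
    rows,
    large_overlap_thresh: int = 100,
    sd_tie_tol: float = 0.1,
    tiebreak_max_overlap: int = 10,
):
    """Naive re-statement of the six elimination rules as list filters."""
    alive = list(rows)

    def narrow(subset):
        nonlocal alive
        if subset and len(subset) < len(alive):
            alive = subset

    narrow([r for r in alive if r.covers_coding_potential])
    narrow([r for r in alive if r.overlap_or_gap <= large_overlap_thresh])
    if any(r.operon for r in alive):
        narrow([r for r in alive if r.operon])
    top = max(r.program_votes for r in alive)
    narrow([r for r in alive if r.program_votes == top])
    top = max(r.similarity_start_matches for r in alive)
    narrow([r for r in alive if r.similarity_start_matches == top])
    if not all(r.operon for r in alive):
        with_sd = [r for r in alive if r.sd_score is not None]
        if with_sd:
            best = max(r.sd_score for r in with_sd)
            narrow([r for r in with_sd if r.sd_score >= best - sd_tie_tol])
    narrow([r for r in alive if r.overlap_or_gap <= tiebreak_max_overlap])
    top = max(r.resulting_length_bp for r in alive)
    narrow([r for r in alive if r.resulting_length_bp == top])
    ordered = sorted(alive, key=lambda r: r.candidate.coordinate)
    if ordered[0].candidate.orf_key[1] == "+":
        return ordered[0]
    return ordered[-1]


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def planted():
    """A 20 kb planted genome with operons and a head-to-head pair."""
    return plant_genome(10, 20000, seed=42, operon_fraction=0.3, head_to_head=True)


@pytest.fixture(scope="session")
def clean_evidence(planted):
    """Clean four-program evidence (no noise, no errors) for ``planted``."""
    from phagecurate.sequence_core import find_orfs

    universe = find_orfs(planted.genome)
    calls_by_program = mock_program_calls(
        planted.truth, n_programs=4, seed=42, universe=universe
    )
    calls = [c for group in calls_by_program.values() for c in group]
    track = mock_coding_track(planted.truth, planted.genome, seed=42)
    matches = mock_similarity(planted.truth, seed=42, genome=planted.genome)
    return {
        "universe": universe,
        "calls": calls,
        "calls_by_program": calls_by_program,
        "track": track,
        "matches": matches,
    }
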