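import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagecurate.evidence_model import CodingPotentialTrack
from phagecurate.gene_scoring import overlap_bp
from phagecurate.sequence_core import Orf, StartCandidate
from phagecurate.start_selection import (
    RULE_COVERAGE,
    RULE_LARGE_OVERLAP,
    RULE_VOTES,
    PlateauRegion,
    StartEvidenceRow,
    coding_plateau,
    covers_all_coding_potential,
    divergent_pair_table,
    select_start,
    shortcut_applies,
    start_overlap_or_gap,
)

from conftest import select_start_oracle


def row(
    coord,
    votes=0,
    covers=True,
    overlap=-10,
    sim=0,
    sd=None,
    length=None,
    operon=False,
    stop=2000,
    strand="+",
):
    if length is None:
        length = stop - coord + 1 if strand == "+" else coord + 1
    return StartEvidenceRow(
        candidate=StartCandidate(coord, "ATG", (stop, strand)),
        covers_coding_potential=covers,
        overlap_or_gap=overlap,
        operon=operon,
        program_votes=votes,
        similarity_start_matches=sim,
        sd_score=sd,
        resulting_length_bp=length,
    )


def worked_example_rows():
    """The five-candidate worked example with its printed evidence."""
    return [
        row(442, votes=0, covers=True, overlap=128, sim=0, sd=-5.9),
        row(578, votes=0, covers=True, overlap=-10, sim=1, sd=-5.0),
        row(587, votes=1, covers=True, overlap=-19, sim=4, sd=-6.5),
        row(605, votes=2, covers=True, overlap=-37, sim=2, sd=-4.6),
        row(626, votes=3, covers=False, overlap=-58, sim=1, sd=-3.8),
    ]


class TestWorkedExample:
    def test_chooses_605(self):
        assert select_start(worked_example_rows()).coordinate == 605

    def test_audit_trail(self):
        sel = select_start(worked_example_rows())
        assert sel.eliminated[626] == RULE_COVERAGE
        assert sel.eliminated[442] == RULE_LARGE_OVERLAP
        assert sel.eliminated[578] == RULE_VOTES
        assert sel.eliminated[587] == RULE_VOTES

    def test_votes_outrank_similarity(self):
        # 605 wins over 587 despite 2 vs 4 similarity matches
        sel = select_start(worked_example_rows())
        chosen = sel.chosen
        assert chosen.similarity_start_matches == 2

    def test_permutation_invariant(self):
        rows = worked_example_rows()
        for perm in itertools.permutations(rows):
            assert select_start(list(perm)).coordinate == 605


class TestSelectStart:
    def test_single_candidate_returned(self):
        sel = select_start([row(100, votes=0)])
        assert sel.coordinate == 100 and sel.eliminated == {}

    def test_all_equal_longest_wins(self):
        rows = [row(100), row(200), row(300)]  # longest gene = 5'-most start
        assert select_start(rows).coordinate == 100

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_start([])

    def test_operon_candidate_preferred(self):
        rows = [row(100, votes=5, overlap=-30), row(200, votes=0, overlap=4, operon=True)]
        assert select_start(rows).coordinate == 200

    def test_operon_skips_sd(self):
        # both operon: SD must not decide; falls through to length
        rows = [
            row(100, overlap=1, operon=True, sd=-9.0),
            row(200, overlap=4, operon=True, sd=-1.0),
        ]
        assert select_start(rows).coordinate == 100

    def test_missing_sd_compares_worst(self):
        rows = [row(100, sd=None), row(200, sd=-5.0)]
        assert select_start(rows).coordinate == 200

    def test_sd_ties_within_tolerance_fall_to_length(self):
        rows = [row(100, sd=-5.05), row(200, sd=-5.0)]
        assert select_start(rows).coordinate == 100  # tie -> longer gene

    def test_large_overlap_kept_when_no_alternative(self):
        rows = [row(100, overlap=150), row(200, overlap=200)]
        assert select_start(rows).coordinate == 100

    def test_length_tiebreak_respects_overlap_cap(self):
        # longest candidate overlaps 50 bp; runner-up within 10 bp wins
        rows = [row(100, overlap=50), row(200, overlap=5)]
        assert select_start(rows).coordinate == 200

    def test_reverse_strand_longest_is_largest_coordinate(self):
        rows = [row(900, strand="-", stop=100), row(700, strand="-", stop=100)]
        assert select_start(rows).coordinate == 900


@st.composite
def evidence_rows(draw):
    n = draw(st.integers(1, 6))
    coords = draw(
        st.lists(st.integers(1, 500), min_size=n, max_size=n, unique=True)
    )
    rows = []
    for c in sorted(coords):
        overlap = draw(
            st.one_of(st.sampled_from([1, 4, 8]), st.integers(-200, 150))
        )
        rows.append(
            row(
                c,
                votes=draw(st.integers(0, 8)),
                covers=draw(st.booleans()),
                overlap=overlap,
                sim=draw(st.integers(0, 5)),
                sd=draw(st.one_of(st.none(), st.floats(-12, -0.5))),
                length=2000 - c + 1,
                operon=draw(st.booleans()) if overlap in (1, 4, 8) else False,
            )
        )
    return rows


@settings(max_examples=200, deadline=None)
@given(evidence_rows())
def test_property_matches_bruteforce_oracle(rows):
    assert select_start(rows).chosen is select_start_oracle(rows)


@settings(max_examples=50, deadline=None)
@given(evidence_rows(), st.randoms())
def test_property_permutation_invariance(rows, rnd):
    shuffled = list(rows)
    rnd.shuffle(shuffled)
    assert select_start(shuffled).coordinate == select_start(rows).coordinate


@settings(max_examples=50, deadline=None)
@given(evidence_rows())
def test_property_chosen_covers_plateau_when_any_does(rows):
    if any(r.covers_coding_potential for r in rows):
        assert select_start(rows).chosen.covers_coding_potential


class TestCodingPlateau:
    def orf(self):
        return Orf("+", 1, 99, 1)

    def track(self, values):
        v = np.zeros((6, len(values)))
        v[0, :] = values
        return CodingPotentialTrack(v)

    def test_constant_high_whole_orf(self):
        p = coding_plateau(self.track([0.9] * 99), self.orf())
        assert (p.left, p.right) == (1, 99)

    def test_all_zero_none(self):
        assert coding_plateau(self.track([0.0] * 99), self.orf()) is None

    def test_longer_run_wins(self):
        vals = [0.0] * 99
        vals[10:20] = [0.9] * 10
        vals[40:70] = [0.9] * 30
        p = coding_plateau(self.track(vals), self.orf())
        assert (p.left, p.right) == (41, 70)

    def test_tie_broken_five_prime_most(self):
        vals = [0.0] * 99
        vals[10:20] = [0.9] * 10
        vals[40:50] = [0.9] * 10
        p = coding_plateau(self.track(vals), self.orf())
        assert (p.left, p.right) == (11, 20)

    def test_tie_reverse_five_prime_is_rightmost(self):
        vals = [0.0] * 99
        vals[10:20] = [0.9] * 10
        vals[40:50] = [0.9] * 10
        v = np.zeros((6, 99))
        v[3, :] = vals
        p = coding_plateau(CodingPotentialTrack(v), Orf("-", 1, 99, 1))
        assert (p.left, p.right) == (41, 50)

    def test_matches_bruteforce_runs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            vals = (rng.random(99) > 0.6) * 0.9
            p = coding_plateau(self.track(vals), self.orf())
            # brute force over all (i, j) runs
            best = None
            mask = vals > 0.75
            for i in range(99):
                for j in range(i, 99):
                    if mask[i : j + 1].all():
                        ln = j - i + 1
                        if best is None or ln > best[0]:
                            best = (ln, i, j)
            if best is None:
                assert p is None
            else:
                assert (p.left, p.right) == (best[1] + 1, best[2] + 1)


class TestCoversAllCodingPotential:
    def test_no_plateau_vacuously_true(self):
        c = StartCandidate(50, "ATG", (99, "+"))
        assert covers_all_coding_potential(c, None)

    def test_forward_upstream_of_plateau(self):
        plateau = PlateauRegion("+", 1, 30, 60)
        assert covers_all_coding_potential(StartCandidate(30, "ATG", (99, "+")), plateau)
        assert covers_all_coding_potential(StartCandidate(10, "ATG", (99, "+")), plateau)
        assert not covers_all_coding_potential(StartCandidate(31, "ATG", (99, "+")), plateau)

    def test_reverse_upstream_is_numerically_larger(self):
        plateau = PlateauRegion("-", 1, 30, 60)
        assert covers_all_coding_potential(StartCandidate(60, "ATG", (1, "-")), plateau)
        assert covers_all_coding_potential(StartCandidate(80, "ATG", (1, "-")), plateau)
        assert not covers_all_coding_potential(StartCandidate(59, "ATG", (1, "-")), plateau)


class TestStartOverlapOrGap:
    def test_forward_overlap(self):
        assert start_overlap_or_gap(998, 1000, "+") == 3

    def test_forward_one_bp_operon(self):
        assert start_overlap_or_gap(1000, 1000, "+") == 1

    def test_forward_gap(self):
        assert start_overlap_or_gap(1010, 1000, "+") == -11

    def test_reverse_overlap(self):
        assert start_overlap_or_gap(1002, 1000, "-") == 3

    def test_worked_example_candidate_442(self):
        assert start_overlap_or_gap(442, 569, "+") == 128

    def test_overlap_agrees_with_interval_arithmetic(self):
        # cross-module consistency for all overlap cases
        stop = 1000
        for start in range(980, 1001):
            signed = start_overlap_or_gap(start, stop, "+")
            shared = overlap_bp((start, 1200), (800, stop))
            assert signed == shared

    def test_bad_orientation(self):
        with pytest.raises(ValueError):
            start_overlap_or_gap(1, 2, "x")


class TestDivergentPairTable:
    def test_printed_formula_and_geometric_gap(self):
        t = divergent_pair_table([1000], [900])
        assert t.formula[0][0] == 150
        assert t.gap5to5[0][0] == 99
        assert t.ok[0][0]

    def test_boundary_gap_exactly_50_ok(self):
        t = divergent_pair_table([951], [900])
        assert t.gap5to5[0][0] == 50 and t.ok[0][0]

    def test_overlapping_five_prime_ends_violate(self):
        t = divergent_pair_table([890], [900])
        assert t.gap5to5[0][0] < 0 and not t.ok[0][0]

    def test_matrix_shape(self):
        t = divergent_pair_table([100, 200], [50, 60, 70])
        assert len(t.formula) == 2 and len(t.formula[0]) == 3


class TestShortcut:
    def test_single_candidate(self):
        assert shortcut_applies([row(100)], n_programs_called=0)

    def test_longest_voted_by_all(self):
        rows = [row(100, votes=8), row(200, votes=0)]
        assert shortcut_applies(rows, n_programs_called=8)

    def test_votes_split(self):
        rows = [row(100, votes=3), row(200, votes=5)]
        assert not shortcut_applies(rows, n_programs_called=8)

    def test_no_programs_called(self):
        rows = [row(100), row(200)]
        assert not shortcut_applies(rows, n_programs_called=0)
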