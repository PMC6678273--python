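"""Planted-gene genome simulator and mock evidence generators.

Every stage of the curation pipeline is testable offline: genomes carry
known coding genes (with operon junctions and a head-to-head pair on
request), and the mock generators emit program-call tables, a six-frame
coding-potential track, similarity matches and SD scores shaped exactly
like the real inputs.

All randomness flows from one integer seed through named substreams, so
each mock is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .evidence_model import (
    CodingPotentialTrack,
    N_FRAMES,
    ProgramCall,
    SimilarityMatch,
)
from .evaluation import ReferenceAnnotation, ReferenceGene
from .sequence_core import (
    DEFAULT_START_CODONS,
    FORWARD,
    REVERSE,
    GenomeSequence,
    Orf,
    enumerate_start_candidates,
    revcomp,
)

_SUBSTREAMS = {
    "layout": 11,
    "coding": 12,
    "intergenic": 13,
    "calls": 14,
    "track": 15,
    "similarity": 16,
}

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"

#: 61 sense codons in a fixed order
_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)

# non-stop codons whose first base is A (safe fillers inside operon junctions)
_A_CODONS = tuple(c for c in _SENSE_CODONS if c[0] == "A")


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _SUBSTREAMS[stream]])


def _codon_probs(strength: float) -> np.ndarray:
    """Interpolate between uniform (0) and a fixed skewed distribution (1)."""
    strength = float(np.clip(strength, 0.0, 1.0))
    n = len(_SENSE_CODONS)
    biased = np.exp(np.linspace(0.0, 2.5, n))
    biased /= biased.sum()
    uniform = np.full(n, 1.0 / n)
    p = (1 - strength) * uniform + strength * biased
    return p / p.sum()


@dataclass(frozen=True)
class PlantedGene:
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

    @property
    def length_bp(self) -> int:
        return self.right - self.left + 1

    def frame_row(self, genome_length: int) -> int:
        """Row index into the six-frame track (0-2 forward, 3-5 reverse);
        matches the frame convention of find_orfs."""
        if self.strand == FORWARD:
            return (self.left - 1) % 3
        return 3 + (genome_length - self.right) % 3


@dataclass
class PlantedGenome:
    genome: GenomeSequence
    truth: list[PlantedGene]

    def reference(self) -> ReferenceAnnotation:
        return ReferenceAnnotation(
            genes=[ReferenceGene(g.left, g.right, g.strand) for g in self.truth]
        )

    def truth_anchors(self) -> set[tuple[int, str]]:
        return {g.stop_anchor for g in self.truth}


def _coding_sequence(
    n_codons: int,
    rng: np.random.Generator,
    probs: np.ndarray,
    forced: Optional[dict[int, str]] = None,
) -> str:
    """ATG + (n_codons - 2) sense codons + TGA; ``forced`` pins interior
    codons by index (0 = the start codon)."""
    codons = ["ATG"]
    idx = rng.choice(len(_SENSE_CODONS), size=max(0, n_codons - 2), p=probs)
    codons.extend(_SENSE_CODONS[i] for i in idx)
    codons.append("TGA")
    if forced:
        for i, c in forced.items():
            codons[i] = c
    return "".join(codons)


def plant_genome(
    n_genes: int,
    length_bp: int,
    seed: int,
    codon_bias_strength: float = 1.0,
    intergenic_model: str = "uniform",
    operon_fraction: float = 0.0,
    head_to_head: bool = False,
    reverse_fraction: float = 0.3,
    gene_codons_range: tuple[int, int] = (100, 280),
    gap_range: tuple[int, int] = (30, 120),
    genome_id: str = "planted",
) -> PlantedGenome:
    """Generate a genome with ``n_genes`` planted coding genes.

    Operon junctions (exact 1/4/8 bp stop/start overlaps) are created
    between consecutive forward genes at ``operon_fraction``; with
    ``head_to_head`` the first two genes form a divergent pair with a 60 bp
    promoter gap. Raises on infeasible packing.
    """
    if intergenic_model != "uniform":
        raise ValueError(f"unknown intergenic model {intergenic_model!r}")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    layout_rng = _rng(seed, "layout")
    coding_rng = _rng(seed, "coding")
    inter_rng = _rng(seed, "intergenic")
    probs = _codon_probs(codon_bias_strength)

    arr = np.full(length_bp, -1, dtype=np.int8)  # -1 = unwritten

    def write(pos1: int, seq: str) -> None:
        if pos1 < 1 or pos1 + len(seq) - 1 > length_bp:
            raise ValueError(
                f"infeasible packing: gene extent [{pos1},{pos1 + len(seq) - 1}] "
                f"outside genome of length {length_bp}"
            )
        arr[pos1 - 1 : pos1 - 1 + len(seq)] = [_BASES.index(b) for b in seq]

    truth: list[PlantedGene] = []
    eff_reverse = 0.0 if operon_fraction >= 1.0 else reverse_fraction
    pos = 1 + int(layout_rng.integers(40, 140))
    prev: Optional[PlantedGene] = None

    for i in range(n_genes):
        n_codons = int(layout_rng.integers(*gene_codons_range))
        operon = (
            prev is not None
            and prev.strand == FORWARD
            and layout_rng.random() < operon_fraction
        )
        if head_to_head and i == 0:
            strand, operon = REVERSE, False
        elif head_to_head and i == 1:
            strand, operon = FORWARD, False
        elif operon:
            strand = FORWARD
        else:
            strand = REVERSE if layout_rng.random() < eff_reverse else FORWARD

        if operon:
            overlap = int(layout_rng.choice([1, 4, 8]))
            left = prev.right - overlap + 1
            forced: dict[int, str] = {}
            if overlap == 1:
                # prev stop must end in A; rewrite it to TGA
                write(prev.right - 2, "TGA")
            elif overlap == 4:
                # prev stop becomes TGA via our own T,G,A bases; keep prev's
                # penultimate codon stop-free once its last base turns to A
                write(prev.right - 5, "GCA")
                forced[1] = _A_CODONS[int(coding_rng.integers(len(_A_CODONS)))]
            else:  # 8
                forced[1] = "AAT"
                forced[2] = "GAA"
            cds = _coding_sequence(n_codons, coding_rng, probs, forced)
            write(left, cds)
            gene = PlantedGene(left=left, right=left + len(cds) - 1, strand=FORWARD)
        else:
            if head_to_head and i == 1:
                gap = 60
            else:
                gap = int(layout_rng.integers(*gap_range))
            left = pos + gap
            cds = _coding_sequence(n_codons, coding_rng, probs)
            if strand == FORWARD:
                write(left, cds)
            else:
                write(left, revcomp(cds))
            gene = PlantedGene(left=left, right=left + len(cds) - 1, strand=strand)
        truth.append(gene)
        prev = gene
        pos = gene.right

    # intergenic fill
    (unwritten,) = np.nonzero(arr < 0)
    arr[unwritten] = inter_rng.integers(0, 4, size=unwritten.size)
    seq = "".join(_BASES[b] for b in arr)
    return PlantedGenome(genome=GenomeSequence(id=genome_id, seq=seq), truth=truth)


_DEFAULT_PROGRAMS = (
    "glimmer",
    "genemark",
    "prodigal",
    "phanotate",
    "genemark_s",
    "heuristic_genemark",
    "genemark_s2",
    "genemark_hmm",
)


def mock_program_calls(
    truth: Sequence[PlantedGene],
    n_programs: int,
    fn_rate: float = 0.0,
    fp_rate: float = 0.0,
    start_error_rate: float = 0.0,
    seed: int = 0,
    universe: Optional[Sequence[Orf]] = None,
    program_names: Optional[Sequence[str]] = None,
) -> dict[str, list[ProgramCall]]:
    """Per-pseudo-program gene calls: truth genes dropped at ``fn_rate``,
    spurious non-coding ORFs (sampled from ``universe``) added at
    ``fp_rate``, starts shifted downstream at ``start_error_rate``."""
    if program_names is None:
        program_names = _DEFAULT_PROGRAMS[:n_programs]
    if len(program_names) != n_programs:
        raise ValueError("program_names length must equal n_programs")
    rng = _rng(seed, "calls")
    truth_anchors = {g.stop_anchor for g in truth}
    noncoding = (
        [o for o in universe if o.stop_anchor not in truth_anchors]
        if universe is not None
        else []
    )
    out: dict[str, list[ProgramCall]] = {}
    for program in program_names:
        calls = []
        for g in truth:
            if rng.random() < fn_rate:
                continue
            left, right = g.left, g.right
            if start_error_rate > 0 and rng.random() < start_error_rate:
                shift = 3 * int(rng.integers(1, 5))
                if g.length_bp - shift >= 60:
                    if g.strand == FORWARD:
                        left += shift
                    else:
                        right -= shift
            calls.append(ProgramCall(program, left, right, g.strand))
        for o in noncoding:
            if rng.random() < fp_rate:
                calls.append(ProgramCall(program, o.left, o.right, o.strand))
        out[program] = calls
    return out


def mock_coding_track(
    truth: Sequence[PlantedGene],
    genome: GenomeSequence,
    high_level: float = 0.9,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline: float = 0.02,
    profiles: Optional[dict[tuple[int, str], str]] = None,
) -> CodingPotentialTrack:
    """Six-frame posterior track: ~``high_level`` inside each gene's own
    frame, ~0 elsewhere. Per-gene ``profiles`` override the default
    "sustained" shape with "spike" (high, not sustained), "low"
    (sustained at 0.4) or "none"."""
    L = len(genome)
    rng = _rng(seed, "track")
    values = np.full((N_FRAMES, L), baseline)
    for g in truth:
        profile = (profiles or {}).get(g.stop_anchor, "sustained")
        row = g.frame_row(L)
        sl = slice(g.left - 1, g.right)
        if profile == "sustained":
            values[row, sl] = high_level
        elif profile == "spike":
            mid = (g.left + g.right) // 2
            values[row, sl] = baseline
            values[row, mid - 5 : mid + 4] = high_level
        elif profile == "low":
            values[row, sl] = 0.4
        elif profile == "none":
            values[row, sl] = baseline
        else:
            raise ValueError(f"unknown coding profile {profile!r}")
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return CodingPotentialTrack(np.clip(values, 0.0, 1.0))


def mock_similarity(
    truth: Sequence[PlantedGene],
    hit_rate: float = 1.0,
    evalue_sampler: Optional[Callable[[np.random.Generator], float]] = None,
    known_function_rate: float = 0.0,
    seed: int = 0,
    n_matches: int = 2,
    genome: Optional[GenomeSequence] = None,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
) -> list[SimilarityMatch]:
    """Similarity matches for planted genes.

    ``subject_start_offset`` is expressed in codons from the ORF's 5'-most
    permitted start; when ``genome`` is supplied the offset points at the
    planted (true) start, otherwise 0 is used.
    """
    rng = _rng(seed, "similarity")
    if evalue_sampler is None:
        evalue_sampler = lambda r: 10.0 ** (-float(r.uniform(15, 60)))  # noqa: E731
    matches = []
    for g in truth:
        if rng.random() >= hit_rate:
            continue
        offset = 0
        if genome is not None:
            orf = _truth_orf(g, genome)
            cands = enumerate_start_candidates(orf, genome, start_codons)
            coords = [c.coordinate for c in cands]
            if g.five_prime in coords:
                longest = coords[0]
                offset = abs(g.five_prime - longest) // 3
        for _ in range(n_matches):
            matches.append(
                SimilarityMatch(
                    orf_key=g.stop_anchor,
                    e_value=float(evalue_sampler(rng)),
                    known_function=bool(rng.random() < known_function_rate),
                    subject_start_offset=offset,
                )
            )
    return matches


def _truth_orf(g: PlantedGene, genome: GenomeSequence) -> Orf:
    if g.strand == FORWARD:
        frame = (g.left - 1) % 3 + 1
    else:
        frame = (len(genome) - g.right) % 3 + 1
    return Orf(strand=g.strand, left=g.left, right=g.right, frame=frame)
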