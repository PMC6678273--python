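"""Genome representation, ORF enumeration, start-codon candidates, FASTA I/O.

Coordinates are 1-based and fully inclusive throughout (GenBank convention).
An ORF is a stop-to-stop frame segment reported from its 5'-most permitted
start codon through its stop codon; the stop codon counts toward the length.
Each ORF is uniquely identified within a genome by its *stop anchor*: the
(3'-end coordinate, strand) pair, which is stable no matter which start
codon is eventually chosen.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FORWARD = "+"
REVERSE = "-"

DEFAULT_START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

_VALID_BASES = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A single-replicon nucleotide sequence restricted to the ACGT alphabet."""

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"genome {self.id!r} is empty")
        object.__setattr__(self, "seq", self.seq.upper())
        for pos, base in enumerate(self.seq, start=1):
            if base not in _VALID_BASES:
                raise ValueError(
                    f"genome {self.id!r}: invalid base {base!r} at position {pos} "
                    "(only A, C, G, T are accepted)"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "GenomeSequence":
        return GenomeSequence(id=self.id, seq=revcomp(self.seq), circular=self.circular)


@dataclass(frozen=True)
class Orf:
    """A candidate gene interval on one strand, stop codon included.

    ``left``/``right`` are the 1-based inclusive genome coordinates of the
    leftmost/rightmost base. ``frame`` is 1..3 per strand, derived from the
    position of the 5'-most base on the coding strand.
    """

    strand: str
    left: int
    right: int
    frame: int

    def __post_init__(self) -> None:
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if (self.right - self.left + 1) % 3 != 0:
            raise ValueError(
                f"ORF span [{self.left},{self.right}] is not a whole number of codons"
            )

    @property
    def length_bp(self) -> int:
        return self.right - self.left + 1

    @property
    def five_prime(self) -> int:
        return self.left if self.strand == FORWARD else self.right

    @property
    def three_prime(self) -> int:
        return self.right if self.strand == FORWARD else self.left

    @property
    def stop_anchor(self) -> tuple[int, str]:
        return (self.three_prime, self.strand)


@dataclass(frozen=True)
class StartCandidate:
    """One in-frame start codon for an ORF.

    ``coordinate`` is the genome position of the first (5'-most) base of the
    codon; for reverse-strand genes this is the numerically largest base.
    """

    coordinate: int
    codon: str
    orf_key: tuple[int, str]


def _scan_coding_strand(
    seq: str,
    start_codons: frozenset,
    stop_codons: frozenset,
) -> list[tuple[int, int, int]]:
    """Single-pass ORF scan of one coding strand.

    Returns (start0, stop_end0, frame) triples in 0-based coding-strand
    coordinates, where start0 is the 5'-most permitted start codon since the
    previous in-frame stop and stop_end0 the last base of the stop codon.
    """
    out = []
    n = len(seq)
    for off in range(3):
        first_start = -1
        for p in range(off, n - 2, 3):
            codon = seq[p : p + 3]
            if codon in stop_codons:
                if first_start >= 0:
                    out.append((first_start, p + 2, off + 1))
                first_start = -1
            elif first_start < 0 and codon in start_codons:
                first_start = p
    return out


def find_orfs(
    genome: GenomeSequence,
    min_len_bp: int = 76,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
    stop_codons: Sequence[str] = STOP_CODONS,
) -> list[Orf]:
    """Enumerate ORFs of length >= ``min_len_bp`` on both strands.

    One ORF per stop anchor; the reported extent runs from the 5'-most
    permitted start codon through the stop codon inclusive. Results are
    sorted by left coordinate, then strand.
    """
    if min_len_bp < 1:
        raise ValueError("min_len_bp must be >= 1")
    starts = frozenset(c.upper() for c in start_codons)
    stops = frozenset(c.upper() for c in stop_codons)
    L = len(genome)

    if genome.circular:
        # Scan the doubled sequence and deduplicate by stop anchor modulo L.
        # Origin-spanning ORFs keep an unwrapped extent (right may exceed L).
        double = 2 * L
        dedup: dict[tuple[int, str], Orf] = {}
        for strand, seq in ((FORWARD, genome.seq * 2), (REVERSE, revcomp(genome.seq) * 2)):
            for s0, e0, frame in _scan_coding_strand(seq, starts, stops):
                length = e0 - s0 + 1
                if length < min_len_bp or length > L:
                    continue
                if strand == FORWARD:
                    left, right = s0 + 1, e0 + 1
                else:
                    left, right = double - e0, double - s0
                if left > L:
                    left -= L
                    right -= L
                orf = Orf(strand=strand, left=left, right=right, frame=frame)
                anchor = (((orf.three_prime - 1) % L) + 1, strand)
                prev = dedup.get(anchor)
                if prev is None or orf.length_bp > prev.length_bp:
                    dedup[anchor] = orf
        result = list(dedup.values())
    else:
        result = []
        for strand, seq in ((FORWARD, genome.seq), (REVERSE, revcomp(genome.seq))):
            for s0, e0, frame in _scan_coding_strand(seq, starts, stops):
                length = e0 - s0 + 1
                if length < min_len_bp:
                    continue
                if strand == FORWARD:
                    left, right = s0 + 1, e0 + 1
                else:
                    left, right = L - e0, L - s0
                result.append(Orf(strand=strand, left=left, right=right, frame=frame))
    result.sort(key=lambda o: (o.left, o.right, o.strand))
    return result


def enumerate_start_candidates(
    orf: Orf,
    genome: GenomeSequence,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
    stop_codons: Sequence[str] = STOP_CODONS,
) -> list[StartCandidate]:
    """All in-frame permitted start codons for ``orf``, ordered 5' to 3'.

    Candidates lie strictly between the previous in-frame stop (exclusive)
    and the ORF's own stop codon (exclusive), so the first candidate yields
    the longest possible gene.
    """
    starts = frozenset(c.upper() for c in start_codons)
    stops = frozenset(c.upper() for c in stop_codons)
    L = len(genome)
    seq = genome.seq if orf.strand == FORWARD else revcomp(genome.seq)
    if orf.strand == FORWARD:
        stop0 = orf.right - 3  # 0-based coding coord of stop codon first base
    else:
        stop0 = L - (orf.left + 2)
    if seq[stop0 : stop0 + 3] not in stops:
        raise ValueError(f"ORF at {orf.stop_anchor} does not end in a stop codon")
    found0 = []
    p = stop0 - 3
    while p >= 0:
        codon = seq[p : p + 3]
        if codon in stops:
            break
        if codon in starts:
            found0.append((p, codon))
        p -= 3
    found0.reverse()  # ascending coding coordinate == 5' to 3'
    out = []
    for c0, codon in found0:
        coord = c0 + 1 if orf.strand == FORWARD else L - c0
        out.append(StartCandidate(coordinate=coord, codon=codon, orf_key=orf.stop_anchor))
    return out


def random_genome(length_bp: int, seed: int, genome_id: str = "random") -> GenomeSequence:
    """An i.i.d. uniform ACGT sequence; identical seed, identical sequence."""
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    rng = np.random.default_rng(seed)
    bases = rng.integers(0, 4, size=length_bp)
    seq = "".join(np.array(list("ACGT"))[bases])
    return GenomeSequence(id=genome_id, seq=seq)


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a single-record FASTA file (phage genomes are single replicons)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ValueError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise ValueError(
            f"{path}: expected a single record, found {len(records)}"
        )
    rec = records[0]
    return GenomeSequence(id=rec.id, seq=str(rec.seq))


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    rec = SeqRecord(Seq(genome.seq), id=genome.id, description="")
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")
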