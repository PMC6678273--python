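"""Ingest and normalize per-ORF evidence: program calls, coding potential,
sequence similarity.

Gene identity for evidence aggregation is the stop anchor (3'-end coordinate
plus strand): gene callers broadly agree on stop codons while disagreeing on
starts, so start coordinates never enter gene identity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_core import FORWARD, REVERSE, Orf

logger = logging.getLogger(__name__)

#: frame row layout for the six-frame track: rows 0-2 forward frames 1-3,
#: rows 3-5 reverse frames 1-3.
N_FRAMES = 6


@dataclass(frozen=True)
class ProgramCall:
    """One gene call emitted by one auto-annotation program."""

    program: str
    left: int
    right: int
    strand: str

    def __post_init__(self) -> None:
        if not self.program:
            raise ValueError("program label must be non-empty")
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        if self.right <= self.left:
            raise ValueError(
                f"call {self.program} [{self.left},{self.right}]: right must exceed left"
            )

    @property
    def three_prime(self) -> int:
        return self.right if self.strand == FORWARD else self.left

    @property
    def five_prime(self) -> int:
        return self.left if self.strand == FORWARD else self.right

    @property
    def stop_anchor(self) -> tuple[int, str]:
        return (self.three_prime, self.strand)


class CodingPotentialTrack:
    """Per-position, per-frame posterior coding probabilities in [0, 1].

    Stored as a (6, L) array; rows 0-2 are forward frames 1-3 and rows 3-5
    reverse frames 1-3, positions are 1-based on the genome axis.
    """

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != N_FRAMES:
            raise ValueError("track must be a (6, L) array")
        if np.any((values < 0) | (values > 1)):
            raise ValueError("posterior values must lie in [0, 1]")
        self.values = values

    def __len__(self) -> int:
        return self.values.shape[1]

    def frame_row(self, orf: Orf) -> int:
        return orf.frame - 1 if orf.strand == FORWARD else 3 + orf.frame - 1

    def orf_values(self, orf: Orf) -> np.ndarray:
        """Posterior values over the ORF's own frame and extent."""
        if orf.right > len(self):
            raise ValueError(
                f"track length {len(self)} does not cover ORF ending at {orf.right}"
            )
        return self.values[self.frame_row(orf), orf.left - 1 : orf.right]

    @classmethod
    def from_tsv(cls, path: str | Path, genome_length: int) -> "CodingPotentialTrack":
        """Load a (position, frame_code, posterior) TSV; frame_code is 1-6."""
        df = pd.read_csv(path, sep="\t", comment="#")
        df.columns = [c.lower() for c in df.columns]
        values = np.zeros((N_FRAMES, genome_length))
        pos = df["position"].to_numpy(dtype=int)
        frames = df["frame_code"].to_numpy(dtype=int)
        post = df["posterior"].to_numpy(dtype=float)
        if np.any((pos < 1) | (pos > genome_length)):
            raise ValueError(f"{path}: position outside genome of length {genome_length}")
        if np.any((frames < 1) | (frames > N_FRAMES)):
            raise ValueError(f"{path}: frame_code must be 1..6")
        values[frames - 1, pos - 1] = post
        return cls(values)

    def to_tsv(self, path: str | Path, sparse: bool = True) -> None:
        rows = []
        for f in range(N_FRAMES):
            (idx,) = np.nonzero(self.values[f] > 0) if sparse else (np.arange(len(self)),)
            for i in idx:
                rows.append((i + 1, f + 1, self.values[f, i]))
        pd.DataFrame(rows, columns=["position", "frame_code", "posterior"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class SimilarityMatch:
    """A protein similarity hit for one ORF (identified by its stop anchor).

    ``subject_start_offset`` is the in-frame codon offset, measured from the
    ORF's 5'-most permitted start, at which the subject's first residue
    aligns; it is used during start selection and may be absent (None).
    """

    orf_key: tuple[int, str]
    e_value: float
    known_function: bool = False
    subject_start_offset: int | None = None

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"negative E-value {self.e_value}")


@dataclass
class EvidenceBundle:
    """Normalized per-ORF evidence feeding the gene-scoring rubric."""

    orf_key: tuple[int, str]
    program_count: int
    coding_class: int
    similarity_class: int
    length_bp: int
    start_votes: dict[int, int] = field(default_factory=dict)
    start_similarity_matches: dict[int, int] = field(default_factory=dict)
    sd_scores: dict[int, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# loading


def _strand_symbol(raw: str) -> str:
    s = str(raw).strip()
    if s in (FORWARD, "F", "f", "forward", "1"):
        return FORWARD
    if s in (REVERSE, "R", "r", "reverse", "-1"):
        return REVERSE
    raise ValueError(f"unknown strand symbol {raw!r}")


def load_program_calls(
    paths: Mapping[str, str | Path],
    fmt: str = "tsv",
    genome_length: int | None = None,
) -> list[ProgramCall]:
    """Load per-program call files keyed by program label.

    TSV columns: program, left, right, strand (the in-file program column,
    when present, must agree with the label). GFF3 inputs take the label
    from the mapping key. Coordinates are normalized to 1-based inclusive
    with left < right regardless of strand; duplicate (program, stop anchor)
    pairs are collapsed to one call.
    """
    calls: list[ProgramCall] = []
    for program, path in paths.items():
        if fmt == "tsv":
            calls.extend(_calls_from_tsv(program, path))
        elif fmt == "gff3":
            calls.extend(_calls_from_gff3(program, path))
        else:
            raise ValueError(f"unknown call format {fmt!r}")
    if genome_length is not None:
        for c in calls:
            if c.left < 1 or c.right > genome_length:
                raise ValueError(
                    f"call {c.program} [{c.left},{c.right}] outside genome "
                    f"of length {genome_length}"
                )
    seen: dict[tuple[str, tuple[int, str]], ProgramCall] = {}
    for c in calls:
        seen.setdefault((c.program, c.stop_anchor), c)
    out = list(seen.values())
    if not out:
        warnings.warn("no program calls loaded", stacklevel=2)
    return out


def _calls_from_tsv(program: str, path: str | Path) -> list[ProgramCall]:
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        warnings.warn(f"{path}: empty call file for {program}", stacklevel=3)
        return []
    df.columns = [c.lower() for c in df.columns]
    out = []
    for row in df.itertuples(index=False):
        label = getattr(row, "program", program)
        if label != program:
            raise ValueError(
                f"{path}: program column {label!r} conflicts with label {program!r}"
            )
        out.append(
            ProgramCall(
                program=program,
                left=int(row.left),
                right=int(row.right),
                strand=_strand_symbol(row.strand),
            )
        )
    return out


def _calls_from_gff3(program: str, path: str | Path) -> list[ProgramCall]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", force=True
    )
    out = []
    for feat in db.all_features():
        if feat.featuretype not in ("CDS", "gene"):
            continue
        out.append(
            ProgramCall(
                program=program,
                left=feat.start,
                right=feat.end,
                strand=_strand_symbol(feat.strand),
            )
        )
    if not out:
        warnings.warn(f"{path}: empty call file for {program}", stacklevel=3)
    return out


def write_calls_tsv(calls: Iterable[ProgramCall], path: str | Path) -> None:
    pd.DataFrame(
        [(c.program, c.left, c.right, c.strand) for c in calls],
        columns=["program", "left", "right", "strand"],
    ).to_csv(path, sep="\t", index=False)


def load_similarity_tsv(path: str | Path) -> list[SimilarityMatch]:
    """Load similarity matches from a TSV with columns stop_anchor, strand,
    e_value, known_function, subject_start_offset (blank offset allowed)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    out = []
    for row in df.itertuples(index=False):
        offset = getattr(row, "subject_start_offset", None)
        if offset is not None and pd.isna(offset):
            offset = None
        out.append(
            SimilarityMatch(
                orf_key=(int(row.stop_anchor), _strand_symbol(row.strand)),
                e_value=float(row.e_value),
                known_function=bool(row.known_function),
                subject_start_offset=None if offset is None else int(offset),
            )
        )
    return out


def write_similarity_tsv(matches: Iterable[SimilarityMatch], path: str | Path) -> None:
    pd.DataFrame(
        [
            (m.orf_key[0], m.orf_key[1], m.e_value, m.known_function, m.subject_start_offset)
            for m in matches
        ],
        columns=["stop_anchor", "strand", "e_value", "known_function", "subject_start_offset"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# scoring


def count_program_calls(orf: Orf, calls: Iterable[ProgramCall]) -> int:
    """Number of distinct programs calling a gene with this ORF's stop anchor."""
    return len({c.program for c in calls if c.stop_anchor == orf.stop_anchor})


def classify_coding_potential(
    track: CodingPotentialTrack,
    orf: Orf,
    high_thresh: float = 0.75,
    sustain_frac: float = 0.5,
    low_thresh: float = 0.25,
) -> int:
    """Score an ORF's coding potential 0-3.

    3: posterior exceeds ``high_thresh`` somewhere in the ORF's frame and
    does so over more than ``sustain_frac`` of its positions (high and
    sustained); 2: high but not sustained; 1: not high, but more than
    ``sustain_frac`` of positions exceed ``low_thresh`` (low but sustained);
    0: neither.
    """
    vals = track.orf_values(orf)
    high = vals > high_thresh
    if high.any():
        return 3 if high.mean() > sustain_frac else 2
    if (vals > low_thresh).mean() > sustain_frac:
        return 1
    return 0


def score_similarity(
    matches: Sequence[SimilarityMatch],
    sig_thresh: float = 1e-10,
    strong_thresh: float = 1e-20,
    very_strong_thresh: float = 1e-50,
) -> int:
    """Score similarity evidence 0-4.

    Base points from the best (smallest) E-value: 3 below 1e-50, 2 below
    1e-20, 1 below the significance threshold, else 0. One bonus point if
    any significant match is to a protein of known function; the bonus
    never applies without at least one significant match. Capped at 4.
    """
    if not matches:
        return 0
    best = min(m.e_value for m in matches)
    if best < very_strong_thresh:
        base = 3
    elif best < strong_thresh:
        base = 2
    elif best < sig_thresh:
        base = 1
    else:
        base = 0
    bonus = int(
        base > 0
        and any(m.known_function and m.e_value < sig_thresh for m in matches)
    )
    return min(base + bonus, 4)


def group_matches_by_orf(
    matches: Iterable[SimilarityMatch],
) -> dict[tuple[int, str], list[SimilarityMatch]]:
    grouped: dict[tuple[int, str], list[SimilarityMatch]] = {}
    for m in matches:
        grouped.setdefault(m.orf_key, []).append(m)
    return grouped
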