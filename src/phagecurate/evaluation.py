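"""Benchmarking predicted annotations against a reference.

Genes are matched by stop anchor, so nested genes with distinct stops are
scored independently and start-codon disagreements do not affect gene-level
counts. The true-negative universe is the set of >75 bp ORFs that are
non-coding in the reference.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .sequence_core import FORWARD, REVERSE, Orf

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceGene:
    left: int
    right: int
    strand: str

    @property
    def three_prime(self) -> int:
        return self.right if self.strand == FORWARD else self.left

    @property
    def five_prime(self) -> int:
        return self.left if self.strand == FORWARD else self.right

    @property
    def stop_anchor(self) -> tuple[int, str]:
        return (self.three_prime, self.strand)


@dataclass
class ReferenceAnnotation:
    genes: list[ReferenceGene]

    def __post_init__(self) -> None:
        anchors = [g.stop_anchor for g in self.genes]
        if len(anchors) != len(set(anchors)):
            raise ValueError("reference annotation has duplicate stop anchors")

    @property
    def stop_anchors(self) -> set[tuple[int, str]]:
        return {g.stop_anchor for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "FN", "TN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class StartAccuracy:
    n_correct: int
    n_long: int
    n_short: int

    @property
    def tp(self) -> int:
        return self.n_correct + self.n_long + self.n_short

    @property
    def percent_correct(self) -> float:
        return percent_correct_starts(self.tp, self.n_long, self.n_short)


def confusion(
    predicted_genes: Iterable,
    reference: ReferenceAnnotation,
    orf_universe: Sequence[Orf],
) -> ConfusionCounts:
    """Gene-level confusion counts over the >75 bp ORF universe.

    ``predicted_genes`` may be Orf/ReferenceGene-like objects or bare stop
    anchors. Reference stops absent from the universe (usually a start-codon
    set mismatch) still count toward TP/FN but are logged.
    """
    pred = {_anchor(p) for p in predicted_genes}
    ref = reference.stop_anchors
    universe = {o.stop_anchor for o in orf_universe}
    missing = ref - universe
    if missing:
        logger.warning(
            "%d reference stop anchors absent from the ORF universe "
            "(start-codon-set mismatch?): %s",
            len(missing),
            sorted(missing)[:5],
        )
    tp = len(pred & ref)
    fp = len(pred - ref)
    fn = len(ref - pred)
    n_noncoding = len(universe - ref)
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=n_noncoding - fp)


def _anchor(obj) -> tuple[int, str]:
    if isinstance(obj, tuple):
        return obj
    return obj.stop_anchor


def sensitivity(c: ConfusionCounts) -> float:
    """100 * TP / (TP + FN)."""
    if c.TP + c.FN == 0:
        raise ZeroDivisionError("sensitivity undefined: TP + FN == 0")
    return 100.0 * c.TP / (c.TP + c.FN)


def specificity(c: ConfusionCounts) -> float:
    """100 * TN / (TN + FP)."""
    if c.TN + c.FP == 0:
        raise ZeroDivisionError("specificity undefined: TN + FP == 0")
    return 100.0 * c.TN / (c.TN + c.FP)


def percent_correct_starts(tp: int, n_long: int, n_short: int) -> float:
    if tp == 0:
        raise ZeroDivisionError("percent correct undefined: no true positives")
    return 100.0 * (tp - n_long - n_short) / tp


def round_half_percent(x: float) -> float:
    """Round to the nearest multiple of 0.5, halves up (presentation only)."""
    return math.floor(x * 2 + 0.5) / 2


def start_accuracy(
    predicted_genes: Sequence,
    reference: ReferenceAnnotation,
) -> StartAccuracy:
    """Start-codon agreement over true-positive genes.

    A TP gene's start is correct when the predicted 5' end equals the
    reference 5' end, called long when the predicted gene extends beyond
    the reference, and called short otherwise.
    """
    ref_by_anchor = {g.stop_anchor: g for g in reference.genes}
    n_correct = n_long = n_short = 0
    for p in predicted_genes:
        ref = ref_by_anchor.get(p.stop_anchor)
        if ref is None:
            continue  # false positive; not scored for starts
        if p.five_prime == ref.five_prime:
            n_correct += 1
        elif (p.right - p.left) > (ref.right - ref.left):
            n_long += 1
        else:
            n_short += 1
    return StartAccuracy(n_correct=n_correct, n_long=n_long, n_short=n_short)


def read_reference(path: str | Path, fmt: str = "genbank") -> ReferenceAnnotation:
    """Parse CDS features from a GenBank flat file or GFF3.

    Compound (join) locations collapse to their outermost coordinates with
    a warning; non-CDS features (tRNA etc.) are ignored.
    """
    if fmt == "genbank":
        genes = _read_genbank_cds(path)
    elif fmt == "gff3":
        genes = _read_gff3_cds(path)
    else:
        raise ValueError(f"unknown reference format {fmt!r}")
    return ReferenceAnnotation(genes=genes)


def _read_genbank_cds(path: str | Path) -> list[ReferenceGene]:
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise ValueError(f"{path}: no GenBank records found")
    genes = []
    for rec in records:
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            if len(feat.location.parts) > 1:
                warnings.warn(
                    f"{path}: compound location for CDS at {feat.location}; "
                    "using outermost coordinates",
                    stacklevel=3,
                )
            left = int(feat.location.start) + 1  # Biopython is 0-based half-open
            right = int(feat.location.end)
            strand = FORWARD if (feat.location.strand or 1) >= 0 else REVERSE
            genes.append(ReferenceGene(left=left, right=right, strand=strand))
    # distinct stop anchors only (a CDS may be annotated twice, e.g. join forms)
    unique: dict[tuple[int, str], ReferenceGene] = {}
    for g in genes:
        unique.setdefault(g.stop_anchor, g)
    return list(unique.values())


def _read_gff3_cds(path: str | Path) -> list[ReferenceGene]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", force=True
    )
    unique: dict[tuple[int, str], ReferenceGene] = {}
    for feat in db.features_of_type("CDS"):
        g = ReferenceGene(
            left=feat.start,
            right=feat.end,
            strand=FORWARD if feat.strand != "-" else REVERSE,
        )
        unique.setdefault(g.stop_anchor, g)
    return list(unique.values())


def write_reference_gff3(
    reference: ReferenceAnnotation, path: str | Path, seqid: str = "genome"
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, g in enumerate(
            sorted(reference.genes, key=lambda g: (g.left, g.right)), start=1
        ):
            fh.write(
                f"{seqid}\tphagecurate\tCDS\t{g.left}\t{g.right}\t.\t{g.strand}\t0\t"
                f"ID=cds{i}\n"
            )
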