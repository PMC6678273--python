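"""Rubric configuration: every threshold and bin edge in one place.

The default profile, named "salisbury-tsourkas-2019", carries the published
defaults; any field can be overridden from YAML. Output files are stamped
with a hash of the effective configuration so downstream readers can tell
which rubric produced them.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path

import yaml

PROFILE_NAME = "salisbury-tsourkas-2019"


@dataclass(frozen=True)
class RubricConfig:
    # ORF enumeration
    min_orf_len_bp: int = 76
    start_codons: tuple[str, ...] = ("ATG", "GTG", "TTG")
    # coding potential classes
    coding_high_thresh: float = 0.75
    coding_sustain_frac: float = 0.5
    coding_low_thresh: float = 0.25
    # similarity classes
    sim_sig_thresh: float = 1e-10
    sim_strong_thresh: float = 1e-20
    sim_very_strong_thresh: float = 1e-50
    # overlap scoring
    overlap_bins: tuple[int, ...] = (10, 40, 70, 100)
    operon_overlaps: tuple[int, ...] = (1, 4, 8)
    divergent_gap_bp: int = 50
    # length scoring
    length_bins: tuple[int, ...] = (90, 120, 150, 200)
    # decision thresholds
    keep_thresh: int = 3
    discard_thresh: int = 0
    triage_short_len_bp: int = 120
    # start selection
    large_overlap_thresh: int = 100
    sd_tie_tol: float = 0.1
    tiebreak_max_overlap: int = 10
    # anchor programs defining strong calls and coding gaps
    anchor_programs: tuple[str, ...] = ("glimmer", "genemark")

    def __post_init__(self) -> None:
        for name in ("overlap_bins", "length_bins"):
            bins = getattr(self, name)
            if list(bins) != sorted(set(bins)):
                raise ValueError(f"{name} must be strictly increasing, got {bins}")
        if self.keep_thresh <= self.discard_thresh:
            raise ValueError("keep_thresh must exceed discard_thresh")
        if not (
            self.sim_very_strong_thresh
            < self.sim_strong_thresh
            < self.sim_sig_thresh
        ):
            raise ValueError("similarity thresholds must be strictly nested")
        if self.min_orf_len_bp < 1:
            raise ValueError("min_orf_len_bp must be >= 1")
        if not self.start_codons:
            raise ValueError("at least one start codon is required")

    def to_dict(self) -> dict:
        d = asdict(self)
        # YAML-friendly: tuples as lists
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(
            {"profile": PROFILE_NAME, **self.to_dict()}, sort_keys=True
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RubricConfig":
        if isinstance(source, Path) or "\n" not in str(source):
            data = yaml.safe_load(Path(source).read_text())
        else:
            data = yaml.safe_load(source)
        data = dict(data or {})
        data.pop("profile", None)
        valid = {f.name for f in fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for f in fields(cls):
            if f.name in data and isinstance(data[f.name], list):
                data[f.name] = tuple(data[f.name])
        return cls(**data)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def with_overrides(self, **kwargs) -> "RubricConfig":
        return replace(self, **kwargs)


DEFAULT_CONFIG = RubricConfig()
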