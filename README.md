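# phagecurate

A deterministic decision engine for manual curation of phage genome
annotations. It turns the judgement calls of curation — is this ORF a real
gene? which start codon is right? — into a reproducible, configurable
rubric:

- **ORF enumeration** on both strands with stop-anchored gene identity
  (genes are identified by their 3' end plus strand, since gene callers
  agree on stops and disagree on starts);
- **five-criterion additive gene scoring**: number of auto-annotation
  programs calling the gene (0–8), coding-potential class (0–3),
  sequence-similarity class (0–4), overlap/operon score (−4 to +1), and
  length score (−4 to 0), with keep (≥ 3) / discard (≤ 0) / borderline
  verdicts;
- **ordered start-codon selection**: six lexicographic criteria —
  coding-potential coverage, overlap/operon context, program votes,
  similarity start matches, Shine-Dalgarno score, resulting length — with a
  full audit trail of which rule eliminated each candidate;
- **benchmarking**: TP/FP/FN/TN, sensitivity, specificity and
  long/short/correct start accuracy against a GenBank or GFF3 reference;
- **synthetic fixtures**: planted-gene genomes (with operon junctions and
  head-to-head pairs) plus mock program calls, coding-potential tracks and
  similarity tables, so the whole pipeline is testable offline.

## CLI

All subcommands live under one entry point:

```bash
# ORF table from a genome
phagecurate find-orfs --fasta G.fa --min-len 76 --starts ATG,GTG,TTG --out orfs.tsv

# uniform-random test sequence
phagecurate random-seq --length 40000 --seed 17 --out rand.fa

# synthetic fixture: genome + reference + calls/ + cp.tsv + sim.tsv
phagecurate simulate --n-genes 10 --length 20000 --seed 7 --out-dir fixtures/

# five-criterion rubric over all putative genes
phagecurate score-genes --fasta G.fa --calls calls/ --track cp.tsv \
    --sim sim.tsv --out decisions.tsv

# ordered start-codon elimination for kept genes
phagecurate select-starts --fasta G.fa --calls calls/ --track cp.tsv \
    --sim sim.tsv --sd sd.tsv --out starts.tsv

# confusion-matrix benchmark against a reference annotation
phagecurate evaluate --predicted predicted.tsv --reference ref.gbk \
    --fasta G.fa --out report.tsv
```

Every output TSV starts with a provenance header
(`# phagecurate <version> config=<hash>`); readers should skip `#` lines.
Exit codes: 0 ok, 1 user error, 2 internal error.

## Configuration

Every threshold and bin edge is a field of `RubricConfig` (profile
`salisbury-tsourkas-2019` carries the published defaults): minimum ORF
length 76 bp; coding-potential thresholds 0.75 / 0.5 / 0.25; similarity
E-value bins 1e-10 / 1e-20 / 1e-50; overlap penalty bins 10/40/70/100 bp;
operon overlaps {1, 4, 8} bp; divergent promoter gap 50 bp; length bins
90/120/150/200 bp; keep/discard thresholds 3/0. Serialize with
`RubricConfig().to_yaml("rubric.yaml")`, pass via `--config`.

## Input formats

- **Genome**: single-record FASTA, ACGT only.
- **Program calls** (`calls/<program>.tsv`): columns
  `program  left  right  strand` (1-based inclusive; strand `+`/`-`,
  `F`/`R` accepted). GFF3 also accepted (`CDS`/`gene` features).
- **Coding-potential track** (`cp.tsv`): `position  frame_code  posterior`
  with frame_code 1–6 (1–3 forward frames, 4–6 reverse) and posterior in
  [0, 1]; omitted positions default to 0.
- **Similarity table** (`sim.tsv`): `stop_anchor  strand  e_value
  known_function  subject_start_offset`. The offset is in codons from the
  ORF's 5'-most permitted start (blank if unknown); a match supports a
  start candidate when the offset points exactly at it.
- **SD scores** (`sd.tsv`): `start_coordinate  sd_score` (negative; closer
  to zero is better).
- **Reference annotation**: GenBank flat file or GFF3; only CDS features
  are used, compound locations collapse to outermost coordinates.

`phagecurate simulate` writes one example of each format.

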