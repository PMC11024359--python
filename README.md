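# rtkclass

Motif-based classification of crustacean receptor tyrosine kinases (RTKs).

`rtkclass` assigns protein sequences to the four RTK classes found in
pancrustacean transcriptomes — insulin receptors (**InsR**), epidermal
growth factor receptors (**EGFR**), fibroblast growth factor receptors
(**FGFR**), and PDGF/VEGF-related receptors (**PVR**) — and to their
subtypes (InsR1–3, EGFR1, FGFR1–3, PVR1/2A/2B) using degenerate consensus
motifs instead of large-scale phylogenetic analysis. It also ships the
supporting machinery: a supervised group-conservation motif discovery
stage, a logo-style residue-proportion exporter, a domain-architecture
consistency checker, and a synthetic protein-family generator used to
benchmark every stage.

## How it works

- **Motif library** (`src/rtkclass/data/motifs.tsv`): degenerate consensus
  patterns (fixed residues plus `x` wildcards) for the class-level InsR
  catalytic-loop decamer `VHRDLAARNC`, the three InsR FN3-region 20-mers,
  the three FGFR catalytic-domain motifs (bounded by `VAVK` … `HRDLA`),
  and the three PVR motifs (containing `HGDLA` … `PxKW`). Universally
  conserved positions are tracked separately from subtype-specific ones.
  The `EGFR1_catalytic` entry is an **artifact-derived fixture** (marked
  `artifact-egfr-fixture-v1`), not a published consensus: no EGFR-specific
  consensus motif is available, so EGFR is called by elimination plus
  positive evidence against this fixture and/or the EGFR architecture.
- **Scanning** (`motif_model`): windows are scored as the fraction of
  fixed positions matched (wildcards are free; `X` never matches). Shared
  kinase landmarks — the Gly-loop `GxGxFG`, the catalytic loop `H[G/R]DLA`,
  and `DFG` — are located with ordering constraints.
- **Classification** (`rtk_classifier`): evidence-ranked class call,
  then subtype by best motif with a score threshold and a margin over the
  runner-up; optional domain annotations demote conflicting calls.
  Confidence tiers: `full`, `partial`, `architecture_only`, `ambiguous`.
- **Discovery** (`motif_discovery`): per-column profiles of a grouped
  alignment, per-group consensus strings at conservation threshold `tau`
  and gap tolerance `gamma`, universal and discriminative positions, and
  per-column residue proportions for logo rendering.
- **Simulation** (`synthetic_data`): seeded generation of labeled families
  with planted motifs, controlled substitution rates at fixed/background
  positions, and optional N-/C-terminal truncation; truth tables record
  every planted offset.

## Command line

```sh
# generate a labeled synthetic benchmark
rtkclass simulate --out-prefix bench --seed 1 --n-per-subtype 100

# classify sequences (TSV report + summary JSON + manifest)
rtkclass classify --fasta bench.fasta --out results.tsv
rtkclass classify --fasta proteins.fasta --domains cdd.tsv \
    --relaxed-catloop --theta-class 0.8 --theta-sub 0.7 --margin 0.02 \
    --out results.tsv

# derive group consensus motifs from a labeled alignment
rtkclass discover --alignment aln.fasta --groups groups.tsv --out consensus.tsv

# per-column residue proportions (for external logo renderers)
rtkclass logo --alignment aln.fasta --out proportions.tsv

# architecture-compatible classes from a domain table
rtkclass check-arch --domains cdd.tsv --out arch.tsv
```

Subcommands accept `--config file.yaml` (flat key/value; unknown keys are
errors; command-line flags win) and write a `*.manifest.json` beside each
output with the merged parameters, seeds, and package version.

`--relaxed-catloop` lets the PVR catalytic-loop glycine position also
accept arginine (`HRDLA`), admitting a known natural variant at the cost
of a less specific PVR test.

### File formats

- **FASTA** (protein; residues `ACDEFGHIKLMNPQRSTVWY` plus `X`; gaps only
  in alignments). Transcriptome-style headers such as
  `GeclaM_EVm001193t2` yield a species code (`GeclaM`); a trailing `*` or
  a `partial` description token marks partial sequences.
- **Groups TSV**: columns `id`, `group`.
- **Domain TSV**: columns `seq_id`, `domain`, `start`, `end` (1-based
  inclusive). Controlled vocabulary: `RECEPTOR_L`, `FURIN_LIKE`, `FN3`,
  `TM`, `TK`, `IG_LIKE`, `CADHERIN`, `GF_IV`; other labels are kept but
  flagged as unknown.

## Layout

```
src/rtkclass/
  alphabet.py        amino-acid alphabet and integer encoding
  sequence_io.py     FASTA / alignment / domain-table I/O
  motif_model.py     degenerate motifs, scanning, landmarks, library
  motif_discovery.py group-conservation consensus discovery
  rtk_classifier.py  class/subtype decision procedure
  synthetic_data.py  seeded benchmark generator
  cli_app.py         click CLI (`rtkclass`)
  data/motifs.tsv    versioned motif library
tests/               pytest suite (unit, property, acceptance)
scripts/acceptance.py
```
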