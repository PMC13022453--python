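# subtel

Telomere and subtelomere rearrangement analysis for telomere-to-telomere
yeast assemblies.

When budding-yeast telomeres lose their protective cap, surviving clones
carry rearrangements that are confined to the chromosome ends: subtelomeric
Y' elements are lost, gained, tandem-amplified or recombined into new
mosaic variants; chromosome arms acquire BIR-like terminal duplications
through homology junctions; occasionally a chromosome circularizes; and
"type-II-like" survivors massively elongate their telomeres, partly by
rolling-circle amplification of excised telomeric circles (t-circles).
`subtel` is a library (plus a thin CLI) for characterizing all of this
from assemblies: it annotates each extremity, catalogs Y' sequence
variants, calls control-vs-survivor rearrangements, detects t-circle
signatures, and measures telomere length distributions from assemblies and
long reads.  A synthetic-genome generator with an exact planted-truth
ledger makes the whole pipeline testable end to end without external data.

## The models in brief

- **Telomere tracts** are degenerate TG₁₋₃ repeats (no `TT`, no `GGGG` on
  the G-strand); tracts are detected by sliding-window *telomericity* (the
  fraction of window 6-mers generable by the grammar, threshold 0.8).
- **Y' catalog.** Detected Y' copies are homopolymer-condensed (runs > 4
  → 4, neutralizing the dominant nanopore error mode) and compared with
  `sim = %identity × alignment_length / alignment_span`, the span adding
  the unaligned flanks of both sequences.  Copies with `sim > 99.9` share
  a variant label; variants are clustered (average linkage on `100 − sim`)
  with the cluster count at the elbow of the silhouette-vs-k curve.
- **Rearrangement calls.** Per extremity, control and survivor label
  strings are aligned by edit distance: unmatched control labels are
  losses, unmatched survivor labels gains, a gained label equal to its
  neighbour is a tandem amplification, and labels absent from the catalog
  are new variants — explained as *mosaics* when perfect > 50 bp matches to
  known elements cover them completely.  Terminal duplications and
  circularizations are called at the sequence level and reported with
  their donor arm and exact junction homology length.
- **T-circles.** Perfect tandem arrays (units ≥ 30 bp) in telomere tracts
  are consolidated (units ≥ 50 bp, ≥ 3 copies) into circle candidates;
  each candidate is matched against every telomere with a
  circular-permutation-aware local aligner (doubled unit; match 1,
  mismatch −1, gap open −1, gap extend −0.9; normalized score > 0.98),
  reporting copy counts and entry *phases*.  Non-specific units are
  discarded, and a unit found in exactly one copy in the control marks its
  locus of origin.

## Worked example

```sh
python examples/01_simulate_control.py
python examples/02_annotate_and_catalog.py
```

prints, for the default synthetic control strain (seed 1):

```
Y' instances detected:    34
extremities with Y':      20
X elements found:         32 / 32
unique sequence variants: 20
clusters (silhouette elbow): 11
  short family: 10 variants, 5279-5590 bp (mean 5414)
  long  family: 10 variants, 6537-6797 bp (mean 6669)
```

i.e. the 34 detected Y' copies sit on 20 of the 32 extremities and
collapse into 20 sequence variants grouped into 11 clusters — the two size
families (~5.2 kb and ~6.7 kb) plus finer subfamily structure.  The other
examples plant rearrangements and recover them
(`03_call_rearrangements.py`), trace a planted t-circle to its control
origin telomere with per-telomere phases (`04_tcircle_signatures.py`), and
measure per-extremity telomere lengths from simulated long reads
(`05_read_telomere_lengths.py`).

The CLI wraps the same functions:

```sh
subtel demo --outdir demo --seed 0
subtel run --control demo/control.fasta \
           --survivor demo/survivor_yas.fasta \
           --survivor demo/survivor_tiil.fasta \
           --yprime-library demo/yprime_library.fasta \
           --x-library demo/x_library.fasta \
           --outdir results_demo --seed 0
```

writing BED annotations, the variant/cluster tables, the similarity
matrix, the event table, circle and tandem-fraction tables, telomere
length summaries and a manifest.  For real data, point `--control` and
`--survivor` at telomere-to-telomere assemblies (e.g. those deposited
under ENA project PRJEB93986) together with a Y'/X element library FASTA.

## Layout

- `src/subtel/` — `io` (FASTA/BED, canonical extremity frames), `grammar`
  (TG₁₋₃ model), `simulate` (synthetic genomes + truth ledger), `annotate`
  (tracts, X/Y' detection, length distributions), `catalog` (condensation,
  similarity, labels, clustering), `rearrange` (event calling +
  statistics), `tcircles` (tandem arrays, circle matching, origins),
  `pipeline` (orchestration), `cli`.
- `docs/methods.md` — models, parameters, design decisions, limitations.
- `examples/` — one short narrative script per capability.
- `tests/` — pytest suite, including exhaustive-oracle and planted-truth
  acceptance tests.
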