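# Methods

`subtel` analyzes telomere and subtelomere rearrangements in budding-yeast
telomere-to-telomere assemblies, comparing one control assembly against one
or more "survivor" assemblies (clones that recovered from transient
telomere uncapping or analogous stress).  Everything is exercised against a
synthetic-genome generator whose output is described exactly by a
planted-truth ledger, so every detector can be scored with no external
data.  This note records the models, the tunable parameters and the design
choices, and what the synthetic tests do and do not show about real data.

## Coordinate model

All coordinates are 0-based half-open.  Each chromosome end is analyzed in
its *canonical frame*: the terminal window read 5'->3' on the G-rich strand
toward the chromosome end, so the telomere always sits at the right edge;
left arms are reverse-complemented into this frame and only I/O converts
back to original chromosome coordinates (BED output).  Arm windows are
clamped to half the chromosome length so the two arm views never overlap —
without the clamp, the opposite arm's elements appear reverse-complemented
inside the frame.  N bases never match in any alignment or exact-match
step.

## Telomere model and tract detection

Yeast telomeres are ~350 bp of degenerate TG(1-3) repeats.  Operationally a
string over {T, G} is telomeric iff it contains neither "TT" nor "GGGG";
that characterization yields an exact 6-mer dictionary.  *Telomericity* of
a window is the fraction of its 6-mers in that dictionary.  Tract
detection slides a 20 bp window (step 1) from the chromosome end, keeps
windows with telomericity >= 0.8, bridges gaps of up to 10 bp, and reports
the maximal terminal run if it is >= 40 bp.  On error-free synthetic
genomes the measured length is within ~20 bp of the planted length; the
threshold/window/bridge values are package defaults chosen for that
accuracy, not measurements of any real tool.

## Element detection

Y' elements are found by aligning a library of known Y' sequences against
each arm with `blastn`, keeping plus-strand local alignments strictly
longer than 200 bp, taking the interval union, and splitting the union
into instances at interstitial telomeric seeds (a >= 30 bp stretch of
telomericity >= 0.8 between alignment blocks).  Instance boundaries are
then trimmed of terminal {T,G}-only runs (capped at 30 bp): alignments can
extend a few bases into the flanking telomeric seeds, and the trim
guarantees that two copies of the same variant always excise with
identical content — without it, near-identical copies can fall below the
99.9 % label threshold purely through boundary noise.  X elements are the
best plus-strand alignment covering >= 60 % of a library X sequence.
An extremity with more than 5 Y' copies, two of which are adjacent and
identical after homopolymer condensation, is flagged `undetermined` and
excluded from comparisons and from all frequency denominators.

## Y' catalog

Nanopore assemblies concentrate residual errors in homopolymers, so Y'
sequences are first condensed: every base run longer than 4 collapsed to
length 4 (idempotent).  Pairwise similarity of condensed sequences is

    sim = %identity * alignment_length / alignment_span

from the best blastn local alignment, where the span adds the unaligned
flanks of *both* sequences to the alignment length; this penalizes length
differences symmetrically and makes sim symmetric.  Gap columns count in
the alignment length; matches exclude gaps.  Two copies share a *label*
(sequence variant) when sim > 99.9; labels are connected components of
that graph (sim > threshold is not transitive, so a component whose
minimum internal similarity dips below the threshold is flagged
`fragile`).

Variants are clustered by agglomerative clustering (average linkage) on
distance = 100 − sim, with silhouette scores computed for k = 2..n−1.  The
cluster count is taken at the *elbow* of the silhouette-vs-k curve,
defined here as the interior local maximum with the highest silhouette
(ties to the smaller k), falling back to the global argmax when the curve
is unimodal.  A raw second-difference maximum was tried first and proved
fragile: on similarity structures with both a family-level split (k = 2)
and a subfamily-level split (k = 11) it latches onto spurious low-k
spikes.  Both the chosen k and the argmax are reported.

## Rearrangement calling

Per extremity, the control and survivor Y' label strings
(centromere->telomere) are aligned by minimum edit distance (match 0,
mismatch 1, indel 1; deterministic traceback).  Unmatched control labels
are losses; unmatched survivor labels are gains; a mismatched pair is
counted as loss + gain and also reported as a substitution; a gained label
identical to its telomere-adjacent neighbour is additionally a tandem
amplification; a gained label absent from the control catalog is a new
variant.  Events are classified non-exclusively (a tandem amplification is
also a gain) and reported in both granularities.

New variants are tested for *mosaicism*: all maximal exact matches longer
than 50 bp against every catalog variant (both orientations) are
enumerated, and a greedy longest-first (leftmost tie-break) interval cover
is built; the sequence is explained iff the cover is complete, and is a
mosaic when >= 2 donors contribute (or one donor in rearranged order).
Greedy cover is checked against exhaustive search in tests.

Terminal duplications: the 15 kb centromere-proximal to the X element is
compared with the control; on any deviation the divergent terminal segment
is walked junction by junction — each junction located by maximal exact
extension from an upstream control anchor, its continuation mapped onto a
donor arm by exact probe search, and the junction homology measured as the
longest exact match spanning the junction.  Nested duplications produce
one event per junction.  Circularization: a chromosome with both telomeres
missing is matched against each control chromosome by anchored maximal
extension against the doubled survivor sequence; a match spanning at least
the full survivor length identifies the fused chromosome, and the excess
of the matched control span over the survivor length is exactly the
homology through which the two arms fused.  Both detectors assume
error-free assemblies (exact matching); they are not designed for raw-read
noise.

## T-circle signatures

Rolling-circle copying of an extrachromosomal telomeric circle leaves a
perfect tandem array whose unit is a rotation of the circle.  The scan
enumerates all maximal perfect tandem arrays with primitive units >= 30 bp
(a periodic unit is reported at the smallest compatible unit length, so
each array appears exactly once); it is validated against an exhaustive
reference scanner.  Units >= 50 bp from arrays of >= 3 copies are circle
candidates; identical or highly similar units (circular-permutation-aware
normalized score > 0.98) are grouped, represented by the unit with the
largest total copy support (ties: longer unit, then lexicographically
smallest rotation), and named `Circle_<unit length>`.

Matching uses Biopython's `PairwiseAligner` (local; match 1, mismatch −1,
gap open −1, gap extend −0.9) of the doubled unit against unit-sized
telomere windows; the normalized score divides the raw score by the unit
length, so a perfect match scores exactly 1.0 and matches require > 0.98.
Windows are pre-screened by shared k-mers sized from the edit budget (a
window above threshold must share an exact stretch of >= (u−e)/(e+1)
bases with the doubled unit), and the reported match start is the local
score maximum, which pins the phase at perfect-array starts.  Contiguous
matches merge into copy counts with the phase of the run start.  A circle
found in more than one copy in any *other* assembly is non-specific and
discarded; exactly one copy in the control marks the locus of origin.
Telomere windows are scanned on the canonical strand only — telomeric
arrays are strand-defined.

Tandem fractions per clone: perfect fraction = union of perfect-array
intervals (units >= 50 bp) over total telomeric bp; the extended fraction
adds single or imperfect circle-unit matches at the same 0.98 threshold.

## Synthetic genomes and the truth ledger

The generator emits 16 chromosomes (random ~60 kb cores) with each arm
built as X element + (interstitial seed + Y')* + terminal TG(1-3) tract.
Defaults mirror a control strain: 34 Y' instances over 20 of 32
extremities (0-6 per end), terminal tracts ~N(350, 35) bp clipped to
250-450, seeds 50-150 bp, X elements ~1.2 kb diverged 8 % per extremity
from a common ancestor (enough divergence to keep read anchors
distinguishable while the ancestor still aligns).  The Y' library holds 20
variants in 11 subfamilies (6 short ~5.2 kb + 5 long ~6.7 kb, graded
lengths in 60 bp steps, subfamily divergence 6 %, within-subfamily 0.1 %);
singleton subfamilies diverge twice as much, modelling the outliers seen
alongside larger variant groups.  The TG(1-3) emitter appends blocks
'T' + 'G'*k with k grown from 1 by coin flips capped at 3; emitted tracts
are grammar-exact, and independently emitted 50 bp windows essentially
never collide, which is what makes circle-unit matching specific.

Planted events: Y' loss/gain/tandem duplication (list edits), mosaic
creation (large chunks of >= 2 donors), heavily mutated novels, telomere
elongation, rolling-circle amplification (50-600 bp units entering at
arbitrary phase), BIR-like terminal duplication and chromosome
circularization.  The latter two act through *homology cassettes* planted
at two control loci; cassette flanking bases are forced to mismatch
between the two copies so the planted junction homology is exact, and the
planter re-locates cassettes by sequence at event time because build-time
coordinates go stale when other events change chromosome lengths.  Planted
circle units must be telomeric *around the circle* (no TT/GGGG across the
wrap junction): a t-circle is a circular telomeric molecule, and a
non-circular unit would break tract detection at every rotation junction.
Excised origin windows are shifted by up to 30 bp to satisfy this.
`calibrated_survivor_plan` draws event counts around survivor-like rates
(~8 losses and ~18 gains per clone concentrated on ~7 extremities).

The ledger records every planted part as sequence; `TruthLedger.verify`
re-extracts each arm from the emitted FASTA and asserts byte equality.
Reads are sampled uniformly (both strands, left-edge overhang allowed so
both ends get full coverage) with configurable substitution and
homopolymer-length errors; the homopolymer error model only emits
perturbations that condensation absorbs exactly (runs >= 5 gain or lose
one base, runs of 4 may only gain), matching the error mode the
condensation step is designed to neutralize.

## Read-based telomere lengths

Each extremity's anchor is the 1 kb immediately centromere-proximal to its
control telomere tract.  A read contributes its terminal tract length when
exactly one anchor matches (edlib, >= 90 % identity, >= 800 bp of anchor)
and its terminal tract abuts that anchor.  Reads matching several anchors
are dropped — conservative and simple, with a known consequence: ends
whose just-proximal sequence is shared (distal Y' copies recur across ends
at > 99 % identity) anchor nothing and stay unmeasured.  On synthetic
data the X-only ends are measurable and their means recover planted
lengths within a few percent at 30x; reads truncated inside the tract bias
means slightly downward (~3 % at 6 kb reads and 350 bp tracts).

## Statistics

Group comparisons follow the conventions of the survivor analyses:
two-sided Mann-Whitney U for per-extremity-class alteration frequencies,
two-sided Student's t for fraction-altered comparisons, two-sided Fisher's
exact for survivor-type proportions; no multiplicity correction.  For
samples with n <= 8 per group the Mann-Whitney p-value is computed by
exhaustive permutation (exact under ties); tests verify it against an
independent full-enumeration oracle, and Fisher against direct
hypergeometric enumeration.  Degenerate inputs (n < 2, all ties) return
NaN rather than raising.

## Problem sizes and determinism

Synthetic genomes are ~1.2 Mb (16 chromosomes x ~75 kb); read-based tests
use an 8-chromosome ~0.5 Mb genome at 30x with 6 kb reads; the tandem-
array oracle suite uses 200 tracts up to 3 kb with the unit-length cap at
600 bp (circle units are 50-600 bp by definition).  All randomness flows
through `numpy.random.default_rng` seeds; identical (config, seed) gives
byte-identical FASTA, and pipeline reruns produce byte-identical tables.

## Limitations

- Detectors for terminal duplication and circularization use exact
  matching and assume polished, error-free assemblies in those regions.
- Read-based lengths are unavailable for extremities without a unique
  subtelomeric anchor (most Y'-bearing ends); the real read-based method
  this stands in for uses a more elaborate assignment.
- The generator does not model assembly collapse of tandem repeats,
  chimeric reads, or signal-level nanopore artifacts; passing planted-truth
  tests demonstrates correctness of the algorithms under the stated error
  models, not robustness to every real-data failure mode.
- The silhouette-elbow cluster count is reported alongside the full
  silhouette profile; on real data the two should be inspected together.
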