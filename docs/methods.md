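# Methods

## The detection model

A stem-loop is modelled as `5'-arm | loop | 3'-arm`, the arms base-paired
into a stem read outward from the loop (step `t = 0` is loop-adjacent).
Admissible structures satisfy:

| constraint | default | unit | notes |
|---|---|---|---|
| stem length | 10–20 | paired positions | the classic annotation range for retroelement 3′ ends |
| loop length | 3–10 | nt | lower bound is not part of the classic settings; 3 is the smallest sterically sensible loop, configurable (the structure encoder additionally requires ≥ 5) |
| mismatches | ≤ 5 | stem positions | substitutions only; N never pairs and always counts as a mismatch inside the stem |
| bulge | ≤ 1 run of ≤ 3 nt per arm | nt | bulged nucleotides are unpaired and excluded from the paired strings |
| pairing | Watson–Crick | — | G·T wobble available behind `allow_wobble`, off by default because mismatch budgets are conventionally defined against WC pairing |

Detection is exhaustive rather than thermodynamic: for every admissible
loop interval the scan scores every stem configuration (stem length, bulge
length and placement on each arm) and keeps one canonical configuration.
The scan is a banded alignment of the left arm against the reverse
complement of the downstream region, vectorized by reducing the local
complementarity matrix to cumulative sums along its 16 shifted diagonals,
so each configuration costs O(1).

Canonicalization (the rules that make the output well-defined and
deterministic):

* **Stems are bounded by pairs.**  The innermost and outermost stem
  positions must be WC matches; a terminal mismatch is read as loop or
  exterior sequence.  This also prunes ~3/4 of candidate loops upfront.
* **Bulges are interior** — flanked by paired positions on both sides; a
  terminal bulge would be indistinguishable from a longer loop.
* **Ranking within a loop** is by total *defects* — mismatches plus bulged
  nucleotides — then longest stem, then least bulge, then lexicographically
  earliest bulge placement.  Defects-first resolves a structural
  degeneracy: a mismatch and a 1×1 internal loop (one bulge per arm at the
  same step) describe the same molecule; they tie on defects and the
  longer-stem mismatch description wins.  A stem-length-first ranking was
  rejected because, under a mismatch budget, it always pads stems with
  terminal mismatches to the maximum length, which is physically
  meaningless and makes planted structures unrecoverable.
* **Nested-structure pruning**: an annotation whose base-pair set is a
  strict subset of another's is suppressed (it is the same stem, trimmed).
  This pruning reranks across loops, so the monotonicity property
  (relaxing budgets never removes a reported loop) holds for the candidate
  stage and is tested with pruning disabled.
* The left/right tie-break order is deliberately fixed and therefore not
  mirror-symmetric; reverse-complement symmetry holds on the
  (loop, stem, mismatches, total bulge) projection.

Terminal selection keeps, per sequence and end, the single hairpin fully
contained in the terminal window (50 nt by default), ranked by longer stem,
fewer mismatches, then proximity to the terminus — one feature vector per
element.

The detector is verified against an independent brute-force partition
enumerator (plain string operations over all arm/loop/bulge partitions) on
hundreds of seeded random sequences; agreement is exact.

## Negative class: dinucleotide shuffling

Negatives are Altschul–Erikson shuffles: build the dinucleotide multigraph,
fix each vertex's last out-edge by sampling a random arborescence toward
the terminal symbol (rejection sampling), permute remaining edges and emit
the Eulerian walk.  Output length, endpoints and all 16 overlapping
dinucleotide counts are conserved exactly; on sequences with exactly two
admissible walks the sampler is empirically uniform (0.5 ± 0.02 over 10⁴
seeds).  Sequences containing N are shuffled over the observed 5-letter
alphabet, preserving N-containing dinucleotide counts.  One shuffle per
positive (balanced classes) is the default; experiments here use two per
positive and rebalance after structural eligibility filtering.

## Feature encodings

*Sequence-based* (80 features): overlapping k-mer counts for k = 2, 3,
each divided by the number of width-k windows (length − k + 1).  Windows
containing N count in the denominator but not the numerator.
Normalization removes length dependence for windows clipped below 50 nt;
tree ensembles are insensitive to the choice either way.

*Structure-based* (134 features): `[stem 90 | loop 20 | bulge 24]`.

* Stem: the 10 loop-proximal nucleotides of the 5′ arm give 9 overlapping
  dinucleotide steps, LS0 (loop-adjacent) … LS8, each mapped (T→U) to 10
  properties of the bundled RNA dinucleotide table.  The 5′ arm is used
  because a single-track convention must be chosen; the choice is recorded
  in the feature names.  Steps containing N are zero-filled.
* Loop: positions LP0–LP4 (the first five, 5′→3′), one-hot over (A,C,G,T);
  loops shorter than 5 nt are ineligible and filtered out *symmetrically*
  in both classes, so the classifier cannot learn the filter itself.
* Bulge: slots LB0–LB2 and RB0–RB2 filled loop-proximal first, zero-padded;
  absent bulges contribute zeros.

The property table (16 dinucleotides × 10 properties) is a bundled,
provenance-annotated transcription of published compilations: helical step
parameters from crystallographic analyses of RNA duplexes, nearest-neighbor
enthalpy/entropy/free energy from optical-melting experiments, and
dinucleoside-phosphate hydrophilicity.  Raw (unscaled) values are used:
random forests are invariant to monotone rescaling.  Thermodynamic columns
are exactly symmetric under reverse complementation, which the tests check.

## Classification experiments

Random forest, 2000 trees by default (experiments in the test suite use
150–1000 trees; at these dataset sizes the AUC difference is well inside
fold-to-fold noise, and the suite stays fast).  Validation is stratified
k-fold (default 5) with a fixed seed: per-fold ROC-AUC and threshold
metrics (accuracy/precision/recall at probability 0.5 — no calibration
procedure is assumed), pooled out-of-fold ROC/PR curves and confusion
matrix, and normalized impurity (Gini) importances from a final all-data
fit, summarized as top-10 lists.  Importance summaries split feature names
`position:property` and tally both margins across experiments.
Cross-application reports the fraction of foreign instances with positive
probability ≥ 0.5.  Everything is a pure function of (data, seed).

## The synthetic generator

Backgrounds are uniform i.i.d. ACGT — deliberately not genome-like, so the
null is clean and chance-hairpin rates are estimable.  A plant embeds
`arm + loop + revcomp(arm)` (optionally mutated and bulged) entirely within
the chosen terminal 50 nt.  Controls: stem length range, loop motif or
length range, mismatch count, bulge sizes, a first-order dinucleotide bias
for arm composition, and the planting end.

Guards that make detector round-trips well-posed:

* flanking guard zones (4 nt each side) drawn from {A,C}, which cannot form
  a WC pair with each other, so the planted stem cannot be extended outward
  even via a bulge;
* random loops resampled until their terminal bases do not pair;
* mismatches and bulges placed at loop-proximal steps 1–8, inside the core
  that a stem_min = 10 detector cannot trim away;
* optional `gc_clamp` (closing C·G pair) and restricted loop/bulge
  alphabets for strict fixtures in which the planted structure is provably
  the unique canonical explanation.

With those guards, mismatch-free and fixed-mismatch plants are recovered
coordinate-exactly; bulged plants are recovered up to equivalent
descriptions of the same structure (a bulge adjacent to an identical base
has no unique coordinate), so the bulge round-trip asserts span equality
and a high exact-match fraction.

What the generator does *not* emulate: poly-A tails, family phylogeny,
genome-like composition, or multi-hairpin 3′ ends.  Passing tests
demonstrate correctness of the machinery and recoverability of planted
signal under these idealized conditions — not performance on real
transposon data, which depends on signal strength in the real sequences.

A note on background rates: under the permissive classic constraints
(5 mismatches, bulges, any loop 3–10) essentially every random 300-mer —
and nearly every random 50-mer window — contains *some* qualifying
hairpin.  This matches the observation that a majority of arbitrary mRNA
3′ ends carry annotatable stem-loops, and it is why discrimination must
come from hairpin *properties*, not hairpin presence.

## Study conditions used by the validation suite and acceptance script

* Planted-signal recovery: 120–150 positives per replicate, 60-nt
  sequences, stems 14–18 bp with an AG/GA-alternating bias (weight 25),
  two shuffles per positive, classes rebalanced after filtering; forests
  of 300–500 trees.  20 seeded replicates in the test suite.  An AG/GA
  bias is used rather than a G+C-content bias because dinucleotide
  shuffling preserves composition: shuffled negatives of GC-rich input
  re-fold into GC-rich stems, whereas the positional consistency of an
  alternating-step signature is destroyed by shuffling and is therefore
  the kind of signal the structure model is meant to detect.
* Null calibration: 500 instances per class of identical uniform 50-mers,
  k-mer features, 5-fold CV, 1000 trees.
* Detector/oracle equivalence: 500 random sequences of length 10–34 —
  short enough that the brute-force enumerator stays exhaustive over every
  bulge placement while covering multiple hairpins per sequence.
* Pipeline determinism: the `pipeline` subcommand run twice with one seed
  must produce byte-identical reports, feature matrices and annotations
  (JSON written with sorted keys, floats serialized with `%.17g`).

## Known limitations

* No thermodynamics: detection is constraint-based, not minimum-free-energy
  folding; multi-branch structures and pseudoknots are out of scope.
* One hairpin per sequence end enters the models, by design.
* The canonical bulge coordinates of a structurally ambiguous bulge are a
  convention (earliest lexicographic placement), not a physical claim.
* The bundled property table is a static transcription; users wanting a
  different property set can supply their own TSV via
  `DinucPropertyTable.from_tsv`.
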