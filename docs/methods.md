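# Methods

## tRNA reference models

A tRNA locus is described by its genomic body (introns included), an optional
5′ leader and 3′ trailer, the isodecoder family (amino acid + anticodon), and
the 0-based position of the anticodon on the intron-removed body. All
coordinates are 0-based half-open internally; sequences are `{A,C,G,T,N}` on
the + strand (minus-strand genes must be reverse-complemented upstream).

**Mature reference.** Built by the standard processing convention: remove the
annotated intron, append the non-templated `CCA`. The cloverleaf anatomy is
annotated on the mature coordinate system. The anticodon loop is the 7-nt
single-stranded window centred on the anticodon triplet (canonical positions
32–38); the width is configurable because halves are defined by loop
cleavage and some analyses prefer a wider operational loop. The anticodon
stem is the 5 paired nucleotides 5′ of the loop; since the anatomy stores the
5′ strand only, the stem-loop *region* used by the tRF-2 rule extends a
mirror-width 3′ strand immediately after the loop. Acceptor stem, D-arm and
T-arm use canonical coordinates clipped to the sequence; they are annotated
for completeness and do not drive classification.

**Precursor reference.** Leader + body (introns retained) + trailer. The
RNase Z cut site is the body/trailer junction. The RNA polymerase III
terminator is operationalised as the *first maximal run of ≥ 4 consecutive T*
in the trailer — the canonical poly-U termination signal read on the coding
strand. A trailer without such a run yields a precursor with no terminator;
tRF-1 calling is then disabled for that gene with a warning rather than
guessed.

## Alignment cascade

Reads are adapter-trimmed (literal 3′ adapter matched as an exact prefix
overlap at the read 3′ end, ≥ 3 nt, leftmost occurrence; optional 5′ adapter
as a suffix overlap) and rejected below 14 nt — the smallest subtype window
lower bound. Unique sequences are collapsed with multiplicities; quality
strings are ignored after the pass-filter stage.

Placement is substitution-only (Hamming) with at most one mismatch, scanning
every offset of every reference: mature references first, and only reads
without any mature placement are tried on the precursors. Within a pass,
0-mismatch placements anywhere suppress 1-mismatch placements everywhere, and
all equally-best placements are kept. The single tolerated mismatch absorbs
reverse-transcription misincorporation at modified bases (m1A, m3C); no
explicit modification model is attempted, and indels are excluded because
14–40-nt fragments make edit-distance alignment both unnecessary and
ambiguous at this scale. The implementation is an exhaustive vectorised scan;
its contract is checked against an independent brute-force Hamming oracle in
the tests, and it is deterministic: identical inputs give byte-identical hit
tables.

Multi-mapping: a fragment hitting several genes equally well keeps one hit
per gene for classification and naming, but fragments are keyed by sequence,
so each contributes once to counting — consistent with family-level naming.

## Classification

The decision tree is evaluated in fixed order, first match wins:

1. mature, 5′ end at position 0, 3′ terminus inside the anticodon loop,
   length 31–40 → **tiRNA-5**;
2. mature, 3′ end at the mature terminus, 5′ terminus inside the loop,
   length 31–40 → **tiRNA-3**;
3. mature, 5′-anchored, length in 14–16 / 22–24 / 28–32 → **tRF-5a/5b/5c**;
4. mature, 3′-anchored, length in 17–18 / 19–22 → **tRF-3a/3b**;
5. mature, fully inside the anticodon stem-loop region, touching neither
   end, length ≥ 14 → **tRF-2**;
6. precursor, 5′ end at the RNase Z cut (± `end_slack`, default 0), 3′ end
   at or before the terminator end, length 14–33 → **tRF-1**;
7. otherwise **unclassified**.

Placing the tiRNA rules first resolves the silent overlap between the tRF-5c
window (28–32) and the tiRNA window (31–40): a 5′-anchored 31–32-nt fragment
ending inside the loop is a half, because loop cleavage is the stronger
positional claim. Lengths in the 5′ window gaps (17–21, 25–27) and
3′-anchored lengths outside 17–22 are left unclassified rather than forced
into a neighbouring class. All windows are configurable
(`ClassificationScheme`); `end_slack` > 0 tolerates non-templated additions
at the anchored terminus.

Naming follows the field convention `tRF-<AA>-<Anticodon>-<serial>` (or
`tiRNA-…`), with serials assigned per family in lexicographic order of
fragment sequence — deterministic under input permutation and idempotent
under re-registration. Serials are repository-local; external catalogues
number fragments differently, so serials are not comparable across tools.
A fragment mapping to several families is named by the lexicographically
smallest and retains all of them in `source_families`. Known/novel status is
exact sequence membership in an optional plain-text catalogue; with no
catalogue everything is novel.

## Quantification and differential screening

Abundance is counts per million of total aligned reads:
`cpm = count / aligned_total × 1e6`, the denominator counting every aligned
read (classified or not) in the sample. The screen between two conditions
uses, per fragment:

* fold change `FC = (mean_cpm_B + 1) / (mean_cpm_A + 1)` — pseudocount 1
  avoids division by zero on sparse fragments;
* a two-sided Welch t-test on `log2(CPM + 1)` across replicates (the test is
  a pluggable callable, so an exact negative-binomial test can be swapped
  in);
* significance iff `max(FC, 1/FC) ≥ 1.5` **and** `p ≤ 0.05`, with no
  multiple-testing correction by default (Benjamini–Hochberg available via
  `adjust=True`).

Degenerate rows (zero within-group variance on the log scale) get `p = 1`
when the group means agree and `p = 0` with a warning when they differ — a
deterministic convention that keeps noiseless synthetic fixtures meaningful.
Rows that are zero in every sample are excluded and logged.

"Expressed in a condition" is operationalised as CPM ≥ 1 in at least half of
the condition's replicates (both thresholds configurable); condition overlap
(unique-to-A / unique-to-B / shared) is plain set arithmetic on the expressed
name sets. The `2^-ΔΔCt` helper implements the usual qPCR estimator
normalised to a reference gene and a control sample.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated; it emulates a two-condition aging comparison with five biological
replicates per condition.

* **Genes** (default 30): random 73-nt bodies with the anticodon planted at
  position 33 (mature length 76), 10-nt leaders, 40-nt trailers carrying
  exactly one ≥ 4-T run — a 6-nt poly-T tract planted at trailer offset 18
  (accidental upstream runs are broken so the terminator position is known).
  Families cycle through a fixed table headed by Trp-CCA, Asp-GTC and
  Glu-CTC. Thirty genes keep every subtype's pool of distinct fragments
  comfortably larger than the demand implied by the mix below.
* **Fragments** (default 500, unique by sequence): subtype drawn from a mix
  that echoes the observed spectrum — tRF-1 most abundant, then 5′
  fragments, then 3′ fragments, with minor tRF-2 and halves — then anchored
  by the subtype's own rule with length uniform over the feasible window.
  Every truth row is verified against the classifier at generation time, so
  truth labels and pipeline labels agree exactly by construction at zero
  noise (the end-to-end test then checks the whole read-level path).
* **Counts**: per-fragment base abundance lognormal around `nb_mean = 50`
  with σ = 0.8 (a realistic skewed abundance spectrum at desk scale);
  per-sample counts negative-binomial with variance `μ + 0.1 μ²` (common
  dispersion 0.1, the standard small-RNA count model; dispersion 0 gives
  Poisson). A `de_fraction` of 10% of fragments receives the designated fold
  change (default 4), upward or downward with equal probability, in the
  second condition.
* **Reads**: fragment + 3′ adapter (Illumina small-RNA adapter
  `TGGAATTCTCGGGTGCCAAGG`) with iid substitutions at `noise_rate = 0.005`
  per base, mirroring the one-mismatch alignment premise. Fixed seeds make
  every emitted file byte-identical across reruns.

What the generator does **not** model — ligation bias, empirical error
profiles, position-dependent modification read-through, expression shared
between isodecoder copies, non-templated 3′ additions — bounds what passing
tests show: they validate the anchoring logic, the cascade bookkeeping, and
the screen's operating characteristics under the stated count model, not
performance on real libraries with structured artefacts.

## Problem sizes and numerical choices

The default validation experiment is 500 fragments × (2 × 5) samples at mean
depth ~50 reads per fragment (~250k reads), which runs the full read-level
path in seconds; the differential-screen operating characteristics
(sensitivity ≥ 0.9, false-positive rate ≤ 0.05 at fold change 4; null calls
≤ 7%) are aggregated over ten generator seeds at the count level. Dataset
sizes of real studies (hundreds of tsRNAs from tens of millions of reads)
depend on deposited accessions plus undisclosed expression criteria and
catalogues, and are deliberately not reproduction targets here.

Tie-breaks and degenerate inputs: equal-mismatch placements are all
reported, with classification conflicts resolved by decision-tree priority;
empty trailers refuse precursor construction; anticodons within two bases of
a mature end refuse anatomy construction (the loop would overhang); zero
aligned totals are a hard error rather than a silent NaN column.

## Known limitations

* Substitution-only alignment: fragments with real indels (rare in this size
  range) are lost or shifted.
* tRF-2 has no published length window; containment in the stem-loop region
  with the global 14-nt minimum is this package's operationalisation.
* The mirror-width 3′ anticodon-stem strand is an approximation for
  non-canonical stems.
* The Welch-on-log2-CPM screen is a specified, dependency-free computation;
  it is not an exact negative-binomial test and will be slightly
  conservative at very low counts.
* Serial numbers in canonical names are not comparable to external
  catalogues.
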