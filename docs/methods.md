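# Methods

This note documents the models behind each musselkit module, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions that affect results.

## k-mer spectrum model

A k-mer histogram records, for each multiplicity m, the number of
distinct k-mers observed m times in the reads.  The profiler assumes the
classical three-component picture of a diploid spectrum:

1. an **error limb**: sequencing errors create (mostly unique) k-mers
   whose counts decay steeply from multiplicity 1;
2. a **heterozygous peak**: k-mers overlapping a heterozygous site exist
   on one haplotype only and accumulate at roughly half the sequencing
   depth, c_het ≈ c/2;
3. a **homozygous peak** at the full depth c, from k-mers shared by both
   haplotypes.  A high-multiplicity tail from repeats may follow; it is
   retained in the total volume and no repeat correction is applied.

**Error threshold.**  The boundary e between error limb and signal is the
first local minimum of the smoothed count curve scanning upward from
multiplicity 1.  Smoothing is a centred moving average, window 3 bins by
default (window 1 disables it); raw histograms are noisy enough at depth
that an unsmoothed first minimum can fire early.  K-mers at
multiplicities *strictly below* e are "erroneous"; counts from e upward
are retained.  Both e and the peak depths accept explicit overrides so a
published choice (e.g. e = 12, c_hom = 45) can be imposed.

**Genome size.**  G = (T − T_err) / c_hom with T = Σ m·count(m),
T_err the volume below e.  On a noiseless single-peak histogram this is
exactly T/c.  The estimate inherits a ±1-bin discretization of c_hom
(≈2% at 45×).

**Ploidy call.**  Peaks are local maxima of the smoothed curve above e;
*dominant* peaks reach at least 15% of the tallest peak's height.
Exactly two dominant peaks whose depth ratio lies in 2 ± 0.35 →
"diploid-heterozygous"; one dominant peak → "haploid-like"; anything
else → "ambiguous".  The 0.35 tolerance accommodates the ±1-bin
discretization of both depths (22/45 = 2.05 must pass, 70/20 = 3.5 must
not); the 15% dominance floor keeps minor repeat bumps from triggering a
spurious diploid call while still detecting het peaks as small as ~25%
of the hom peak (the 0.5%-heterozygosity regime).

**Heterozygosity.**  Each isolated heterozygous site converts the ~k
spanning k-mers of each haplotype into haplotype-specific ones, i.e.
~2k distinct k-mers at the het depth.  The estimator integrates the
histogram volume A_het over the heterozygous window — from the smoothed
minimum in [e, c_het) (usually e itself) to the minimum in
(c_het, c_hom) — and computes

    D_het = A_het / c_het,   H = D_het / (2k),   r = H / G.

The literature describes several variants of this spectral argument
without printing a formula; this linear version is the package's choice
and is validated by parameter recovery.  Its known bias: at high
heterozygosity the "isolated site" assumption saturates — the chance
that a k-mer window contains ≥1 het site is 1 − (1 − r)^k, not k·r — so
r = 3% with k = 17 is underestimated by ~20%.  The recovery suite bounds
the relative error at 25% over r ∈ [0.5%, 3%]; using 17-mers (the usual
choice for heterozygosity work) keeps saturation inside that bound,
which 25-mers would not at the top of the range.  A missing het peak
yields r = 0 with an explicit `no-het-peak` flag.

## Assembly statistics

Nxx is computed by sorting lengths in decreasing order and returning the
first length at which the cumulative sum reaches x% of the total; the
comparison uses integer arithmetic (cum·100 ≥ x·total), so no float
threshold is involved.  Soft-masked bases are lowercase a/c/g/t; N/n are
gaps, counted separately and *not* as masked (RepeatMasker soft-masking
convention).  Contigs are obtained by splitting scaffolds at runs of ≥10
N's (configurable; the split rule behind published contig counts is
rarely stated).

Display conventions, kept apart from the unrounded internal values:
integer cells round half away from zero; size-threshold percentages use
one decimal (trailing `.0` trimmed); the genome-fraction-in-large-
scaffolds row uses two decimals.  BUSCO percentages are *truncated* to
two decimals rather than rounded — published BUSCO tables follow this
convention (769/978 → 78.62, 105/978 → 10.73) and rounding would differ
in both cases.  The comparison table offers `display=False` to emit
full-precision values that round-trip numerically.

## Gene-model curation

Filters run in a fixed order — alignment coverage, exon count,
redundancy, repeat overlap — each producing a subset of its input and a
reason for every rejection, so the final report accounts for every
model.  Conventions:

* Coordinates are 0-based half-open internally; GFF3 (1-based closed) and
  BLAST query ranges (1-based closed; span = qend − qstart + 1) are
  converted at the file boundary, BED passes through unchanged.
* **Coverage**: the best hit per model (min e-value, then max span, then
  subject id — fully deterministic) must cover ≥ 90% of the query,
  boundary inclusive.  Models without hits are rejected as `no-hit`.
* **Exons**: "more than 3 exons" is read literally (keep ≥ 4); the
  inclusive variant is one parameter away (`min_exons=3`).
* **Redundancy**: pairwise overlap is shared exon-projected bases divided
  by the shorter model's cds length (denominator configurable:
  shorter | longer | union).  At ≥ 90% the shorter model is removed;
  equal lengths keep the lexicographically smaller id.  Because removal
  only ever eliminates the shorter member, iterating to fixpoint is
  order-independent: a model survives iff no surviving longer model
  covers it.  The implementation processes models longest-first, which
  realizes that fixpoint directly; tests verify equivalence against a
  naive remove-any-violating-pair oracle and input-order invariance.
* **Repeats**: any ≥1-base intersection between an exon and a repeat
  interval disqualifies (half-open: abutting intervals do not touch).
  Models on scaffolds absent from the repeat track are treated as
  repeat-free and logged.

Strand is carried but ignored by all interval logic — the filters are
strand-agnostic as usually described.

## Domain expansion/contraction test

Counts are normalized per genome by its total domain count N_g
(compensating genome size and annotation depth).  The focal expectation
for domain d is the reference-frequency average rescaled to the focal
total:

    lambda_d = mean_{g != focal} (count_{g,d} / N_g) * N_focal.

One-sided Poisson tails P(X ≥ x | λ) and P(X ≤ x | λ) are
Bonferroni-adjusted; *expanded* requires a significant upper tail with
x > λ, *contracted* a significant lower tail with x < λ.

**Bonferroni family.**  The default multiplies by 2m (m = domains
tested): the call set is the union of two one-sided families, and a
calibration study (500 null matrices) measured family-wise error 0.086
under 2m versus 0.140 under m.  `family_size="domains"` selects the
single-family variant.

**Rare-domain guard.**  The plug-in rule degenerates when the references
contain no counts at all: λ̂ = 0 makes any positive focal count
"infinitely significant" (P(X ≥ 1 | 0) = 0), and at realistic matrix
shapes focal-only singletons would dominate the call set.  The test
therefore floors the expectation at the rate implied by one pooled
pseudo-count among the references, N_focal / Σ N_others (≈0.11 for ten
equal-sized genomes), before computing tails.  `min_expected=0` restores
the literal rule; the reported `expected` field is always the raw λ̂.

**Known limitation — anti-conservativeness.**  λ̂ is the mean of 9 noisy
per-genome counts, so the statistic x − λ̂ has variance ≈ λ(1 + 1/9)
while the Poisson tail assumes λ.  At the Bonferroni threshold
(z ≈ 4.2) this inflates the true tail mass ~2.4×; measured family-wise
error on nulls is ~0.08–0.10 at α = 0.05 rather than ≤ 0.05, and over
many planted-recovery runs an occasional false call appears (measured
precision ~0.99 with perfect separation of true 4-fold changes, recall
≈ 0.98).  This is inherent to the plug-in formulation; an exact
conditional (binomial) two-sample test would control the error rate at
the cost of no longer being the plug-in Poisson rule this package
reimplements.

**Display matrix and clustering.**  The log2 matrix is
log2((n + pc) / (mean_d + pc)) on frequency-normalized counts rescaled
to a common total (default: the mean genome total), with pseudocount
0.5; the pseudocount affects only this display matrix, never the test.
Clustering is complete-linkage agglomeration on the "average dot
product" similarity S_ij = (x_i · x_j)/p (mean elementwise product over
the p profile entries), converted to a distance by subtracting from the
global maximum similarity (which lies on the diagonal, so distances are
non-negative).  Ties merge in lexicographic label order, making the
merge sequence deterministic.  Note that under raw dot products an
identical pair of rows merges at distance 0 only when its self-similarity
is the global maximum (i.e. it carries the largest profile norm); the
`similarity="cosine"` option guarantees it unconditionally.  Dendrograms
are emitted as ultrametric Newick.

## Synthetic generators

All generators are pure functions of (parameters, seed) — regenerating
with the same seed yields byte-identical files — and every dataset ships
a truth record sufficient to recompute the expected downstream output.

* **Diploid spectra.**  The default *direct* mode samples each distinct
  k-mer's multiplicity analytically: a genome position's k-mer is
  haplotype-specific with probability 1 − (1 − r)^k (two distinct k-mers
  at Poisson(c/2) each), otherwise shared (one k-mer at Poisson(c));
  errors add G·c·e_rate·k unique k-mers with geometric multiplicities
  (mean 1.3 — steep enough to carve the low-multiplicity valley).  The
  *sequence* mode actually builds both haplotypes, enumerates their
  k-mers exactly (2-bit codes, circular) and samples per distinct k-mer;
  it validates the direct mode on small genomes.  Not emulated: repeat
  content, GC-coverage bias, read-edge effects — so passing recovery
  tests demonstrate correctness of the estimators under the spectral
  model, not robustness to repeat-rich real spectra.
* **Scaffolds.**  Lognormal lengths by default, contiguous soft-masked
  block per record, optional N-gap runs.  No sequence composition
  structure beyond uniform bases.
* **Gene models.**  One model per scaffold (no accidental overlap), one
  planted violation category per model; redundant duplicates are strict
  sub-models of their host so the intended cascade stage rejects them.
  Violations are disjoint by construction — the truth records the single
  stage at which each model must fall.
* **Domain matrices.**  10 genomes × 2000 domains with per-genome totals
  of 40 000 by default, matching the scale of a typical multi-proteome
  Pfam comparison (tens of thousands of assignments over a few thousand
  distinct families, exponential-tailed family sizes).  Planted
  fold-changes get baseline expectations drawn from [20, 200] so both
  directions are detectable at fold 4.  Multinomial sampling holds
  genome totals exactly fixed; Poisson sampling is the natural null for
  calibration.  Compositional closure is real here as in real data:
  planting expansions deflates the focal genome's remaining frequencies
  by a few percent.

## Numerical and degenerate-input conventions

* Histogram multiplicities are strictly increasing; gaps are zero counts.
  Out-of-order files are re-sorted by default (`reorder=False` to make
  them an error); a catch-all last bin can be dropped (`drop_last_bin`).
* Monotonically decreasing spectra raise "no valley found" rather than
  guessing an error threshold.
* Poisson tails use scipy's survival/cumulative functions with the λ = 0
  degenerate convention P(X ≥ x) = [x = 0], P(X ≤ x) = 1; the identity
  p_up + p_down = 1 + pmf(x; λ) holds throughout.
* Plateaus: valley detection returns the last flat bin, peak detection
  the first; both are deterministic.
* All file writers are atomic (temp file + rename); interrupted runs
  leave no partial outputs.  Analysis outputs are byte-stable across
  reruns; the only timestamp lives in the provenance sidecar.

## Test problem sizes

The shipped suites run on one CPU in well under a minute: five recovery
spectra at 0.5–2 Mb, 1000 random length lists for the N50 oracle, 20
seeds × 500 models for curation recovery, 500 null matrices plus 20
planted matrices (10 × 2000) for the domain-test calibration, and 50
random 5 × 8 matrices for the clustering oracle.  These sizes were chosen
so each property has enough replication to be meaningful while keeping
the whole suite fast to iterate on.
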