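# Methods

## The statistic

`msikit` calls microsatellite instability (MSI) from targeted gene-panel
sequencing without a matched normal, using a baseline-referenced allele-count
statistic in the mSINGS lineage.

For a sample *s* and microsatellite locus *l*, let `H(s,l)` be the histogram
of repeat tract lengths over spanning reads.  The **allele count** `A(s,l)`
is the number of distinct lengths whose read support is at least
`allele_fraction` × the modal length's support (inclusive ≥, so a count
exactly at the threshold is an allele).  From a pool of known-MSS training
samples the per-locus **baseline** stores the mean `μ_l` and sample standard
deviation `σ_l` (n−1 denominator) of `A(·,l)`, using only training samples
with spanning depth ≥ `depth_min` at that locus; loci with fewer than two
contributing samples are excluded and recorded.

A test locus is **evaluable** when its spanning depth is ≥ `depth_min`, and
**unstable** when `A(s,l) > μ_l + k·σ_l` (strict >, so a zero-variance
baseline still demands a count strictly above the mean).  The **sample
score** is

    score(s) = (# unstable evaluable loci) / (# evaluable loci),

classified MSI when `score ≥ cutoff` (a trained cutoff when available,
otherwise the classical 20% fraction-of-mutated-markers default).  A sample
with fewer than `min_evaluable` evaluable loci is reported FAIL, not called;
FAIL samples are excluded from cutoff fitting and AUC but tallied in the
failure rate with the whole cohort as denominator.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `allele_fraction` | 0.05 | minimum support relative to the modal length for a distinct length to count as an allele |
| `sd_multiplier` | 2.0 | baseline SDs above the mean allele count that flag a locus unstable |
| `depth_min` | 30 reads | spanning depth needed for a locus to be evaluable (10/15/20 are common relaxations, explored by `depth_threshold_sweep`) |
| `min_evaluable` | 6 loci | minimum evaluable loci for a sample call, ≈20% of a 29-locus panel |
| `msi_cutoff` | 0.20 | fraction-unstable threshold when no trained cutoff is supplied |

`allele_fraction` and `sd_multiplier` follow the mSINGS lineage defaults and
are exposed rather than hard-coded.  `min_evaluable` is capped at the panel
size when scoring a restricted panel: a deliberately small marker set (the
panel-optimisation experiments go down to one locus) must still be able to
call samples, and the cap reproduces the expected behaviour that small
panels convert borderline samples into failures only via per-locus depth,
not by construction.

## Spanning-read profiling

A read spans a locus when it contains the locus' left flank anchor followed,
after any number of tract bases, by the right flank anchor; the tract length
is the base count strictly between the anchors (bases, not repeat units — a
unit count is recoverable by division, and bases are robust to interrupted
repeats).  Anchors are found by exact substring match — leftmost left-flank
hit, first right-flank hit after it — on the read as given and its reverse
complement.  CIGAR-walking is deliberately avoided: aligners place indel
gaps inside homopolymers inconsistently, whereas flank anchoring measures
the tract as sequenced.  Flanks default to 5 bp per side: long enough to
anchor uniquely in a 150 bp read, short enough to survive read trimming.
Mapping quality below 1 (unmapped / ambiguous multi-mappers) is skipped;
mates are treated independently, accepting the rare double-count of a tract
in overlapping pairs because PCR duplicates are assumed collapsed upstream
by UMI consensus.

Depth subsampling draws exactly `max_depth` reads without replacement
(multivariate hypergeometric), with a stream seed derived from
(global seed, sample id, locus id) so results are independent of processing
order.

## Cutoffs, AUC and cross-validation

The trained cutoff minimises total mis-calls (false positives + false
negatives) of the rule "MSI iff score ≥ c".  Only the gaps between adjacent
observed scores can change the decision, so all 2n+1 candidate intervals are
scanned; among minimisers the midpoint of the widest open interior gap is
returned (maximum margin, deterministic), with unbounded end intervals given
width 0 and remaining ties broken toward the lowest cutoff.

AUC is the Mann–Whitney pair statistic — the probability that a random MSI
sample outscores a random MSS sample, ties counting ½ — computed from
midranks.  It equals the trapezoidal ROC area but has an unambiguous tie
rule, which matters because fraction-unstable scores live on a coarse
lattice.

Cross-validation follows a replicated train:validation design: the cohort is
dealt into 3, 5 or 10 stratified folds (ratios 1:2, 1:4, 1:9), each fold
serving once as the *training* set (baseline from its MSS members, cutoff
from all its non-failing scores) with the remainder as validation; the
dealing is repeated, 10 replicates by default, giving e.g. 30 runs at 1:2.
Stratification is used because at 14% prevalence an unstratified small fold
frequently contains no MSI sample, making cutoff training degenerate; such
degenerate runs, when they still occur (e.g. all MSI members failing on
depth), are recorded as invalid rather than silently dropped.

## Panel optimisation

Marker panels are judged lexicographically on (total validation mis-calls
across all CV runs, total failures), final ties broken by sorted locus ids.
The backward-forward search grows the panel one locus at a time: a forward
step adds the best absent locus; a backward refinement then repeatedly tests
whether dropping a member (strict improvement only, which prevents
add/remove oscillation) and re-adding the best replacement improves the
size-k objective, stopping when no removal helps or a size-k panel repeats
(revisit tracking guarantees termination); the best size-k panel seen is
recorded before growing.  Exhaustive subset search is used only as a test
oracle on 6-locus instances — 2²⁹ subsets are out of reach by design.

## The synthetic cohort

The simulator emulates the failure modes of FFPE tumour panel sequencing at
the histogram level (the caller's input surface; read sequences are only
exercised by a small alignment fixture in the test suite):

- **PCR stutter**: a read's slippage magnitude is geometric-tailed,
  P(magnitude = j) = (1−s)·s^j with s = 0.15 per base step, deletion-biased
  (20% of slipped reads gain bases) — the classical slippage profile of
  mononucleotide repeats.
- **Somatic instability**: a mutated locus mixes in reads centred
  `shift` ∈ [2, 8] bases below the reference tract with doubled stutter,
  weighted by the tumour fraction (uniform 0.3–0.7, the range typical of
  macrodissected resection samples).
- **Mutation load**: MSI samples mutate each locus independently at rate
  0.85; a 10% MSI-low stratum mutates at 0.25, producing the borderline
  scores that stress cutoff training.
- **Depth**: per-sample median depth is log-normal (median 200×, σ = 1.0)
  with an extra per-locus log-normal factor (σ = 0.6) and Poisson counts; a
  5% under-sequenced stratum is scaled ×0.05 so that sample failures occur.
  At defaults the per-locus depths span more than three orders of magnitude.
- **Cohort**: 120 samples at 14% MSI prevalence over a 29-locus synthetic
  panel of mononucleotide repeats (tract lengths 15–30 bp; flanks drawn from
  non-unit bases so anchors are unambiguous).  The panel is illustrative,
  not a set of genomic coordinates.

The standard study conditions used throughout the tests and examples are the
simulator defaults with seed 0, and a 1:2 × 10-replicate CV scheme (seed 0).
At those conditions the caller reaches mean validation AUC ≈ 0.999 with a
miscall rate ≈ 1.2% of assessable samples; across other seeds the mean AUC
varies roughly between 0.96 and 1.0, driven by how many MSI-low samples a
cohort happens to draw and where they fall against the MSS tail.

### What the simulator does and does not show

Stable loci in the simulation carry minor stutter alleles at ~2–3% relative
frequency — just below the 5% allele threshold — so at moderate depth the
allele count of a clean locus stochastically flips between 2 and 3 and the
per-locus false-instability rate is several percent.  Two consequences are
worth knowing:

- MSS sample scores cluster near 0.1 rather than 0, so the fixed 20%
  default cutoff mis-classifies a visible tail of MSS samples (~10% at
  defaults).  Trained cutoffs sit above that tail; cohort evaluation should
  always use the cross-validated path.
- Capping validation depth at 40× inflates MSS scores relative to cutoffs
  trained at full depth, raising mis-calls while leaving the score *ranking*
  — and hence AUC — essentially unchanged (shift < 0.001 at 40/60/80×).

Both effects mirror the clinical observation that low spanning depth
associates with false-positive MSI calls; neither implies anything about
sequence-level artefacts (substitution errors, quality scores, alignment),
which the simulator does not model.  Passing tests therefore demonstrate
correct behaviour of the statistic, the harnesses and the search under a
realistic depth/stutter regime, not assay performance on real FFPE data.

## Numerical and degenerate-input choices

- Allele threshold comparison is inclusive (≥), instability comparison is
  strict (>): together they avoid mass false instability at zero-variance
  loci while keeping the boundary case of the allele definition countable.
- Empty histograms cannot be allele-counted (error); depth-0 loci are simply
  not evaluable.  An empty alignment profiles to all-zero histograms.
- Percentages are reported rounded to one decimal; scores to four in
  reports, two when quoting the lattice of small panels.
- All randomness flows through explicit seeds: cohort simulation, CV
  dealing, subsampling (per-sample/locus derived streams), and random panel
  draws are bit-reproducible.

## Known limitations

- No matched tumour–normal mode; the baseline pool is the only null model.
- The histogram-level simulator cannot probe alignment- or chemistry-level
  failure modes, UMI errors, or locus-specific stutter heterogeneity.
- `backward_forward_select` evaluates O(panel²) CV sweeps per size step; on
  a 29-locus panel with the full 30-run scheme it is minutes, not seconds.
- The greedy search is not guaranteed globally optimal; the oracle tests
  verify it only on small instances where exhaustive search is feasible.
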