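# Methods

## The model

`hmmenrich` asks whether a transcription-factor binding motif is
over-represented in the promoters of a gene set, without ever calling
individual binding sites.  Each motif (a position probability matrix, PWM) is
embedded in a small hidden Markov model:

* a silent **start** state;
* four **background** states, one per nucleotide, each emitting its own base
  with probability 1 and transitioning according to a first-order
  (dinucleotide) Markov chain estimated from the promoter pool;
* a chain of **motif** states, one per PWM column, whose emissions are the
  PWM rows and whose internal transitions are 1; with double-stranded
  scanning (the default) a second chain carries the reverse-complement PWM.

From every background state (and from the start) the motif chain is entered
with probability *e*, the **entry probability** — the model's "how often does
this motif occur" knob; with two strand branches a single *e* is split
equally between them.  The background block is scaled by 1−*e* so rows stay
stochastic, and the last motif state exits to the background states according
to the background's initial distribution (the exit law is not otherwise
constrained by the model; this choice keeps the chain well normalised and is
symmetric with the start).

A promoter's score for a motif is the log likelihood ratio

    score(s) = log P(s | motif HMM) − log P(s | background-only chain),

computed with the forward algorithm, i.e. summed over *all* parses of the
promoter into motif occurrences and background.  Weak sites that a hard
threshold would discard still contribute; a promoter with no plausible site
scores ≈ 0.  With *e* = 0 the score is exactly 0.

*e* is fitted per motif by Baum–Welch restricted to the entry transitions:
emissions, within-motif transitions and the shape of the background block are
frozen, so the M-step reduces to
*e* ← E[# entries] / E[# transitions leaving background or start].  The
training log likelihood is non-decreasing by the usual EM argument, and this
is asserted in tests at every iteration.  Entry probabilities are learned
once per motif on the full promoter pool and reused for the target set and
every random set — learning per target set would make the empirical null
non-exchangeable.

## Enrichment test

For a target gene set, the per-promoter scores are summed (sums of *log*
ratios: raw-ratio sums are dominated by single promoters and overflow; a
raw-ratio mode exists behind `score_mode="raw_ratio"` for fidelity
experiments).  The null is empirical: `n_random` (default 100) random
promoter sets of the same size are drawn uniformly without replacement from
the full pool (targets are not excluded; an exclusion mode is available),
their sums form the null sample, and the target sum is standardised,

    z = (target − mean_null) / sd_null,   p = 1 − Φ(z),

with sd the sample standard deviation.  p-values are corrected across motifs
by Benjamini–Hochberg and findings reported at FDR < 5%.  One shared
collection of random sets serves all motifs in a run, which keeps ranks
comparable across motifs; because a promoter's score does not depend on which
set it sits in, the whole null is computed from a single pass of per-promoter
scores over the pool (an exact refactoring, not an approximation).

An alternative estimator, `p_value_mode="rank"`, uses the smoothed rank of
the target sum among the null sums, (1 + #{null ≥ target}) / (1 + n).  It is
exactly calibrated under the null by exchangeability (see *Calibration*
below) but has resolution limited to ~1/n.

## Preprocessing: matrix normalisation, thresholds, clustering

Count matrices (TRANSFAC flat-file dialect) are converted to probabilities
with an additive pseudocount, default **0.25 per cell**: the forward
algorithm requires strictly positive emissions, and 0.25 is small enough not
to blur informative columns of typical count depths.  Information content is
Σ positions (2 + Σ_b p log₂ p) bits: 2 per position for a deterministic
column, 0 for uniform.

For the hard-threshold side, windows are scored with log-odds against the
background's stationary nucleotide distribution.  A motif's empirical
threshold is the larger of the 100th-highest window scores on two background
collections (model-generated sequences and segments of real promoters); with
10,000 window scores per collection the threshold is the 99th percentile,
i.e. FPR 0.01 by construction.  Redundant matrices are pruned by hit overlap
on the pool: for every pair whose symmetric overlap fraction — intersecting
hits of both matrices over total hits of both — reaches `overlap_x` (default
0.2), the lower-information-content member is discarded.  Pairs are
processed in decreasing overlap (ties by motif id), which makes the result
deterministic and order-independent; raising `overlap_x` can only retain
more matrices.  An alternative `min` denominator (overlap over the smaller
hit list) is selectable.

The scanner baseline counts above-threshold windows per promoter, merging
same-strand overlapping hits (a strong site should not count once per
shifted window); opposite strands count separately.  Promoters are
categorised 0 / 1 / 2 / >2 by occurrence count, and the default enrichment
statistic is an upper-tail hypergeometric on promoters with ≥ 1 occurrence.
Note one subtlety: *merged* occurrence counts are not monotone in the
threshold (a merged run can split into two disjoint occurrences as the
threshold rises); the raw window counts that feed the merge are monotone,
and that is the invariant asserted in tests.

## Numerical choices

* **Forward/backward in scaled linear space.**  500 bp promoters underflow
  in linear space; instead of log-sum-exp per cell, the recursion
  renormalises the state distribution at every position and accumulates log
  scale factors.  This is exact in log likelihood (asserted against
  exhaustive path enumeration at 1e-9) and lets the machine's sparsity —
  indicator background emissions, deterministic motif chains — be exploited:
  whole same-length sequence batches are scored in one vectorised sweep.
  The recurrences are compiled with numba when available; a pure-numpy
  implementation of the identical recurrence serves as fallback and as a
  cross-checked reference in the tests.
* **N bases** emit probability 1 in every state: masked sequence neither
  rewards nor penalises the motif branch.  Because all four background
  states stay live across an N, an isolated N contributes a factor of
  exactly 1 to the likelihood.
* **EM settings.**  Initial total entry 0.01 (order one expected occurrence
  per 500 bp for a ~10 bp motif); convergence when the per-sequence log
  likelihood gain drops below `tol` = 1e-6 (library default; the simulation
  harness uses 1e-5 with `max_iter` 50 as its documented problem scale);
  entry clamped below 1.  The degenerate sd = 0 null yields p = 1 unless the
  target exceeds the mean, in which case p is floored at 1e-300.
* **Coordinates** are 0-based half-open; BED TSS handling is strand-aware
  (start for +, end for −); promoters truncated at chromosome edges are kept
  with a logged warning.
* **Reproducibility.**  A single seed governs every random choice through
  named SeedSequence substreams; reports embed a config digest, and two runs
  with equal seed and digest are byte-identical.

## Synthetic data: what it emulates and what it does not

No external data are needed to build or test the package.  The generator
provides: (i) a fixed *promoter-like* dinucleotide background (mildly
GC-rich, C→G-depleted — the qualitative signature of vertebrate promoter
sequence) from which promoter pools are sampled; (ii) decoy PWMs with
per-position Dirichlet(0.5) rows, lengths 8–14, standing in for a curated
vertebrate matrix library; (iii) planted-motif target sets following the
simulation protocol: sets of 100 background promoters of 500 bp in which a
chosen fraction receives exactly 3 non-overlapping motif instances sampled
column-wise from the PWM (forward strand by default; positions uniform by
rejection).

Synthetic pools lack several features of real promoters: CpG islands and
other long-range composition structure, repeats, shared regulatory grammar
between co-regulated genes, and correlated motif co-occurrence.  Passing the
simulation benchmarks therefore demonstrates the statistical machinery
(scoring, learning, calibration, power) under the model's own assumptions —
not performance on real genomes, which additionally depends on matrix
quality and promoter annotation.

## Study scales used by the test suite and acceptance script

Forward-vs-enumeration checks use 200–500 randomized machines with ≤ 12
states and sequences ≤ 8 bp.  Null calibration uses a pool of 1000 synthetic
promoters (pool ≫ set, mirroring draws from a whole-genome promoter
collection), 20 decoys, 200 replicate target draws of size 100 and 100
random sets per draw.  The power benchmark plants a 12-bit motif in 50% of
100 promoters (3 instances each) against 20 decoys, 20 replicates with a
pool of the target set plus 100 extra background promoters.  The small-set
false-positive comparison draws 50 target sets of size 30.

## Known limitations

* The normal-CDF p-value inherits the normality assumption on null sums.
  When a motif's score mass concentrates in a few pool promoters — typical
  for a specific motif absent from most sequences — null sums are
  right-skewed and near-discrete, and the normal tail approximation is
  measurably non-uniform under the null (the package's calibration tests
  quantify this; the rank estimator passes the same checks exactly).  FDR
  control at 5% remains comfortably conservative in all measured settings.
* Only the entry transitions are learned; motif emissions are taken at face
  value from the matrix library, so matrix quality bounds everything.
* The scanner baseline's category-based statistic is a documented stand-in
  (hypergeometric on ≥ 1 occurrence); the 0/1/2/>2 categories are exported
  for users who want to plug in alternatives.
* In planted-motif benchmarks, decoy "false positives" are partly genuine:
  a decoy sharing sequence content with the planted motif (or with its
  consensus periodicity) is truly enriched in the planted promoters, so the
  decoy call rate under planting overstates the null false-positive rate.
  The null simulations (no planting) are the clean FPR measurements.
* No Viterbi decoding or site calls: the method is threshold-free by design
  and reports set-level enrichment, not binding-site coordinates.
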