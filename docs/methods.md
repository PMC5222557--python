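# Methods

## The generative model

The simulator treats a genome as a set of chromosomes carrying licensed
replication origins at fixed positions, each with a firing probability
(efficiency) e<sub>i</sub> ∈ [0, 1]. In every simulated cell:

1. each origin fires independently with probability e<sub>i</sub>; if no
   origin on a chromosome fires, the chromosome's firing vector is redrawn
   (every chromosome must replicate every cycle). This rejection step
   raises each origin's realized firing frequency to
   e<sub>i</sub> / (1 − Π<sub>j</sub>(1 − e<sub>j</sub>)), and all oracles
   apply the same conditioning;
2. forks move bidirectionally outward from each fired origin at uniform
   speed, so the fork direction at any position is determined by the
   nearest fired origin: rightward if it lies strictly left of the
   position, leftward if strictly right. A position exactly equidistant
   from two fired origins is resolved uniformly at random, matching the ½
   contribution such ties receive in the closed-form oracle;
3. Okazaki-fragment 5′ anchors are sampled uniformly over the genome.
   Fragment strand follows the local fork: Watson under leftward forks,
   Crick under rightward forks. A Watson fragment spans
   [anchor, anchor+L), a Crick fragment (anchor−L, anchor]; lengths come
   from a mixture over 1–3 nucleosome-repeat multiples (period 172 bp,
   weights 0.5/0.35/0.15, Gaussian jitter sd 25 bp, bounded to
   [100, 600] bp), emulating the periodic fragment-size ladder of
   ligase-depleted chromatin. End-truncated fragments are shortened, and
   discarded only below 30 bp (counted and logged).

An optional per-cell jitter of fired-origin positions turns point origins
into broad initiation zones; the transition-zone statistic grows
monotonically with this jitter, which is exercised in the tests.

**Exact strand-bias oracle.** For ≤ 20 origins per chromosome,
`expected_watson_fraction` enumerates all firing combinations, weights each
by its probability renormalized to exclude the all-unfired event, and
scores whether the nearest fired origin lies right of the position (exact
tie = ½). Empirical Watson fractions from ≥ 5,000 simulated cells agree
with it within binomial error, which is the package's core correctness
guarantee for the strand logic.

**A useful identity.** The step in replication-fork directionality across
an origin — the Crick fraction just right of it minus just left of it —
equals that origin's conditional firing probability exactly: the only event
distinguishing the two sides in the limit is the origin's own firing. This
identity underpins the `rfd_step` efficiency estimator below.

## Origin calling

* Binning: each fragment increments one 100 bp bin on its strand — the bin
  holding its 5′ end (Watson: start; Crick: end−1). The 5′ end marks where
  each Okazaki fragment was initiated and is the convention for OK-seq
  profiles; whole-fragment-per-bin counting is deliberately not used, and
  the choice is recorded in output metadata.
* Smoothing: centred sliding median, default 1.5 kb (15 bins; even windows
  are coerced up to odd). Edges use the truncated window. Zero-coverage
  bins are *masked* — excluded from medians and normalization rather than
  treated as f<sub>W</sub> = 0 — so coverage gaps cannot fake strand
  signal.
* Normalization: per unmasked bin, f<sub>W</sub> = W/(W+C),
  f<sub>C</sub> = C/(W+C).
* Transition metric: M(b) = F<sub>W</sub>(left) − F<sub>W</sub>(right),
  where F<sub>W</sub> is the aggregate Watson fraction of smoothed counts
  over the 12 kb of bins [b−n, b) and [b, b+n). M ∈ [−1, 1], is
  antisymmetric under strand swap, and is undefined where a window leaves
  the chromosome or holds no counts.
* Calling: local maxima of M above a threshold (default 0.1; with ~1,200
  fragments per 12 kb window the null sd of M is ≈ 0.015, so the default
  sits far above noise). Maxima closer than 12 kb are merged keeping the
  larger, ties keeping the leftmost; on a flat plateau the leftmost bin is
  the candidate. Midpoints are bin centres. Both the threshold and the
  merge distance are exposed in the config.

## Efficiency and transition zone

Two efficiency estimators are provided:

* `fraction_max` (default): the maximum normalized strand fraction within
  20 kb of the midpoint — Watson searched left of the midpoint, Crick
  right (strand-appropriate windows stop a neighbouring origin's
  opposite-strand peak from inflating the estimate; a strand-blind ±20 kb
  search is available by flag). A perfectly strand-balanced locus scores
  exactly 0.5. Because this reads the *absolute* fork-directionality
  level, it also absorbs passive replication by forks from neighbouring
  origins: in a dense origin landscape the absolute fraction saturates
  toward 1 near almost every origin, so this estimator compresses the
  upper range and ranks firing probabilities only weakly (rank correlation
  ~0.5 on the default simulation, a property the enumeration oracle
  reproduces noise-free).
* `rfd_step`: the jump in aggregate Crick fraction across the midpoint
  (right 20 kb window minus left 20 kb window, clipped to [0, 1]). By the
  identity above this targets the origin's own conditional firing
  probability, and it recovers simulated firing-probability ranks at
  Spearman ≈ 0.94 on the default run. Pipeline outputs carry it as
  `firing_rate_estimate` alongside the default efficiency.

The transition zone is the distance between the normalized Watson maximum
left of the midpoint and the Crick maximum right of it, each searched
within ±25 kb. Argmax ties — frequent where the fraction saturates at
exactly 1.0 — are resolved toward the midpoint (innermost maximum), so a
noiseless point origin has a zero-width zone and broad initiation zones
widen it monotonically. Negative zones cannot arise with the one-sided
windows but would be flagged, not dropped; flagged origins are excluded
from the ranked strand heatmap, whose rows are mean-centred and scaled to
unit sum of squares (an all-constant row becomes the zero vector and is
flagged).

## Chromatin association

Origins are fixed 5 kb blocks centred on midpoints. Peaks pass a strict
\> 5-fold enrichment filter. Distance is the gap to the nearest block edge
(0 on overlap). The association p-value places an interval of the peak's
length uniformly on the peak's chromosome and computes, by exact interval
arithmetic, the fraction of placements at least as close to an origin
block as observed. This is an analytic, dependency-free simplification of
interval-association testing: single-chromosome uniform null, no domain
masking, no reciprocal test — a deliberate deviation from the original
external tool, checked against Monte-Carlo placement in the tests. The
distance × intensity association grid counts peaks cumulatively along the
distance axis within fold-enrichment bins (bin edges are package defaults,
exposed in config). Signal-versus-efficiency uses Spearman rank
correlation by default (robust to signal scale; Pearson by flag) over
per-origin mean signal in midpoint ± 2.5 kb, with decile efficiency bins
for display.

## Gene context and transcriptome coupling

Genes anchor at their interval midpoint by default (start or strand-aware
5′ end by flag). Orientation profiles report per-signed-bin Watson/Crick
gene counts, log2 ratios (only where both counts are positive; empty sides
flagged) and median gene length. Positional gene-set enrichment uses exact
hypergeometric tails — upper tail for enrichment, lower for depletion,
with the direction reported — and Benjamini–Hochberg adjustment across the
whole set × bin grid; raw and adjusted p-values are both emitted since the
per-bin raw tail is the classical readout.

Expression rows are normalized to sum to 1 across the 50 time points;
all-zero rows are labelled unexpressed and excluded. The maternal/zygotic
split clusters normalized profiles with k-means (k = 6, fixed seed,
n_init = 10) and labels a cluster maternal iff its centroid's mass in time
points 1–5 beats every other contiguous 5-point window; a deterministic
audit rule (per-gene argmax ≤ 5) is available by flag. The coupling
heatmap ranks origins by efficiency, keeps the top N (default 1,000,
clipped with a warning), and sums zygotic normalized expression per time
point × signed 2.5 kb distance bin within ±25 kb; a gene inside the flank
of several retained origins contributes to each (per-origin stacking; a
dedupe-to-nearest flag exists). The coupling statistic is
log2((proximal mean + ε)/(distal mean + ε)) per time point with proximal =
|d| ≤ 5 kb, distal = 15–25 kb, ε = 1e−9; a uniform heatmap scores 0
everywhere.

## Synthetic data: what it does and does not emulate

The generator reproduces: ~40 kb median origin spacing (jittered-lattice
placement — grid spacing length/n with Gaussian jitter sd = spacing/4 —
chosen so the spacing median matches its mean, as observed in embryos;
plain uniform placement, whose median falls well below the mean, is
available), beta(2,2) efficiencies with median 0.5, nucleosome-periodic
fragment sizes, mark peaks with fold-enrichment = baseline + slope ×
efficiency + noise (floored at 1) plus uniform background peaks, and a
three-class expression course: maternal decay from time point 1, early
zygotic genes placed preferentially near efficient origins and peaking at
points 11–22, late genes ≥ 15 kb from any origin peaking from ~point 42,
with a configurable co-directional strand bias inside ±25 kb of origins.
Default gene-class proportions are 0.40/0.35/0.25
(maternal/early/late) with log-normal expression noise (σ = 0.3).

Not emulated: replication timing structure, fork stalling or variable
speed, sequence-level reads, and — importantly — replication-independent
background fragments of random strand. Real OK-seq libraries contain such
background (residual ligase activity), which damps absolute fork
directionality genome-wide; its absence here is why absolute-fraction
efficiencies saturate near 1 in simulation while real data centre near
0.5. Passing tests therefore demonstrate the strand logic, the calling
geometry and the estimators' behaviour, not the absolute efficiency scale
of any real library.

## Problem sizes and numerical conventions

The default study is deliberately desk-scale: 2 × 5 Mb chromosomes, 125
origins each, 2,000 cells × 500 fragments (10<sup>6</sup> fragments,
~10 per 100 bp bin), which runs the full chain in a few seconds while
keeping the OEM statistic far above its sampling noise. Oracle-equivalence
checks use a single 1 Mb chromosome with 8 origins (within the 20-origin
enumeration cap) and 5,000 cells; the jitter-monotonicity experiment uses
one 2 Mb chromosome, 50 origins at e = 0.8, and four jitter levels.

Coordinates are 0-based half-open everywhere (BED convention); bedGraph
output writes one record per run of constant value and omits zero/masked
runs. All randomness flows through `numpy.random.default_rng` seeds
recorded in JSON sidecars together with the full configuration and its
hash; identical seeds give byte-identical outputs. Known limitations:
greedy nearest pairing in map comparison and recovery scoring is not
globally optimal matching; the association p-value ignores chromosome-end
accessibility subtleties beyond clipping; k-means labelling depends on the
fixed seed (the argmax rule is provided for audits).
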