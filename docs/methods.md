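# Methods

This note documents the statistical model, the simulator that defines
the package's test conditions, the numerical choices, and the known
limits of what the tests demonstrate.

## Study design and data model

The unit of analysis is a *triad*: two inbred parents (P1, P2) and
their F1 hybrid, each measured with r biological replicates (default
r = 3) at one or two vegetative stages (S = seedling, H =
early-heading).  Counts per feature (miRNA or gene) and sample are
modelled as negative binomial with mean sf_j·μ_g — sf_j a per-sample
library-size factor, μ_g the genotype mean — and variance μ + αμ².
α = 0 recovers Poisson.

The *mid-parent value* (MPV) is the additive expectation for the
hybrid: the average of the two parental expression levels.  A hybrid
whose expression differs significantly from the MPV is *nonadditive*
(repressed if below, activated if above).

## Normalization

Between-sample normalization for testing uses median-of-ratios size
factors computed over features with positive counts in every sample and
rescaled to geometric mean 1; if no such feature exists, total-count
ratios are used with a warning.  Within-sample summaries use TPM
(columns sum to 1e6) or FPKM.  For mature-miRNA matrices all features
are ~21 nt, so the length term of TPM cancels; the matrix is then
normalized as counts-per-million and tagged `TPM(length-free)`.

Median-of-ratios assumes most features are not differential between
samples.  The simulator's default class mix violates the "most" part
(7/8 of features are differential somewhere in the triad), but because
the high/low parent orientation is randomized for the parent-symmetric
classes the violations are balanced in log space and the median ratio
stays near 1.  Fixtures in which *every* feature shifts the same way
(e.g. a single planted mean triple for all features) confound library
size with biology; such tests pass explicit unit factors.

## Differential test

For groups A and B on the size-factor-scaled counts:

* log2FC = log2((m̄_B + c)/(m̄_A + c)), pseudocount c = 0.5 so zero
  counts give a finite fold change;
* Var(log2 m̄_g) = (m̄_g + α m̄_g²)/(n_g m̄_g² ln²2) by the delta
  method, evaluated at max(m̄_g, 0.5) to guard m̄ = 0;
* z = log2FC / sqrt(Var_A + Var_B), two-sided normal p.

Dispersion is estimated per feature by the method of moments on
normalized counts, (s² − m̄)/m̄² pooled across the two groups by
degrees of freedom and floored at 0, then shrunk 50/50 toward a common
center.  The center is the ratio-of-sums estimate
Σ(s² − m̄) / Σ(m̄² − s²/n) over all groups and features; the
denominator correction uses E[m̄²] = μ² + Var(m̄).  At two or three
replicates the per-feature ratio is extremely noisy and, averaged or
trimmed across features, biased low; the ratio-of-sums form is nearly
unbiased (simulated truth 0.05 → center 0.047–0.048) and that bias is
what otherwise inflates the null false-positive rate.  Features with
zero mean in both groups are untestable (p = NA, excluded from the BH
hypothesis count).

Calibration, measured by simulation (equal group means, α = 0.05,
n = 3, 2000 features, means log-uniform over 10–1000): the fraction of
raw p ≤ 0.05 is ≈ 0.055–0.08 depending on the seed, versus ≈ 0.049
with the true α plugged in.  The residual anticonservativeness is the
price of normal quantiles and moment dispersion at three replicates;
t(4) or t(6) quantiles overcorrect to 0.01–0.03.  Fold-change
filtering (below) pulls the realized false-call rate down further.

**Calling.** A feature is called differential when estimated fold
= 2^|log2FC| ≥ 1.5 *and* p ≤ 0.05, both inclusive.  Raw p is the
default for miRNA panels (~150 features), BH-adjusted p for
genome-scale mRNA; both are switchable (`CallThresholds.use_adjusted`).

**MPV pseudo-samples.** Rather than testing against a fitted contrast,
the MPV is materialized: pseudo-replicate i is
round((P1_i/sf + P2_i/sf)/2) with size factor 1, pairing parents by
sorted replicate index (truncating to the smaller count with a warning).
Every comparison then reuses the same two-group code path.  The
rounding and the re-use of parental noise make the F1-vs-MPV test very
slightly conservative; the additive-null simulation in the test suite
bounds the effect.

## Eight-pattern classification

From the three pairwise calls (significance + direction), in order:

1. parents differ, hybrid matches P1, differs from P2 → ELD-P1-high if
   P1 is the higher parent else ELD-P1-low (symmetrically for P2);
2. hybrid significantly above both parents → transgressive-up; below
   both → transgressive-down;
3. all three comparisons significant and the hybrid mean strictly
   between the parents → additive;
4. nothing significant → conserved;
5. any other combination → conserved with an ambiguity flag (kept in
   the output so unclassifiable evidence is never silently forced);
   a tie in parent means with a significant parent test is likewise
   flagged.

Nonadditivity (the MPV-DEM/DEG call) is deliberately independent of the
eight-way label: it is exactly the F1-vs-MPV differential call.

## Simulator: what it plants and what it cannot show

`gen_triad_counts` draws a baseline mean per feature from
10^U(1, 3) and splits the parents of every non-conserved feature by
`effect_log2fc` (default 2, i.e. fold 4): parents at base·2^(±e/2),
ELD hybrids exactly on the matched parent, additive hybrids on the
arithmetic mid-parent, transgressive hybrids at the extreme parent
×2^(±e/2).  The high/low parent is randomized for additive and
transgressive features (either parent can be the stronger allele in a
real cross; it also keeps normalization unbiased, see above).  Class
proportions default to equal eighths; truth tables record the planted
class and mean triple.

Recovery under the default conditions (fold-4 split, α = 0.05, r = 3,
thresholds 1.5/0.05): ELD classes and conserved ≥ 0.91, transgressive
≈ 0.72–0.89, additive ≈ 0.55–0.63.  The additive ceiling is
structural, not a bug: the hybrid sits at the arithmetic mid-parent,
only 1.6-fold from the higher parent, and with α = 0.05, n = 3 the
standard error of a log2 fold change cannot go below
sqrt(2α/(n·ln²2)) ≈ 0.26 even at infinite depth, capping the
probability that the estimated fold clears 1.5 at ≈ 0.64.
Transgressive-down features at the bottom of the mean range (hybrid
mean ≈ 2.5 counts) are similarly power-limited.  Miscalled additive
features land almost exclusively in ELD labels — the same leakage that
real triad studies face, which is worth remembering when interpreting
high ELD tallies at few replicates.

The simulator draws independent NB counts: it does not emulate
feature-feature correlation, GC/length biases, batch effects, or
mapping artifacts, so passing recovery tests here demonstrates the
statistics, not robustness to those real-data complications.

`gen_phenotypes` solves the weaker parent and hybrid means exactly from
the planted MPH/BPH pair (better parent fixed at 100), then adds gamma
noise with the requested CV — means are exact, so noiseless recovery is
exact by construction.  BPH defaults to 0.6×MPH, a typical spread for
biomass traits.  `gen_degradome` plants perfect reverse-complement
target windows and spikes the planted cleavage position on top of a
per-position Poisson background (default rate 0.1), the simplest null
for degradome noise; real degradome background is position- and
abundance-structured.

## Degradome scoring and categories

Duplex scoring: miRNA position i (5'→3') pairs with window position
L−i+1; penalties 0 / 0.5 / 1 for Watson–Crick / G:U / other, doubled
across miRNA positions 2–13.  U and T are interchangeable; N never
pairs; alignments are ungapped (bulged sites are out of scope).  The
default site cutoff is 7.0, the conventional plant cutoff.  The
reported cleavage coordinate is the transcript position paired with
miRNA position 10, and all external coordinates are 1-based inclusive.

Categories with r = reads at the site, M = transcript maximum, median
over positions with ≥ 1 read: 4 if r = 1; 0 if r = M > 1 and unique;
1 if r = M > 1 tied; 2 if 1 < r < M and r > median; 3 if
1 < r ≤ median; sites with r = 0 are dropped.  Raw tag counts are
used (per-million scaling would not change within-transcript ranks).
The median-over-covered-positions choice is documented because a
median over *all* positions (mostly zeros) would make category 3
nearly unreachable.

## Other numerical choices

* Student's equal-variance t-test for the F1-vs-better-parent
  phenotype comparison (Welch behind a flag); zero-variance noiseless
  fixtures return p = NA instead of raising.
* Better parent = larger trait mean for all default traits (biomass
  direction); a direction flag would be needed for traits where smaller
  is better.
* Trait means are pooled over all measured plants per genotype before
  computing MPH/BPH.
* miRNA–target correlations use log2(normalized + 1); Pearson r is
  exactly invariant to affine maps of the log values and only
  approximately invariant to rescaling raw expression (exact in the
  high-expression limit).
* BH adjustment excludes NA p-values from the hypothesis count and
  enforces step-up monotonicity (statsmodels implementation,
  cross-checked against a textbook oracle in the tests).
* Pipeline outputs embed the seed and a config hash; report bodies
  contain no timestamps, so identical config + seed reproduces
  byte-identical output.

## Problem sizes

The shipped simulations are sized for interactive runs: 1000–2000
features × 3 replicates for calibration and recovery, 20 transcripts ×
20 miRNAs for degradome end-to-end checks, 50 plants × 100 seeds for
phenotype recovery.  All scale linearly if larger runs are wanted.
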