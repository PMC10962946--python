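# Methods

This note records the models implemented in `admixwave`, the numerical and
design choices behind them, and what the synthetic-data experiments do and do
not demonstrate.

## The transform

All decompositions rest on the Haar maximum-overlap DWT (MODWT) of a single
evenly spaced signal. Three conventions are fixed throughout and are load-bearing:

* **Circular (periodic) filtering.** The level-j coefficient at position t is
  the circular convolution of the signal with the level-j filter. Circularity
  is the only boundary rule under which the per-level variances plus the
  scaling variance sum *exactly* (to machine precision) to the population
  variance of the signal, which in turn is what makes the genome-wide variance
  and correlation decompositions exactly additive. Boundary (wrapped)
  coefficients are flagged, and a boundary-excluding variance estimator is
  available (`wavelet_variance(..., drop_boundary=True)`), but the additive
  identities hold only for the boundary-inclusive estimator.
* **Maximum-overlap normalization.** Level-j taps are ±2⁻ʲ over support 2ʲ
  (tap sum 0, energy 2⁻ʲ); the level-j variance is the mean of squared
  coefficients over all L positions; all variances are divide-by-L
  ("population") variances.
* **Scale labels.** λ_j = 2^(j−1)·d is the length of each constant stretch of
  the wavelet; the filter support is 2λ_j. The largest level on a chromosome
  is J = ⌊log₂ L⌋ (largest support that fits), and the scaling variance at J
  absorbs whatever broader-scale variance remains when L is not a power of
  two.

Coefficients are computed from sliding window sums (never FFTs), so that a
constant signal yields *exactly* zero wavelet coefficients — identical values
summed in identical order cancel exactly. The scaling variance
mean(ṽ²) − x̄² can round to a value in (−10⁻¹², 0); it is clamped to zero in
that band only.

An independent oracle, `modwt_brute_force`, evaluates any single coefficient
as the dot product of the signal with an explicitly constructed, circularly
wrapped wavelet vector; the test suite checks the fast path against it on
random signals.

## Genome-wide decompositions

Per-scale variances are combined across chromosomes with weights equal to
chromosome length in grid units, in two forms that answer different
questions: **magnitude** (average over only the chromosomes on which the
scale is present — the size of the variance at that scale where it exists)
and **proportion** (absent chromosomes contribute zero; divided by the total
genomic variance, so all components sum to one). The among-chromosome
component ("chrom") is the length-weighted variance of chromosome means; by
the law of total variance, within-chromosome components plus "chrom" recover
the pooled population variance exactly.

For two signals on one grid, the pooled Pearson correlation decomposes as
Cor(x,y) = Σ_λ c_λ ρ_λ + scaling + chrom terms. Here ρ_λ is the pooled
(length-weighted across chromosomes) correlation of level-λ coefficients, and
the weight c_λ is the **geometric mean** of the two signals' per-scale
variance proportions. The geometric mean is not an arbitrary averaging
choice: it is the unique weight for which Σ c_λ ρ_λ collapses algebraically
to covariance over the product of pooled standard deviations, making the
decomposition exact for arbitrary inputs. The "chrom" term uses the weighted
covariance of chromosome means over the same denominators. A scale with zero
pooled variance in either signal has undefined ρ_λ (reported as NaN) and a
zero contribution; this occurs naturally on short chromosomes rather than
being an error.

The per-scale regression (`scale_regression`) fits x-coefficients on
y-coefficients through the origin — wavelet coefficients sum to zero per
chromosome under circular filtering, so an intercept is identically zero —
which makes r exactly equal to ρ_λ and r² the proportion of variance in x at
that scale explained by y.

### Uncertainty

Standard errors come from a weighted delete-one-chromosome jackknife with
block weights m_h = chromosome grid length, M = Σ m_h, h_h = M/m_h:

    θ̂_J = n_b·θ̂ − Σ_h (1 − m_h/M)·θ̂_(−h)
    var  = (1/n_b)·Σ_h (h_h·θ̂ − (h_h−1)·θ̂_(−h) − θ̂_J)² / (h_h − 1)

With equal weights this reduces algebraically to the classical delete-one
jackknife (verified numerically in the tests). CIs are θ̂_J ± 1.96·se (normal
approximation — the tables report 95% intervals, no distributional claim
beyond that). A statistic undefined on any delete-one subset (e.g. a scale
that survives on no remaining chromosome) is reported without a CI. At least
three chromosomes are required.

## Neutral expectations

For a single pulse (proportion α, t generations ago) with no drift, the
two-locus ancestry product on one haplotype is
α·e^(−rt) + α²(1 − e^(−rt)), and α² across haplotypes; the covariance of mean
ancestry over n independent haplotypes is α(1−α)e^(−rt)/n. The expected power
spectrum substitutes this stationary covariance into the double sum over tap
pairs for the squared coefficient. Two details matter for exactness:

* The expectation is computed under the same *circular* filtering as the
  estimator: a tap pair at lag k sees genomic distance k in L−k of its L
  circular placements and distance L−k in the remaining k. Without this wrap
  correction the expectation is visibly biased at the broadest levels.
* The per-generation recombination rate between grid points k bins apart is
  taken as the map distance k·d Morgans (crossover rate ≈ map distance at
  fine scales); a Haldane option, r = (1 − e^(−2m))/2, is available for
  coarse grids.

In the t → ∞ limit the spectrum reduces to white noise, α(1−α)2⁻ʲ/n per
level; the summed expectation over all levels plus scaling approaches
(1 − 1/L)·α(1−α)/n — the 1/L deficit is the usual cost of subtracting the
realized mean in a divide-by-L variance.

A closed-form expectation under drift with time-varying population size is
*not* implemented; instead `expected_power_spectrum` accepts a plug-in
two-locus covariance function, and the forward simulator provides the
Monte-Carlo expectation for any demographic scenario.

## Forward simulator

Diploid Wright–Fisher with soft selection: each generation, 2N gametes are
produced by sampling diploid parents with probability proportional to
fitness and performing one meiosis per chromosome, chromosomes assorting
independently. Ancestry is tracked as tracts — each haplotype is a sorted
breakpoint list partitioning the chromosome into segments alternating between
the two ancestries — so cost scales with ancestry junctions, not loci.
Specifics:

* **Founding.** The pulse is deterministic: exactly round(2Nα) of the 2N
  founding haploid genomes are single full-length introgressed tracts, so
  generation-0 quantities are exact, with no binomial founding noise.
* **Meiosis.** Crossover count ~ Poisson(chromosome map length); positions
  uniform on the genetic map, converted to bp through the map
  (piecewise-linear); no interference; starting haplotype by fair coin.
  Coincident crossover positions (possible on flat map segments) cancel
  pairwise.
* **Selection.** Fitness w = 1 − pS, with p the fraction of the individual's
  selected-locus allele copies that are introgressed (read directly off tract
  labels: introgressed tract ⇒ selected allele), and w = 1 − (1−p)S in
  reversed-direction windows. Selection windows index *hybrid* generations
  (1 = the F1s) and weight those individuals as parents; the founding
  parental generation is exempt. This matters: under a deterministic 50/50
  pulse with S = 1, half the founders are pure-introgressed individuals with
  w = 0, and weighting them would extinguish introgression in a single
  generation rather than producing the intended F1-fitness-0.5 dynamics.
* **Reproducibility.** Each generation uses an RNG substream derived from
  (seed, generation). Per-individual substreams were considered and rejected:
  individuals are processed in a fixed order within a generation, so
  per-generation streams already give bit-reproducible runs at a fraction of
  the RNG overhead.
* **Drift disabled.** The drift-free single-pulse model is sampled by its
  exact equivalent construction: in an infinite population no lineages
  coalesce, so a sampled haplotype is a mosaic whose junctions are
  Poisson(t·G) uniform points with independent Bernoulli(α) founder
  ancestries per segment (adjacent same-label segments merge). This is
  distributionally exact for that model and orders of magnitude faster than
  literal simulation.

## Signal preparation

Interpolation of uneven sites to the grid is linear with constant
extrapolation beyond the terminal sites — the minimal-assumption choice; the
known subtle biases of interpolating physically sampled data onto a genetic
grid are a property of any such pipeline and can be studied here because
`physical_to_genetic_grid` exposes the resampling step explicitly. Grid
positions are midpoints of 0-based half-open windows (unambiguous BED overlap
arithmetic); input site and map positions are 1-based. Recombination-rate
log-transforms are base 10 with non-positive rates floored at the smallest
positive rate present. LD-map calibration caps per-interval 2Nₑr values at
the chosen truncation cutoff, then regresses cumulative capped lengths on
reference genetic lengths *through the origin* (both are proportional to the
same genetic lengths, so an intercept has no physical meaning); the slope
estimates 2Nₑ and rescales the map to Morgans.

## The synthetic genome and the desk-scale experiments

The built-in heterogeneous genome (`default_genome`) has three 32-Mb
chromosomes with a 10-fold broad-scale rate contrast (5 vs 0.5 cM/Mb)
between chromosome halves, crossed by a linear ramp over the middle 20% and
overlaid with a fixed ±5% per-50-kb multiplicative jitter. Two design points
are deliberate. A hard block boundary would concentrate *all* fine-scale rate
wavelet power at the single position where selection also steps the ancestry
profile, manufacturing a spurious fine-scale rate–ancestry correlation (a
neutral-run control shows no such bias, confirming the co-location origin);
the ramp removes that concentration and the jitter distributes fine-scale
rate power along the chromosome as real maps do. Second, the jitter amplitude
is kept modest because fine-scale rate variation couples *genuinely* to early
selection: escape from linked selected alleles depends on local map length at
every scale, so windows with locally higher recombination retain slightly
more introgression. Diagnostics showed this legacy is independent of the
number of selected loci and proportional to the jitter amplitude; at ±30%
jitter in a large population it is individually detectable (a real, if small,
fine-scale correlation), whereas the regime the selection-timing analyses
describe is one where drift noise dominates any fine-scale legacy. The ±5%
default, with 2N = 2,000 observed at generation 200, sits firmly in that
regime while leaving the broad-scale imprint of early selection unmistakable.

Problem sizes used by the end-to-end tests, chosen as desk-scale versions of
the study conditions: bottleneck-vs-constant comparison on a 10-Morgan
3-chromosome genome (3.4/3.3/3.3 Morgans — near-equal so the broadest scales
exist on all chromosomes) with 2N = 2,000, 100 generations, 20 replicate
pairs; selection experiments on the synthetic genome above with S = 1 over
500 loci (generation 20) or 5,000 loci (highly polygenic variant, selection
in generations 1–10 only, observed at generation 200), 20 replicates, 50-kb
physical grid; drift-free theory checks at L = 512 bins of 2⁻¹⁰ Morgans with
n = 100 haplotypes and 200 replicates.

## What the generator emulates, and what it does not

The simulator reproduces the joint action of recombination, drift and
additive polygenic selection on tract structure after a single pulse. It does
**not** model mutation, crossover interference, dominance or epistasis,
continuous migration or hybrid-zone geography, sex chromosomes, or local
ancestry *inference* — simulated ancestry is known exactly, so passing tests
say nothing about HMM calling error, reference-panel bias, or the
detection biases (e.g. against short fragments in high-recombination
regions) that real call sets carry. Empirical-scale results that depend on
real genomes and call sets are outside what the synthetic experiments can
establish.

## Known limitations

* Exact additivity is tied to circular filtering; users wanting
  reflection-boundary MODWTs will not find them here.
* The correlation-decomposition weight c_λ makes the decomposition exact but
  is one of several defensible "average proportion of variance" definitions;
  alternative weightings would redistribute contributions across scales
  without changing ρ_λ.
* The neutral theory covers a single pulse without drift; drift, multiple
  pulses and continuous migration are delegated to the simulator's
  Monte-Carlo path.
* Jackknife CIs use a normal approximation and chromosome-level blocks; with
  few chromosomes the intervals are themselves noisy.
* With strong fine-scale recombination heterogeneity, early selection leaves
  a small genuine fine-scale rate–ancestry correlation (see above); analyses
  asserting a strictly broad-scale legacy should check the fine-scale rate
  variance of their map first.
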