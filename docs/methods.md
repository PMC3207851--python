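# Methods

This note documents the models implemented in `heterochiasma`, the
assumptions they make, the tunable parameters and their defaults, and the
numerical choices that matter. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The meiotic model

Crossovers form on the **bivalent** (the paired homologs). The gamma renewal
model places them so that inter-CO genetic distances are
Gamma(shape ν, rate 2ν) Morgans: the mean spacing is 0.5 Morgan, hence an
intensity of 2 COs per Morgan, which is forced by the definition of genetic
distance. ν = 1 makes the process Poisson (no interference); ν > 1
suppresses close pairs and under-disperses counts (positive interference);
ν relates to the counting model's parameter by ν = m + 1.

A gamete inherits each bivalent CO independently with probability ½
(**thinning** — each CO involves two of the four chromatids), so the gametic
process has intensity 1 per Morgan and the expected gametic CO count equals
the genetic length. In a backcross, each progeny genotype reads out one
gamete of the F1: a homozygous call (`A`) means the gamete carried the
recurrent-parent allele, a heterozygous call (`H`) the donor allele, and
every `A↔H` switch along a chromosome marks a crossover.

**Stationary start.** The simulator draws the first bivalent CO from the
equilibrium (length-biased residual) distribution, with CDF
`F_e(x) = x·S_ν(x)/μ + F_{ν+1}(x)` (μ = 0.5; same rate for both gamma
terms), so the expected CO count on *any* sub-segment of length ℓ is exactly
2ℓ. This matches the fitting model; a fixed-origin renewal start would
distort lengths near chromosome ends. Sampling inverts `F_e` on a cached
8192-point grid (inversion error < 10⁻³ Morgan, negligible against
Morgan-scale spacings).

**Assumptions / non-goals.** Chromosomes are independent (no
cross-chromosome interference); there is no chromatid interference beyond
the ½-thinning; gene-conversion tracts are not modeled; marker order is
taken as given.

## Genetic-map estimation

Per adjacent-marker interval, `r = N_r/N` over plants with complete data at
both markers, `se² = r(1−r)/N`, CI `r ± 1.96·se`. Chromosome length comes
from two estimators:

1. **Interval sum**: Σ of Haldane distances `d = −½ ln(1−2r)`. The Haldane
   map function assumes no interference within an interval; at the marker
   densities used here (intervals ≪ 0.1 M) the correction is second order.
2. **Switch counting**: the mean per-plant number of `A↔H` switches over the
   non-missing call sequence, treating missing calls as transparent. Its
   estimator variance is the per-plant count sample variance divided by the
   plant count. A double CO hidden inside a missing run (or inside a single
   marker interval) is necessarily uncounted; this is documented, not
   corrected — which is also why raw switch counts slightly exceed the
   genetic length when genotyping errors are present (each isolated flip
   fakes two switches; singleton QC exists to flag exactly those).

The male/female ratio `f = L_m/L_f` uses the Gaussian approximation in which
the relative variance of the ratio is the sum of the two relative variances.
Map-length equality is tested by Welch's two-sample t-test on per-plant
counts (the unequal-variance default of standard statistical software).

**Truncation analysis** removes a physical fraction per chromosome end
(default 15% and 25% per end, i.e. −30% and −50% of the chromosome) and
keeps only markers — hence only genetic intervals — wholly inside the
central region. The per-CO-class loss table compares each class's observed
CO loss with the class-independent expectation (the genetic fraction
removed); positive interference makes multi-CO plants lose more, because
their COs sit disproportionately near the ends.

## Segregation distortion and map correction

Under no distortion each parental allele has frequency 0.5. The per-marker
band has half-width `2.33·s` with
`s² = 1/(4(N_C+N_L))`; 2.33 is the one-sided 1% normal quantile, so the
two-sided null exceedance of the band is ≈2% (≈1% per side). Bands vary
marker-to-marker with the number of valid calls.

Selection is modeled as post-meiotic gamete filtering: retention probability
`s₁` for the unfavored allele at locus L1, `s₂` at L2, `s₁·s₂` jointly (no
epistasis). Single-locus selection rescales recombinants and
non-recombinants equally — every interval's `r` stays unbiased (verified by
simulation in the test suite). Two linked selected loci do bias intervals
between them. For each interval (Mᵢ, Mᵢ₊₁) between L1 < Mᵢ < Mᵢ₊₁ < L2, the
three consecutive intervals defined by the four loci determine the 16
four-locus haplotype frequencies under the Haldane (independence) model;
selection re-weights and re-normalizes them. Fitting the observed 16-class
counts by Pearson chi-squared (expected-count weights; classes with expected
0 and observed 0 contribute 0; expected 0 with observed > 0 rejects the
parameters) recovers the bias-free middle rate. Summing the per-interval
chi-squareds and minimizing over (s₁, s₂) — a 0.05-step grid by default,
refined by Nelder–Mead — infers the selection coefficients. When an interval
endpoint coincides with a selected locus the class model collapses to 8 (or
4) classes; the implementation handles the collapse rather than assuming
distinctness. Intervals outside (L1, L2) keep their naive estimates.

Note that with the loci in linkage, the *marginal* allele-ratio estimate of
`s` at each locus is biased toward 1 by selection at the other locus; the
joint fit corrects this, and the test suite asserts exactly that
relationship.

## Interference estimation

The gametic CO process is the ½-thinned stationary gamma renewal. Its gap
density is the geometric gamma mixture
`g(x) = Σ_{j≥1} ½ʲ · GammaPDF(x; jν, 2ν)` (mean gap 1 Morgan), with survival
`S_g`; the stationary first-event density is `S_g(x)` itself, the final
segment contributes `S_g(L − x_k)`, and a zero-CO gamete contributes
`∫_L^∞ S_g(t) dt`, for which the closed form
`∫_L^∞ S_{a,b}(t) dt = (a/b)·S_{a+1,b}(L) − L·S_{a,b}(L)` is used instead of
quadrature. The series is truncated at J = 60 terms (tail < 10⁻¹⁸); at ν = 1
the whole construction collapses to the unit-intensity Poisson process and
the tests assert agreement with its closed-form likelihood to 10⁻¹⁰.

Three likelihood routes are provided, in increasing fidelity to marker data:

* **`midpoint`** — each switch is imputed at the midpoint of its bracketing
  non-missing marker pair and the position likelihood is evaluated directly.
* **`censored`** — each CO is integrated over its bracketing interval by a
  chained Gauss–Legendre quadrature (5 nodes per interval).
* **`pattern`** (default) — the censored base plus first-order terms for
  crossovers hidden by parity: a switch-free observation segment of genetic
  span d may conceal a CO *pair*, with probability weight
  `c(d) = ∫₀^d (d−t) g(t) dt` times the local pair-density ratio R at the
  segment midpoint given the neighboring observed COs; a switch segment may
  conceal a *triple* (one visible switch), with relative weight `T3(d)/d`,
  `T3(d) = ∫₀^d g(u) c(d−u) du`. Corrections multiply across segments.

The pattern terms matter because parity censoring removes precisely the
shortest inter-CO gaps, which a position-only likelihood reads as
interference: on interference-free data scored at 50 markers per 1.4 Morgan,
midpoint fitting is biased to ν ≈ 1.2 and its CI essentially never covers 1,
while the pattern likelihood is calibrated (the acceptance suite measures
both the ν ≈ 1 recovery and CI coverage). At ν = 1 the pattern likelihood
agrees with the exact Poisson pattern probability
`e^{−L} · Π sinh(d_switch) · Π cosh(d_free)` up to the neglected ≥4-CO
terms. Marker genetic coordinates are estimated from the data itself
(cumulative Haldane distances), exactly as a real analysis must.

`fit_nu*` maximizes over log ν on [0.05, 50] (bounded scalar search,
xatol 10⁻⁵); the 95% CI is the profile-likelihood set
`{ν : ℓ(ν) ≥ ℓ_max − 1.92}` (χ²₁ cutoff), clipped to the search bounds.
Evaluations use 4096-point grid tabulations of `g`, `S_g` and `c` per ν
(linear interpolation; for ν < 1 the density diverges integrably at 0 and
the grid is evaluated half a step off the origin). Fits are refused with
fewer than 2 total COs. The Poisson goodness-of-fit test is a Pearson
chi-squared on count classes with λ estimated from the sample mean, upper
classes pooled until every expected count is ≥ 5, and df = classes − 2.

The model's own gametic count distribution (for cross-checks) is computed by
numeric convolution of the first-event and gap densities on a grid,
integrated against the censoring survival.

## Features, hot/cold, multiple testing

Heterochromatin is inferred from euchromatic histone-mark presence
(H3K4me3/H3K27me3, either-mark indicator) averaged in 2 kb windows: an
interval is heterochromatic iff its mean presence is strictly below 0.2.
Arm mean rates weight each euchromatic interval by its bp span; an interval
is *hot* iff its 95% rate-CI lower bound exceeds the arm mean, *cold* iff
the upper bound falls below it. Male/female interval comparison uses the
two-proportion z-test `z = (r_m − r_f)/√(se_m² + se_f²)` by default
(Fisher's exact is available by flag), with Benjamini–Hochberg control at
q = 0.05 applied genome-wide across all tested intervals (statsmodels'
step-up implementation, cross-checked against brute-force enumeration in the
tests). Rate-feature association is ordinary least squares of cM/Mb on the
feature with heterochromatic intervals excluded; positional gradients are
Pearson correlations of a feature against distance from the centromere,
per arm.

## Chromosome scaling

Per-bivalent CO number is twice the genetic length in Morgans. The threshold
model `L_G = 0.5 + a(L_Mb − L_thr)` encodes the obligate CO: every
chromosome gets 0.5 Morgan (one CO per bivalent), and physical size above
`L_thr` adds length linearly. It is fitted by inverse-variance-weighted
least squares — linear in (slope, intercept), with
`L_thr = (0.5 − intercept)/a`, so `L_G = 0.5` at `L_Mb = L_thr` by
construction — using per-chromosome variances equal to the per-plant
CO-count sample variance over the plant count. The Li–Freudenberg special
case fixes `L_thr = 0` (one free parameter); its chi-squared survival at
dof = points − 1 is the test of that model. The free fit's chi-squared never
exceeds the constrained one (nesting), and with equal variances the weighted
fit reduces to OLS; both are property-tested.

## The synthetic-data generator

Defaults mirror the study design: two backcross populations of 1,505 / 1,507
plants, 380 markers allocated across five chromosomes proportionally to
Arabidopsis physical sizes (30.43, 19.70, 23.46, 18.59, 26.98 Mb), per-sex
genetic lengths matching literature per-bivalent CO means for the Col×Ler
cross (male chromosome 1 simulated at its selection-corrected 1.59 M truth),
interference shapes per chromosome and sex in the literature 2.5–4.1 range, 2% missing calls, 0.1%
genotyping errors, and male-chromosome-1 two-locus selection with retention
0.67 (recurrent allele at 7,267,270 bp) and 0.37 (donor allele at
26,188,466 bp). Feature tracks rise (GC, gene density) or fall (TE density)
from centromere to telomere with Gaussian noise; the CpG ratio has no
positional trend; euchromatic-mark presence drops to ~0.05 within ±1.5 Mb of
the centromere. The genetic↔physical map is linear by default and
piecewise-linear via `map_knots` to emulate end-loaded male maps.

What the generator does **not** emulate: real fine-scale hotspot structure
(rates are homogeneous within the model's coordinate choice), NOR regions,
linkage between feature tracks and the CO landscape beyond shared position,
and non-independent genotyping errors. Passing tests therefore demonstrate
estimator correctness under the stated model, not robustness to every
artifact of real genotyping.

## Problem sizes and determinism

Test and acceptance runs use deliberately scaled simulations chosen for
statistical resolution: 25 replicate seeds for estimator-calibration checks
(2,000 and 1,505 gametes per replicate), 200 seeds for map-length
unbiasedness (800 plants at 1,000 markers, where discretization bias is far
below the Monte-Carlo SEM), 10⁵ gametes for the selection-unbiasedness
lemma, and 3–5·10⁴ replicates for Monte-Carlo count-distribution oracles.
All simulation randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; the pipeline spawns per-stage child streams
from one master seed, so a rerun with the same configuration is
byte-identical.

## Known limitations

* The pattern likelihood's hidden-CO corrections are first order (≤ 3 COs
  per observation segment); at marker spacings ≫ 0.05 Morgan or ν ≪ 1 the
  neglected terms grow.
* The distortion correction assumes exactly two selected loci per
  chromosome, no epistasis, and the Haldane model within the four-locus
  system; it reports both marginal and jointly fitted coefficients because
  the two differ under linkage.
* Switch counting cannot see double COs inside one marker interval or a
  missing run; map lengths from sparse or gappy data are lower bounds in
  that respect.
* Hot/cold calibration (~5% flags under homogeneity) treats the arm mean as
  fixed, though it is itself estimated; with few intervals per arm the flag
  rate deviates slightly from nominal.
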