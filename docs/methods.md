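# Methods

## Problem setting

All carriers of a founder mutation descend from a single chromosome that
existed g generations ago. Each sampled carrier chromosome reaches that
founder through g meioses; each meiosis can recombine the mutation-bearing
segment against the population background, and each marker can mutate. The
observable is therefore the decayed sharing of the founder's marker alleles
among present-day carriers, compared against control chromosomes, and g is
the parameter of interest.

## Marker maps

Physical positions convert to genetic distance at a constant rate (default
1 cM/Mb) and to recombination fractions through the Haldane map function
θ = (1 − e^(−2d))/2 (d in Morgans), with a linear no-interference
approximation (θ = d, capped at 0.5) selectable; at the sub-10-cM scales of
founder-mutation maps the two differ by well under 2%. Two θ views are kept:
marker-to-locus (used by the single-marker estimator) and per-interval
between inward neighbours (used by the outward likelihood scan, and by the
simulator). A per-interval override table accepts empirical estimates.
Coordinates are 0-based bp; markers are points; a marker exactly at the
locus position is rejected.

Default per-generation marker mutation rates by type, overridable per
marker: SNP 1e-8, dinucleotide STR 5e-4, tetranucleotide STR 2e-4, other
1e-5. These are order-of-magnitude field defaults; at the tens-of-generations
time scales of interest, marker mutation is a second-order effect for SNPs
and matters mainly for STRs.

## Single-marker estimator

δ = (p_D − p_N)/(1 − p_N) and g = ln δ / ln(1 − θ). p_N comes from direct
allele counting in control chromosomes, p_D from probability-weighted
counting over carrier haplotype distributions. Estimates are undefined when
δ ≤ 0 (the associated allele no more frequent in carriers than controls) and
flagged unstable within 0.1 cM of the locus, where θ is too small to
support a believable estimate; unstable and undefined markers are excluded
from the across-marker median (midpoint convention for even counts).

### Growth correction

Under a growing population the intra-allelic genealogy shares early
branches, so a single early recombination can strip the ancestral haplotype
from a large clade; the distribution of the observed excess is left-skewed
and the typical (median) raw estimate understates g. The correction is
additive: ĝ_corrected = ĝ + Δ(θ, r, ĝ), and when applied to an interval it
shifts both bounds equally.

Two modes:

* **table** — apply a user-supplied Δ directly (e.g. to reproduce published
  corrections exactly).
* **montecarlo** — calibrate Δ against the package's own branching
  simulator: find, by integer bisection with common random numbers and
  linear interpolation between bracketing integers, the true age g* whose
  median simulated estimate (≥1000 replicates at the marker's θ, the
  population's r, the study's carrier count, and the allele's pool
  frequency) equals the observed ĝ; Δ = max(0, g* − ĝ). As r grows the
  genealogy approaches a star and Δ → 0.

Two caveats are inherent to median-matching at small carrier counts. With
n carriers the observed p_D is quantized to multiples of 1/n, and at close
markers the median simulated estimate is exactly 0 over a wide range of true
ages (most replicates show no decay at all); the bisection then returns the
smallest bracketing age and Δ = 0 — the correction is unidentifiable from
such a marker. Conversely, a marker whose raw estimate exceeds every
attainable median (possible when δ̂ is small by chance) cannot be
calibrated; it is flagged unstable and excluded from medians. The
calibration simulator marginalizes the branching process to (intact copies,
total copies) by Poisson thinning — the marginal law is identical to the
full chromosome-level simulation — samples min(n, N) chromosomes per
replicate, and switches to expectation dynamics above 10^9 copies, where
demographic fluctuations are negligible.

## Multi-marker likelihood

For one candidate mutation-bearing haplotype at age g, each flank of the
locus is scanned outward as a two-state chain. The ancestral segment
survives interval j (recombination fraction θ_j) across g meioses with
probability (1 − θ_j)^g; recombination is absorbing, and all markers beyond
the first lost interval emit independently at population frequency p_N.
While intact, marker i emits its ancestral allele with probability
(1 − μ_i)^g; the complementary mass goes to the alleles reachable by a
single mutation — the other allele for a SNP (shared equally among the
others for a generic multi-allelic marker), the one-step neighbours under
the stepwise model for an STR (all of it to the single neighbour at a range
bound). Emissions sum to 1 over alleles at every (marker, g). The two
flank likelihoods multiply, and with recurrence probability π the total is
(1 − π)·L_descent + π·Π p_N (a carrier chromosome that is an independent
mutation event looks like background). Summing over each carrier's
haplotype distribution with its probabilities and over carriers gives the
data log-likelihood.

Modelling choices, isolated behind the transition/emission functions:

* Double recombination back onto an ancestral-matching background is
  captured only through p_N (absorbing chain). Exact at linkage
  equilibrium; an approximation when the background has LD.
* Marker mutation is at-most-once per lineage and only on the intact
  branch; mutations on recombined segments are absorbed into p_N. Both are
  second-order at these time scales.
* θ is interval-based (locus→first marker, then marker→marker), matching
  the outward scan's geometry.

The estimate is a direct search over an integer grid (default 0–500), so
reported ages are integers. The 95% confidence interval is every grid point
within 1.92 log-units of the maximum (χ²₁/2); the 1-LOD convention
(ln 10 ≈ 2.303) is available. Interval bounds on the grid edge are flagged
and rendered "≤ low". Ties at the maximum resolve to the smallest age,
flagged. The growth correction is applied additively to the estimate and
both bounds afterwards; the likelihood itself contains no growth model.

An exhaustive oracle that enumerates every recombination placement (first
event per interval per meiosis) and every first-mutation placement on small
maps agrees with the scan to better than 1e-10 (tested for ≤3 markers,
g ≤ 5, SNP and STR, with and without recurrence).

## Haplotype uncertainty

Phased input passes through unchanged. Unphased genotypes are phased by an
enumeration EM (uniform initialization, cap 500 iterations, tolerance 1e-8,
deterministic, log-likelihood asserted non-decreasing) over windows of ≤12
markers; the mutation site enters as an anchor column heterozygous in
carriers, so each phase configuration identifies the mutation-bearing
chromosome. This is a stand-in for PHASE's coalescent-informed model and is
adequate for small windows; a reader for PHASE v2 pair listings is provided
for users with real PHASE output. Per-carrier distributions merge duplicate
haplotypes, prune entries below 1e-6, and renormalize. Cases and controls
are phased jointly by default (logged as an assumption).

The ancestral (mutation-associated) allele at each marker is the
probability-weighted mode across carrier distributions; ties prefer the
allele most enriched in carriers (largest p_D/p_N), then the smallest
label. Inference is reliable at close markers (simulation: correct at
θ < 0.01 in ≥95% of replicates at moderate age) and degrades with distance
as the ancestral segment erodes.

## Demography

r = (p1/p0)^(1/g), g = (year1 − year0)/years_per_generation (default 25),
kept fractional. r is the multiplicative per-generation fold. Constant
growth only; fluctuating or piecewise schedules are out of scope.

## Synthetic data generator

The generator is the validation instrument: a founder chromosome drawn from
a control-like background pool (its alleles define the ancestral
haplotype), evolved for g generations. Per meiosis, each interval (locus
flank and inter-marker) recombines with probability θ_interval, at most
once, and each recombination switches the chromosome's remainder to a fresh
pool draw — no explicit diploid pedigree, matching the
background-linkage-equilibrium assumption of both estimators. Markers
mutate per generation (SNP flip; STR ±1 step reflecting at range bounds).
Genealogy modes: **star** (independent lineages of depth exactly g — the
estimators' null model) and **branching** (Poisson(r) Galton–Watson,
conditioned on survival by full resampling, cap 10,000 attempts; carriers
sampled without replacement from the survivors, an error if fewer than
requested). Controls are i.i.d. pool draws; unphased genotypes can be
emitted by pairing each carrier chromosome with a pool draw. Ground truth
records the ancestral haplotype, the lineage-count trajectory, each sampled
chromosome's intact core extent per flank, and mutation counts. Seeded runs
are bit-reproducible.

Default study conditions mirror the desk-scale validation scenes: 19 SNP
markers evenly spanning 12.3 Mb at 1 cM/Mb with the locus midway between
the central markers, pool allele frequencies uniform on (0.2, 0.8), 16
carriers and 109 control individuals, g = 17, r = 1.5 — the shape of the
colorectal-cancer dataset the methods were originally applied to. What the
generator does not emulate: background LD (pools may be haplotype lists,
but the default is linkage equilibrium), genotyping error, missing data,
ascertainment through affection status, and fluctuating growth. Passing
tests therefore demonstrate correctness of the estimators under their own
assumptions plus the branching-genealogy stress, not robustness to those
real-data features.

## Calibration findings

Measured with this package's own simulator (100 seeded replicates per
condition):

* Given the true ancestral haplotype on star-genealogy data, the
  likelihood-ratio CI covers the true age ~95% of the time — the estimator
  is correctly calibrated under its model.
* Inferring the ancestral haplotype from the same 16–50 carriers costs
  roughly 10–20 points of coverage: the weighted mode conditions the model
  on the data, and far markers are often mis-assigned once the ancestral
  segment has decayed.
* Under a branching genealogy at r = 1.5 the CI covers the truth in only
  ~65–75% of replicates, and the median estimate sits a few generations
  below truth. This is the expected behaviour of an independence
  likelihood on correlated lineages — the variability of the genealogy is
  not in the model — and is the reason coalescent-based methods report
  wider intervals and older estimates. The additive growth correction, as
  calibrated by median-matching on this SNP scene, is too small to restore
  nominal coverage (see the correction caveats above).

## Numerical notes

Likelihoods are computed in probability space per haplotype (products over
at most tens of markers) and logged once; impossible haplotypes yield −inf
cleanly. Carrier mixtures use log-sum-exp. The likelihood curve is
vectorized over the whole integer grid. Zero-probability carriers over the
entire grid abort with the carrier names. The EM phaser raises if its
log-likelihood ever decreases. Degenerate inputs (empty controls, empty
distributions, reversed intervals, non-growing populations for the
correction) raise typed errors naming the cause.

## Validation problem sizes

The shipped checks use: 100 replicates for coverage and calibration
experiments (16–2000 carriers as the condition dictates), 10,000
unconditioned Galton–Watson replicates for mean/extinction checks, ≥1000
replicates per Monte-Carlo correction evaluation, and exhaustive
enumeration up to 3 markers × 5 generations for the likelihood oracle.
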