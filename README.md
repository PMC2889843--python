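# founderage

Estimate the age of a founder mutation — the number of generations since a
disease variant's ancestral chromosome — from case–control marker data
flanking a known disease locus.

When all carriers of a mutation descend from one founder, they initially
share that founder's marker haplotype. Recombination and marker mutation
erode the shared segment at a rate governed by the genetic map, so the
remaining extent of sharing carries a clock. `founderage` implements two
erosion-based estimators plus the demographic arithmetic needed to interpret
them, and ships a forward-in-time simulator with known ground truth to
validate them.

## Methods

**Single-marker decay.** For a marker at recombination fraction θ from the
locus, with the mutation-associated allele at frequency p_D on carrier
chromosomes and p_N on control chromosomes, the allelic excess

δ = (p_D − p_N) / (1 − p_N)

decays in expectation as (1 − θ)^g under a star genealogy, giving the
maximum-likelihood age **g = ln δ / ln(1 − θ)**. Estimates are computed per
marker and summarized by their median; markers with δ ≤ 0 are undefined, and
markers closer than 0.1 cM are flagged as unstable. Because a growing
population's intra-allelic genealogy is not a star, the typical raw estimate
understates the true age; an additive correction (a function of the
per-generation growth rate r) is applied, either from a user-supplied table
or calibrated by Monte-Carlo simulation of the branching genealogy.

**Multi-marker likelihood (modified Goldgar method).** Scanning outward from
the disease locus along each flank, the ancestral segment survives each
inter-marker interval with probability (1 − θ)^g; once lost, outer markers
emit at population frequencies. Intact markers emit the ancestral allele
with probability (1 − μ)^g, with the complementary mass assigned by a
single-mutation model (SNP flip, or stepwise ±1 for microsatellites), and a
recurrence probability π mixes in an all-background term. Carriers with
uncertain phase contribute a probability-weighted sum over their candidate
mutation-bearing haplotypes (from PHASE-style output or the built-in EM
phaser). The age is the integer-grid maximum-likelihood estimate with a
likelihood-ratio 95% confidence interval (Δlog L ≤ 1.92); the growth
correction is added to the estimate and both interval bounds.

**Demography.** Growth rates come from census pairs via p1 = p0·r^g with g
in (possibly fractional) generations at 25 years per generation; ages
convert to calendar years the same way.

## Worked example

Simulate a mutation 17 generations old in a population growing 1.5-fold per
generation — 16 carrier chromosomes and 109 controls typed at 19 SNP markers
spanning 12.3 Mb at 1 cM/Mb — then estimate its age by both methods:

```yaml
# config.yaml
seed: 42
out_dir: out
simulate:
  g_true: 17
  r: 1.5
  n_cases: 16
  n_controls: 109
  n_markers: 19
  span_bp: 12300000
  genealogy: branching
methods: [single_marker, goldgar]
growth_rates: [1.5]
correction_mode: montecarlo
grid: [0, 120]
```

```
$ founderage -v all config.yaml
INFO founderage: simulated dataset: g_true=17 r=1.5 16 cases, 109 controls, 19 markers
INFO founderage: inferred ancestral haplotype: BBBABAABABBAAABBBBA
INFO founderage: single-marker r=1.5: median 11.36 over 17 markers (2 excluded)
INFO founderage: goldgar r=1.5: g_hat=13 CI [8, 20] flags=()
              method  growth_rate  g_raw  g_corrected  ci_low  ci_high  interval_width
single_marker_median          1.5  11.36         13.0     NaN      NaN             NaN
             goldgar          1.5  13.00         13.0     8.0     20.0            12.0
```

The single-marker median over the 17 markers with a defined, stable estimate
is 11.36 generations (two markers were excluded because the associated
allele was no more frequent in carriers than in controls). The multi-marker
likelihood estimates 13 generations with a 95% interval [8, 20] — covering
the true age of 17 and illustrating the downward pull of the shared early
genealogy that the growth correction addresses. Per-marker tables, the
log-likelihood curve, the simulated dataset, and the report are written
under `out/`; rerunning with the same config is bit-identical.

The same pipeline runs on real data: point `input_dir` at a dataset
directory (marker map TSV, haplotype/genotype TSVs — see
`founderage.synthetic_data.write_dataset` for the layout) instead of the
`simulate` block.

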