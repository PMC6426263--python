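# Methods

This note documents the models, estimators, defaults and deliberate design
choices behind the package, and what the synthetic-data validation does and
does not establish about real data.

## Selection scan

### FST and branch lengths

Per-SNP FST defaults to the Hudson estimator in the Bhatia et al. (2013)
ratio form,

    N = (p1 − p2)² − p1 q1/(n1 − 1) − p2 q2/(n2 − 1),
    D = p1 q2 + p2 q1,

with haploid sample sizes n. It is nearly unbiased and robust to unequal
sample sizes, which matters when the focal cohort is much larger than the
reference panels. The Reynolds (1983) coancestry estimator is available as
`estimator="reynolds"` (implemented in the mean-square form
num = MSP − MSG, den = MSP + (n_c − 1)·MSG for allele-frequency data)
because the original branch-statistic literature used it. Whichever is
chosen is written into every run header. Window-level FST is always the
ratio of summed components, never the mean of per-SNP ratios. Per-SNP
estimates are clamped to [0, 1 − 1e−12] so T = −log(1 − FST) stays finite
and non-negative; sites where any of the three pairwise estimators is
undefined (jointly monomorphic pairs, n < 2) are dropped from windows.

### Windows, outliers, index SNPs

The scan averages per-SNP PBS (not window-level FST first) in windows of 20
usable SNPs; "overlapping by 5 SNPs" is read as *consecutive windows share
5 SNPs*, i.e. stride 15, and a `shared` parameter allows the alternate
stride-5 reading. Windows never span chromosomes and the trailing partial
window is dropped. At array-like density (~1 SNP per 2.9 kb) a 20-SNP
window spans roughly 50 kb. Outliers are windows at or above the empirical
99.9th percentile (linear-interpolation quantile) of window means; with
fewer than ~1000 windows the percentile is coarse and a warning is issued.
The index SNP of a region is the site with maximal per-SNP PBS, ties broken
toward the smaller position.

### Neutral null and empirical p-values

The null comes from a single-locus structured-coalescent simulator speaking
the ms dialect. Rates follow the ms bookkeeping exactly: with deme sizes
x_i relative to N0, a lineage pair in deme i coalesces at rate 1/x_i per
scaled unit, each lineage migrates i→j at rate M_ij/2 (M = 4·N0·m), and
mutations fall as Poisson(θ·L/2) on the total tree length — the scale on
which E[pairwise TMRCA] = 1 and E[S] = θ·Σ 1/i. Exponential growth is
handled by analytic inversion of the integrated hazard. `-s 1` gives
exactly one segregating site per replicate. Replicates where any pairwise
FST is estimator-undefined (derived allele private to one sample) are
redrawn and counted; the observed scan drops such sites identically, so
observed and null are conditioned the same way.

The published command for the three-population neutral model leaves its
numeric growth/size/migration entries as placeholders, so the package
requires explicit numbers and ships a documented default: three demes
(focal study population, reference/outgroup, sister group), joins at 0.025
(sister→focal) and 0.06 (reference→focal), recent focal growth (α = 50 from
t = 0.002), an ancestral size change to 0.5 at t = 0.1, and migration
switched on at t = 0.002 with M₁₃ = 31.0 and M₃₁ = 4.46 — obtained from the
ancestry-proportion helper M = −2·ln(1 − a)/τ with a ≈ 0.30 (sister-related
ancestry in the focal population) and a ≈ 0.05 over the contact window
τ = 0.023. Any other model can be supplied as an ms command string.

Window-level nulls average consecutive groups of 20 independent replicate
values. Because the null model has no recombination, this ignores the LD
between the 20 SNPs of a real window and is therefore *anti-conservative*
for window p-values; this mirrors the single-site design of the original
simulation strategy and is flagged here as a limitation.

Empirical p-values use the pseudo-count form p = (1 + #{null ≥ obs})/(1 + n),
one-sided upper tail, significant at p < 0.05. With a single segregating
site the null statistic is discrete (allele-count configurations; the
largest atom is ~17% at 50 haploids per population), so these p-values
contain atoms and are conservative, never anti-conservative. Calibration
checks therefore use the randomized probability-integral transform
(`empirical_pvalue(..., rng=...)`), which is exactly uniform under the
null; reported pipeline p-values keep the conservative form.

## Haplotype statistic (EHH / iHH / xpEHH)

EHH at extension x is the probability that two random haplotypes identical
at the core are identical at every site from the core to x —
Σ_h C(c_h,2) / Σ_a C(c_a,2), the site-homozygosity-normalized EHHS of
Sabeti/Tang as implemented in rehh. The normalization makes EHH(0) = 1
exact and prevents the core site's own allele frequency from masking the
decay contrast (an unnormalized variant systematically *penalizes* the
focal population at intermediate-frequency sweep cores). Decay curves are
truncated at the first site with EHH < 0.05; cores whose extension reaches
a chromosome edge or crosses an inter-site gap > 200 kb before the cutoff
are flagged and excluded from standardization (rehh-like defaults). iHH is
the two-sided trapezoidal integral over physical distance by default, or
genetic distance when a map is supplied; the unit in force is logged.
xpEHH raw values are computed as ln iHH_A − ln iHH_B (difference of logs,
so that swapping populations negates the statistic bit-exactly) and
standardized globally over unflagged cores — not within frequency bins,
matching the common default. The focal population carries the positive
sign; the screening threshold is +2. The comparator defaults to the PBS
sister group and is configurable.

## f3 admixture test

The per-site statistic is (c − a)(c − b) − c(1 − c)/(n_c − 1); the
correction removes the binomial sampling variance of the target's
frequency, making the estimator unbiased for the population-level f3 (this
is validated by simulation rather than asserted). Sites missing a
frequency in any member are dropped test-wise. Standard errors use a
weighted delete-one-block jackknife (Busing-style weighting by block size)
over contiguous physical blocks, default 5 Mb; the pipeline shrinks blocks
with a warning when the input spans fewer than ten. Z ≤ −3 marks highly
significant gene flow. The scan covers every (target; sourceA, sourceB)
combination, sources unordered; the statistic is exactly symmetric in the
sources and invariant to population listing order.

## Kinship and pruning

IBD probabilities use method-of-moments on aggregated IBS counts with
finite-sample-corrected expected proportions (unbiased falling-factorial
estimators of the allele-frequency monomials — the PLINK `--genome`
derivation), truncated to [0, 1] and renormalized. Frequencies come from
the same population subset being tested; pooled-panel frequencies inflate
apparent relatedness under structure and are deliberately not the default.
Inbreeding is F = (O_hom − E_hom)/(L − E_hom) with the unbiased per-site
expected heterozygosity 2pq·m/(m − 1). Family networks connect pairs with
Φ ≥ 0.1 (second degree or closer; 0.0625 would admit third-degree pairs);
pairwise tables written for display keep PI_HAT > 0.05. Pruning removes
the node of maximum degree repeatedly until no edges remain; because an
interactive procedure is not reproducible, ties break deterministically by
larger summed incident Φ, then smallest id. On star-shaped families this
removes one individual per family (the minimum possible).

## Synthetic data generator

A forward-time Wright–Fisher engine with recombination, used both as test
substrate and as the sweep fixture factory. Desk-scale rescaling divides
Ne by 100 (3×10⁴ → 300 diploids) while preserving θ = 4·Ne·μ, ρ = 4·Ne·r
and the scaled event times, so drift, LD and sweep dynamics match the
full-size model. Defaults: 1 Mb chromosome, ρ = 1.2×10⁻³/bp (r = 10⁻⁸ at
full scale), burn-in 10·N generations from an empty (monomorphic) state,
50 diploids sampled per population.

*Markers.* θ is set to 1.38×10⁻⁴/bp and the emitted panel keeps variants
with pooled minor-allele frequency ≥ 0.05, yielding array-like marker
density (~1 per 2.7 kb, 20-SNP windows ≈ 50 kb). The MAF floor matters
beyond density: on common markers haplotype-homozygosity decay is
recombination-dominated, as on real genotyping arrays, whereas a panel of
mostly rare variants decays by marker mutation — a regime in which no
sweep lengthens haplotype homozygosity. Matching any specific chip's
ascertainment spectrum remains out of scope.

*Demography.* Three populations: the focal lineage is the root; the sister
splits 20 rescaled generations before present (~50 kya equivalent, the
deep end of the plausible divergence range) and the reference/outgroup at
24 (~60 kya equivalent). Migration is off by default in fixtures (it is
part of the null model instead).

*Sweep preset.* A de novo beneficial mutation (genic selection, fitness
(1+s) per copy, s = 1/6 so 2·Ne·s ≈ 100) is injected into one focal
haplotype 43 generations before present — i.e. *before* the sister split —
and selection acts in the focal lineage only: the sister buds off while
the allele is still rare (~10–20%) and evolves neutrally afterwards. This
is the selection-relaxation geometry the scan is designed to detect (the
sister group left the environment driving selection), and at desk scale it
is the only geometry that works: the rescaled split is ~20 generations
deep, while a 2Ns ≈ 100 sweep needs ~50 to rise from a single copy. The
onset accounts for survivorship (a conditioned sweep behaves as if started
from ~1/(2s) copies), putting the expected focal sample frequency near
0.8. Runs where the allele is lost, *or merely survives without
establishing* (focal frequency < 0.5 at sampling), are re-run from a
checkpoint taken at onset with fresh randomness, bounded at 200 attempts
and counted in the truth record: a sweep fixture is required to actually
contain a sweep.

*Relatives.* Offspring are built by explicit meiosis: crossover counts are
Poisson in map distance, positions uniform in genetic-map space.
Supported relationships: parent–offspring (Φ = 0.25), full sibs (0.25,
with a positive IBD-2 component), half sibs (0.125). The `related` preset
uses an unlinked HWE panel (10,000 markers, uniform frequencies) rather
than the forward engine, since the kinship moment estimators do not use
LD; relatives go through the same meiosis code either way.

*Admixture panel.* For f3 validation, a frequency-level Balding–Nichols
panel: two sources at pairwise FST ≈ 0.1 from a shared ancestor, a target
that is an α/(1−α) frequency mixture, a control drifting independently,
and binomial sampling noise at 100 haploids per population.

## Validation scale and what it shows

The test suite and `scripts/acceptance.py` run at fixed desk-scale sizes
chosen to exercise every code path with meaningful statistics: 20 sweep
fixtures of 1 Mb; a 10,000-replicate neutral null against 2,000 observed
draws for calibration; 10,000 replicates for the coalescent closed forms;
ten 50,000-SNP admixture panels; pedigree panels with 15 families. Passing
them shows the estimators are implemented correctly and the pipeline
recovers known signals under its own model assumptions. It does not show
robustness to features real cohorts have and the generator deliberately
lacks: genotyping error, chip ascertainment, variable recombination and
mutation rates along the genome, background selection, or unmodelled
substructure and admixture in the scan populations.

## Known limitations

- Window-level empirical p-values inherit the no-recombination null and
  are anti-conservative (see above).
- The single-site null statistic is discrete; pseudo-count p-values are
  conservative and carry atoms.
- The ms dialect covers the flags the neutral model needs (`-t -s -I -g
  -ej -en -eg -em`); recombination (`-r`) and admixture pulses (`-es`) are
  explicitly unsupported.
- EHH cores near chromosome edges are censored and excluded from
  standardization; on short fixtures this removes an appreciable fraction
  of cores.
- Phasing is assumed, never inferred: haplotype statistics require phased
  input or synthetic phased data.
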