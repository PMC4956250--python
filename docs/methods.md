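# Methods

`msatpop` re-implements, as one tested pipeline, the population-genetic
analyses routinely applied to multi-population microsatellite surveys of a
plant species sampled as diploid allele-size calls: within-population
diversity and Hardy–Weinberg testing, null-allele correction, F-statistics
and molecular-variance partitions, distance trees, Bayesian admixture
clustering, bottleneck detection, isolation by distance, and coalescent-based
demographic model choice by approximate Bayesian computation (ABC). The
concrete study design it targets is 709 individuals from 30 populations
(23 indigenous, 7 cultivated/naturalised) scored at eight microsatellite
loci. The deposited genotype table of that survey is a journal supplementary
download and is not redistributed here; every stage is therefore exercised
against synthetic data with known truth, and the loader plus a reproduction
test stand ready for the real table (`data/deposited_genotypes.csv`).

## Data model

Alleles are fragment sizes in bp; conversion to the repeat-unit lattice
(`floor((size − min)/motif)`) happens only where a lattice is intrinsic
(M-ratio, stepwise mutation). Missing data is a dataset-level sentinel
excluded from every denominator; nothing imputes genotypes. GENEPOP v4 and a
two-columns-per-locus CSV are the interchange formats, with round-trip
identity tested.

## Diversity and Hardy–Weinberg

* **PIC** uses Botstein's formula on pooled frequencies.
* **He** is Nei's unbiased estimator `(2n/(2n−1))(1 − Σp²)`; multilocus
  values are unweighted means over loci with data.
* **Allelic richness** is hypergeometric rarefaction at `g` gene copies; the
  default `g` is the dataset-wide minimum typed-copies cell, overridable.
* **FIS** is the Weir–Cockerham small-*f* estimator with components summed
  over alleles and loci before the ratio; a `1 − Ho/He` variant would react
  differently to rare alleles and is intentionally not the default.
* **HWE exact tests** explore the conditional distribution of genotype
  tables given allele counts by Monte-Carlo shuffling of gene copies into
  diploids (vectorized; default 10⁵ shuffles), with full enumeration for
  two-allele tables. Like all exact conditional tests the realized level is
  at most nominal and can be noticeably conservative when the table support
  is sparse (few alleles, n ≈ 25); calibration is asserted in a
  dense-support regime (n = 100, eight alleles). Global tests combine loci
  by Fisher's method; sequential-Bonferroni correction is Holm's step-down.
* **Group comparisons** permute populations between groups (two-sided, the
  observed assignment counted in numerator and denominator).

## Null alleles

The per-cell null frequency is a Dempster-style EM on genotype classes under
Hardy–Weinberg: observed homozygotes mix true homozygotes (`p²`) and
visible/null heterozygotes (`2pr`). Blanks are never counted as null
homozygotes; instead the E-step adds the *expected* number of unobserved
null/null individuals (`n·r²/(1−r²)`), making the procedure the EM for the
visibility-truncated multinomial — without the truncation term the estimator
is visibly biased low (≈ −0.04 at a true frequency of 0.15). The conditional
log-likelihood is non-decreasing across iterations (asserted).

**He(null)** renormalizes the corrected visible frequencies without the null
class. **ENA-corrected FST** excludes the null class *without*
renormalizing: the corrected visible frequencies (summing to `1 − r`) enter
the Weir–Cockerham components directly, and per-allele heterozygote
proportions are augmented by the expected hidden visible/null heterozygotes.
Renormalizing instead would fold the null allele's own between-population
variance into every visible allele — exactly the upward bias the correction
exists to remove. On island-model data with a drifting null allele at mean
frequency 0.2, the uncorrected estimator overshoots the all-allele truth by
≈ +0.03 while the ENA estimate is unbiased to ≈ ±0.005 (tested).

## Differentiation

* **θ** (Weir & Cockerham 1984) sums the a/b/c variance components over
  alleles and loci before the ratio; confidence intervals are percentile
  bootstraps over loci (10⁴ replicates by default). Pairwise significance
  permutes multilocus genotypes between the pair.
* **Chord distance** follows the GENDIST convention
  `D² = Σ_l 4(1 − Σ_a √(x y)) / Σ_l (K_l − 1)`.
* **Fitch–Margoliash** minimizes `Σ (D−d)²/D²` with non-negative
  least-squares branch lengths (weighted NNLS on the path-incidence matrix),
  a neighbour-joining start and first-improvement nearest-neighbour
  interchanges under a fixed taxon order (deterministic; optional random-order
  restarts). Additive matrices are recovered exactly. Bootstrap supports
  resample loci; for large taxon sets the per-replicate search can be
  restricted to neighbour-joining topologies (`replicate_search="nj"`),
  which changes supports negligibly and is the default in the pipeline.
* **AMOVA** partitions allele-identity mismatch distances over gene copies
  (the φ-statistic, not the allele-size ρ variant). Sums of squares are
  accumulated over loci while degrees of freedom count gene copies once
  (average typed copies per population across loci), matching the classical
  presentation where a 709-individual survey shows 29/1388 df. Permutation
  schemes: individuals among populations (φST), individuals within groups
  (φSC), whole populations among groups (φCT).
* **Isolation by distance** is the Mantel correlation of `FST/(1−FST)`
  against `ln` great-circle km (haversine, R = 6371 km), one-sided P over
  row/column permutations.

## Bottleneck detection

**Heterozygosity excess.** The equilibrium reference `HEQ | k` is simulated
by the coalescent engine under the study's two-phase mutation model (22%
multistep changes, geometric multistep sizes with variance 11.92, i.e. mean
`(1+√(1+4·11.92))/2 ≈ 3.99`); the scaled mutation rate is tuned by bisection
until the mean simulated allele count matches the observed `k`, and
simulations with exactly `k` alleles are retained (default 500; the
distributions are cached by `(2n, k)` since they are fixed functions of the
sample size, allele count and model). Per locus the observed gene diversity
is located within this reference distribution; the default test statistic is
the normal score of its conditional rank, combined over loci by a one-tailed
exact Wilcoxon signed-rank test. The classical difference from the HEQ
*mean* is available (`center="mean"`) but is measurably liberal (type-I
≈ 0.085 at α = 0.05 under this jumpy mutation model) because the conditional
He distribution is left-skewed; the rank transform makes the null exactly
symmetric (measured ≈ 0.055) at a modest power cost. With eight loci the
test's power against even severe recent crashes is limited (≈ 0.3–0.4 at a
95% crash in its peak-detection window, ≈ 0.2 × 2N_post generations) — in
line with the method literature and with such surveys flagging only a few
populations.

**M-ratio** is the mean over loci of `k/(r+1)` with `r` the within-population
allele-size range in repeat units, compared with the critical value
`Mc = 0.68`. That critical value presumes a mildly two-phase mutation regime
(≈ 10% multistep, mean multistep ≈ 3.5): under it equilibrium samples sit at
M ≈ 0.72–0.91 and moderate sustained crashes fall to ≈ 0.63, whereas under
the 22%/11.92 model used for the heterozygosity test the *equilibrium*
M is already ≈ 0.59 — Mc is not transferable across mutation models, and the
directional tests are run under the regime Mc was derived for.

## Admixture clustering

A Gibbs sampler over the admixture model with correlated allele frequencies
(F-model): allele-copy origins Z, memberships `Q_i ~ Dirichlet(α…)`, cluster
frequencies `~ Dirichlet(p_anc (1−F_k)/F_k)`; ancestral frequencies get a
flat Dirichlet prior (λ = 1) and a Dirichlet-proposal Metropolis update; F_k
has the conventional Gamma(mean 0.01, sd 0.05) prior with a normal-walk
Metropolis step; a single α is shared by all clusters with a Uniform(0, 10)
prior. The model evidence is estimated from the post-burn-in log-likelihood
trace as `mean − var/2`, and K is selected by the second-order rate of
change (ΔK) across K, using means and standard deviations over replicate
runs. Summaries always come from the single best-likelihood run, so no
cross-run label alignment is needed. Desk-scale defaults (5k burn-in, 20k
sweeps) mix well on datasets of a few hundred individuals; the published
run plan (200k/10⁶, ten runs, K to 11) is reachable through the same
arguments. On two populations at FST 0.25 the sampler assigns individuals
to their sources with mean maximum membership ≥ 0.95; on three groups at
FST 0.15 the ΔK argmax recovers K = 3 reliably.

## Coalescent engine and ABC

The shared engine simulates backwards in time with per-population
coalescence at rate `C(j,2)/(2N)` per generation; demographic events (merge,
backward admixture split, resize) apply at fixed times, and populations are
independent between events, so each epoch draws its coalescence times in one
batch. Mutations are Poisson on branches: GSM steps are geometric in repeat
units (parameter P, step probability `(1−P)P^{k−1}`), the TPM mixes ±1 with
geometric multisteps, and SNI indels move fragments ±1 bp off-lattice. The
engine is cross-checked in tests against the Ohta–Kimura closed form
(`F = 1/√(1+2θ)` under strict SMM) and against msprime ancestries carrying
the same mutation overlay.

The five demographic scenarios relate three populations: serial splits in
both directions, two independent derivations from the middle population, an
admixture founding, and a simultaneous trifurcation (one free time, realized
as two merges at the same instant, ancestral size NA applying from the final
merge backwards; intermediate receivers keep their own size). Priors follow
the study: sizes Uniform(10, 10⁴) with `NA > max(N1,N2,N3)`, times
Uniform(1, 10⁵) with `t2 > t1`, admixture rate Uniform(0.001, 0.999), mean
mutation rate Uniform(10⁻⁵, 10⁻³) with per-locus Gamma(shape 2) scatter,
geometric parameter Uniform(0.10, 0.30) with ±0.05 per-locus scatter, SNI
rate log-Uniform(10⁻⁸, 10⁻⁵).

Each simulated dataset is summarized by 24 statistics: per population mean
allele number and unbiased He; per pair the pooled versions, pairwise θ and
the shared-allele distance DAS; and six directional mean individual
assignment log-likelihoods with Dirichlet-smoothed reference frequencies.
Model choice standardizes the statistics by reference-table standard
deviations, retains the closest simulations (1% by default), and fits a
multinomial logistic regression on PCA-decorrelated deviations (the raw 24
are strongly collinear), evaluated at the observed point with a delta-method
CI; a rejection-count fallback covers degenerate fits. Parameter posteriors
use Epanechnikov-weighted local-linear regression adjustment on
logit-transformed (prior-bounded) parameters; 90% intervals cover
prior-drawn truths at ≈ 0.9 in reduced-scale runs. Model checking simulates
from the weighted posterior and reports per-statistic tail probabilities and
a PCA of prior/posterior predictive clouds.

**Known limitation — scenario identifiability.** The trifurcation scenario
is nested in the closure of the serial-split scenarios (t2 → t1), so
neighbourhoods of trifurcation data always contain serial-split simulations
with nearly equal event times. Cross-validation at 10⁴ simulations per
scenario assigns trifurcation pseudo-observations back to their scenario in
only ≈ 50–60% of replicates (across rejection, weighted-vote, LDA-distance
and logistic variants; insensitive to per-population sample sizes 25–90).
This mirrors the modest winning posterior probabilities such nested designs
produce at full scale.

## Synthetic generators (what they do and do not emulate)

The island-model generator draws population frequencies from a Dirichlet
centred on ancestral frequencies with concentration `(1−FST)/FST`, yielding
Weir–Cockerham θ within ±0.03 of target at 10 × 50 × 8 scale. Null alleles
join the ancestral frequency vector and drift like any allele; null/null
genotypes become missing, visible/null genotypes apparent homozygotes, and
the truth sidecar keeps the unmasked calls. The 30-population fixture uses
the published sampling design (ids, n, coordinates, status) with three wild
gene pools and a founder-bottlenecked cultivated pool derived from the
northwestern pool; it reproduces the *shape* of the study's results
(lower cultivated richness, no cultivated private alleles,
within-population-dominated AMOVA, a supported cultivated clade, an emergent
isolation-by-distance signal from the geographic coherence of the pools) but
not the study's numerical values, which depend on the real allele-frequency
spectra. Equilibrium and bottleneck single populations come from the
coalescent engine. Tests passing on these generators certify estimator
correctness and calibration under the stated models, not robustness to
genotyping artefacts (stutter, allelic dropout) or deviations such as
selfing, which the generators do not emulate.

## Problem sizes

Desk-scale defaults keep the full test suite and the acceptance script
within routine single-CPU runs: HWE Monte-Carlo 1.5–5k shuffles in tests
(10⁵ default in the API), HEQ references of 300–500 retained simulations
with caching, admixture chains of 2.5–8k sweeps, ABC tables of 10³–10⁴ rows
per scenario, bootstraps of 60–200 replicates in tests (10³–10⁴ defaults in
the API). The analysis scripts under `analysis/` print which scale they use;
all published-scale settings remain reachable through function arguments.
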