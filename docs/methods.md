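# Methods

This note documents the models behind `hybridassign`, the assumptions they
make, the parameters that matter, and the choices taken where the design was
genuinely open.

## The problem

Two recently diverged taxa (the motivating system is the mallard / American
black duck pair) hybridize, and individual samples must be placed on a
generational axis: pure parental, F1, or an F2+ recurrent backcross toward
one parent. With a sparse biallelic SNP panel (~3,000 ddRAD-like loci) and
genome-wide differentiation around F_ST = 0.01, almost no marker is
individually diagnostic, and the two available signals — genome-wide
ancestry proportion and the spatial arrangement of ancestry blocks — degrade
in different ways. The package implements both estimators plus the
simulation machinery needed to calibrate and stress-test them.

## Pedigree simulator and analytic expectations

Individuals are diploids whose chromosome copies are lists of maximal
ancestry tracts (origin A or B) on [0, L] Morgan. Meiosis draws a
Poisson(L) number of crossovers, uniformly placed, with no interference and
no obligate chiasma — the standard assumption of the theory of junctions; a
junction forms only where a crossover hits a site heterogenic for ancestry.
Generation labels use t = 1 for the F1; F(k) has k−1 further meioses behind
it.

Two schemes are provided.

* **Recurrent backcross.** F(t+1) = gamete(F(t)) × pure recurrent parent.
  Expected ancestry heterozygosity at F_t is 2^−(t−1) and the recurrent
  parent's genome share is 1 − 2^−t, both independent of any population
  size: the recurrent parent is an effectively infinite pool, so drift never
  fixes loci. Both laws are verified against 1,000-replicate simulations at
  3 standard errors in the test suite.
* **Hybrid swarm.** A closed population of N diploids; the founder cohort
  (hybrid age t = 1) has each haplotype independently pure A or pure B with
  probability ½ — the Hardy–Weinberg cohort of offspring of randomly mating
  pure ancestors, with expected heterozygosity 0.5 and no junctions. Each
  round of random mating (selfing excluded) produces N offspring.
  `expected_stats` reports the classical closed form
  H(t) = 0.5 (1 − 1/2N)^(t−1). That form assumes random union of gametes
  including selfing; with selfing excluded the exact decay is the two-term
  recursion h[t+1] = x[t], x[t+1] = (1/N)·h[t]/2 + (1 − 1/N)·x[t]
  (heterozygosity lags the between-individual coalescence probability by one
  generation). The asymptotic rate is identical; the unit tests oracle the
  simulator against the exact recursion and treat the closed form as the
  documented approximation. Because individuals within one population share
  drift, simulation checks use standard errors across replicate populations,
  not across individuals.

Diploid junction counts are defined on the A-dosage signal (2/1/0 copies of
A ancestry): the number of change points of that step function. This is
deliberately the same signal the HMM posterior argmax estimates, so true and
inferred junction counts share one definition; per-haplotype tract-boundary
counts are also reported, and the diploid count is the pipeline default.

## Synthetic parental panels

No real data are required anywhere. Marker maps place SNPs uniformly at
random on chromosomes with the genetic lengths of the seven largest
chromosomes of the motivating system (3.17, 2.26, 1.12, 0.93, 0.79, 1.20,
0.98 Morgan); a uniform recombination rate maps base pairs to Morgans
proportionally, and the default density target is a few hundred kbp per
marker (~300 SNPs per Morgan, matching a ~3,000-marker genome-wide panel).

Allele frequencies follow a symmetric divergence model: an ancestral
frequency drawn from Beta(0.5, 0.5) (U-shaped, mimicking SNP-rich
ascertainment; clipped to [0.02, 0.98] so the perturbation distributions
exist), then an independent Balding–Nichols perturbation per population,
Beta(p(1−F)/F, (1−p)(1−F)/F) with F equal to the target F_ST. Under this
model the expected Hudson composite F_ST equals F; the realized composite on
default panel sizes (82 and 65 diploids, the study-scale panels) lands
within roughly ±50% of the target at 1,000 SNPs. A configurable fraction of
SNPs can be made diagnostic with frequency differential `diag_delta`
(1.0 = fixed differences, the "perfect markers" control). Genotypes are
binomial draws per diploid; missing calls are off by default (the motivating
panels were filtered to <20% missingness) and excluded from allele counts
when enabled.

What the generator does not emulate: linkage disequilibrium within parental
populations (panel SNPs are exchangeable given their frequencies), locus
dropout structure of real ddRAD libraries, genotyping error conditional on
read depth, and any demography beyond the single divergence parameter.
Passing tests therefore demonstrate correctness of the estimators under the
stated statistical structure, not robustness to every artifact of real
reduced-representation data.

## Local-ancestry HMM with a prior on hybrid age

Per chromosome, a 3-state HMM over diploid ancestry {AA, AB, BB}. Emissions
use panel allele-frequency posteriors with add-one smoothing
(q = (alt+1)/(total+2), avoiding zero-probability emissions; panels of realistic
size make the smoothing negligible); the AB state mixes one binomial draw
from each population. SNPs with zero panel counts in either population are
skipped with a warning; missing genotypes contribute flat emissions.

Transitions model the two haplotypes as independent two-state Markov chains
relaxing toward a stationary ancestry mix with factor exp(−t·d) over genetic
distance d — the standard well-mixed (pulse-admixture) approximation of
two-way local-ancestry HMMs, under which admixture t generations back leaves
ancestry blocks of scale ~1/t Morgan. The stationary minor-ancestry
proportion is tied to the age as 2^−t (the genome-wide recurrent-backcross
expectation), and the direction — which ancestry is minor — is profiled
alongside t. The hybrid age maximizes the profile log-likelihood plus a log
exponential prior with mean 10 generations over the fixed grid
t ∈ {1, 1.1, …, 50}, ties broken toward smaller t (the likelihood surface in
t is characteristically flat, which is why the prior exists at all);
posteriors come from forward–backward at the selected age. The batched
forward pass evaluates all 982 (age, direction) grid points simultaneously,
exploiting the fact that every entry of the lumped 3×3 transition matrix is
a quadratic polynomial in the relaxation factor.

Two deliberate properties of this model class deserve emphasis.

* A literal F1 has perfectly anti-correlated haplotypes (all-heterozygous,
  zero junctions), which independent haplotype chains cannot represent.
  With strongly diagnostic markers the emissions still force the AB state
  everywhere and the F1 is recovered exactly. With weakly differentiated
  panels (F_ST ≈ 0.01), P(g | AB) ≈ P(g | hom) at every SNP, heterozygosity
  is systematically under-detected, ancestry switches are over-called, and
  downstream junction counting assigns F1 individuals essentially zero
  F1 weight (the acceptance suite asserts the mean AIC weight below 0.05). This
  failure mode is inherited intentionally: it is a documented property of
  applying this HMM class to low-divergence data, and quantifying it is part
  of the package's purpose. An earlier variant with switch intensity
  (t−1)·d — a backcross-aware parameterization whose t = 1 chain is frozen —
  removed the failure by construction (it recovers low-F_ST F1s as
  whole-chromosome heterozygotes) and was rejected in favour of the
  field-standard pulse form precisely because the pipeline's documented
  behaviour on weak markers is part of its contract.
* The backcross process is not first-order Markov and its two haplotypes are
  not exchangeable (one is pure recurrent-parent); the transition model is
  an approximation throughout, adequate because emissions dominate whenever
  markers carry signal and because junction counting, not the HMM age,
  drives the final generation call.

Forward–backward is verified against exhaustive enumeration of all 3^n
state paths on instances up to 8 SNPs at |Δ| < 1e−8. A monotone-
regularization property (stronger prior never increases the inferred age)
is property-tested.

### Reference panel vetting

Reference panels can be built at three stringencies mirroring a realistic
vetting workflow: `default` keeps individuals with ≥99% supervised
assignment to their own population; `pure` additionally requires a
leave-one-out self-inference (each candidate removed from the counts,
re-inferred, junctions called) with zero junctions on every chromosome;
`one_recombination` allows at most one recombined chromosome. Panels are
always equalized per SNP — the larger population's alleles are subsampled
without replacement (hypergeometric) to the smaller total — because
asymmetric panel sizes bias rare-allele detection toward the larger panel.

## Junction counting and generation assignment

Junctions are called from posteriors by windowing: 20 equal-Morgan,
non-overlapping windows per chromosome (window boundaries in Morgans so they
align with the transition model), window state = argmax of the mean
posterior over its SNPs, empty windows inheriting the previous non-empty
window's state (leading empties take the first non-empty state — windowing
needs a total state sequence and this is the minimal completion), junctions
= adjacent state changes. Ties in the argmax break toward higher A dosage,
deterministically.

There is no analytic distribution for windowed junction counts after t
generations, so P(j | t, L) is tabulated per chromosome from 1,000 simulated
pedigree replicates per generation (F1–F10 by default), counting windowed
junctions on the true dosage signal with the identical window definition.
Tables store raw observed frequencies (rows sum to one; the F1 row is exactly
P(0|1) = 1). At likelihood evaluation, an unobserved count inside the
simulated support is floored at 1/(10·replicates) to avoid −∞, and the
assignment records that the floor was used; a count beyond the support of
every candidate raises an error rather than silently extrapolating. The
full log-likelihood of an individual sums log P(j_c | t, L_c) over
chromosomes; each candidate generation gets AIC = 2·1 − 2 log P(t) (one
free parameter, t) and the relative support is its AIC weight. The best
generation is the maximum weight, ties toward smaller t, with an ambiguity
flag when the top two weights differ by less than 0.1. Tables can be cached
on disk keyed by (scheme, L, windows, replicates, seed).

Known behaviour, not a bug: a genome whose minor-ancestry tracts have all
been lost (or fall below window resolution) shows zero junctions everywhere
and is maximally supported as F1, because F1 likewise has no junctions. At
F6+ this collapses a visible fraction of individuals onto t = 1 and is the
main cost in the ±1 generation-recovery rate, which the acceptance suite
requires to stay at or above 80% over F2–F6 with perfect markers.

## Admixture route

The allele-sampling hybrid simulator follows the assignment-probability
protocol exactly: ten F1s built by sampling one allele per SNP from each
parental pool, five lineages per direction backcrossed for nine generations,
each backcross drawing one allele from the previous hybrid's pair and one
from the recurrent pool — SNPs unlinked by design (this simulator feeds the
q estimator, which ignores linkage; the tract simulator feeds the junction
route). The supervised estimator maximizes the binomial-mixture likelihood
in q, strictly concave whenever any SNP differentiates the panels, by
bounded scalar maximization (tolerance 1e−9, boundary-snapped). An
unsupervised K=2 alternating EM (ADMIXTURE-style updates, initialized from
the supervised fit, stopping when the log-likelihood gain drops below 1e−4
or at 500 iterations) is provided as a cross-check; its log-likelihood is
non-decreasing by construction and is asserted so.

Bins on the population-A proportion scale follow the simulation-derived
envelope table: PURE_A at q ≥ 0.95, F3-toward-A at 0.90 ≤ q < 0.95,
F2-toward-A at 0.73 ≤ q < 0.90, F1 at 0.28 < q < 0.73, F2-toward-B at
0.02 < q ≤ 0.27, PURE_B at q ≤ 0.02. The pure thresholds are deliberately
asymmetric (≥95% own assignment on the A side, ≤2% interspecific on the B
side), as derived; the stretch (0.27, 0.28] is left uncovered by the
envelopes and is labelled UNASSIGNED explicitly — the classifier is total on
[0, 1].

## Summary statistics

Hudson's F_ST with finite-sample correction per locus; the composite is the
ratio of summed numerators to summed denominators (monomorphic loci are
undefined, excluded, and counted). These are SNP-genotype statistics and are
labelled F_ST, not the haplotype-sequence Φ_ST of concatenated-sequence
packages; on biallelic data with equal weighting they estimate the same
quantity, and equal-site weighting is assumed for the composite. π uses the
unbiased 2·alt·(tot−alt)/(tot(tot−1)) per site; Watterson's θ uses S/a1;
Tajima's D uses the published a1…e2 constants and is null when S = 0 or
fewer than four chromosomes are available. d_XY is the between-population
allele-frequency cross-product per site; note the exact identity
d_XY(X, X) = π·(n−1)/n for a sample compared against itself (self-pairs
included), which the tests assert. All three are oracle-tested against
independent brute-force implementations at 1e−12.

## Problem sizes and determinism

Simulation-backed checks run at the sizes the analyses themselves use:
1,000 pedigree replicates for decay laws and likelihood tables, 1,000-member
swarms for the heterozygosity expectation, 100 individuals per generation
(F2–F6) on the seven-chromosome map at ~300 SNPs/Morgan for generation
recovery, and 82/65-diploid panels at target F_ST 0.01 for the
low-divergence failure mode. Every stochastic component consumes a
`numpy` `SeedSequence`, with per-replicate child streams spawned from one
root seed, so any run is exactly reproducible from its resolved
configuration plus seed; the CLI writes that resolved configuration beside
its outputs.

## Limitations

* No crossover interference, no obligate chiasma, no sex chromosomes, and
  no selection or hybrid-viability differences in the pedigree simulator.
* The HMM is two-way only (K = 2); read-level emissions and recombination
  maps (beyond the uniform bp→Morgan scaling) are out of scope.
* Junction-based assignment cannot distinguish a junction-free late
  backcross from an F1, and its resolution past F6 is limited by the
  saturation and overlap of the count distributions; these are properties
  of the method being studied, reproduced on purpose.
* The bin table encodes envelope boundaries derived for the motivating
  system's panel sizes and divergence; other systems should re-derive
  envelopes with `derive_envelopes` rather than reuse the defaults.
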