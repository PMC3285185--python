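# Methods

## The question and the procedure

Coalescent inference programs return posterior distributions of demographic
parameters under deliberately simple models. This package implements a
posterior predictive goodness-of-fit workflow for such fits on
two-population multilocus sequence panels. The quantity of central interest
is among-locus *heterogeneity*: under neutrality, every locus experiences
the same demographic history, so the cross-locus spread of nucleotide
diversity is predicted by the model plus the stochasticity of the
coalescent and known rate variation. Observed heterogeneity beyond that
prediction indicates a model violation — unmodelled size changes, gene flow
from unsampled populations, or selection.

The workflow: (1) assemble "histories" — joint draws of demographic
parameters, per-locus relative substitution rates μ_R, per-locus
recombination rates, and fragment lengths; (2) simulate every locus under
every history and compute π, Φst, and Tajima's D per locus; (3) compare the
empirical per-locus values, cross-locus means, and cross-locus coefficients
of variation with the resulting posterior predictive distributions; (4)
independently, test polymorphism-versus-divergence homogeneity with a
multilocus HKA test against several outgroups.

## Summary statistics

All statistics use complete deletion: any alignment column containing `-`
or `N` is removed before anything is computed, and per-site denominators
count surviving columns only.

* **π** — mean pairwise differences per analysed site over the whole
  sample. Computed from per-column allele counts (a column with counts
  c over alleles contributes (n² − Σc²)/2 mismatching pairs), which equals
  the O(n²L) pairwise loop exactly; the test suite asserts that equality.
* **Φst** — two-level AMOVA on the matrix of pairwise difference counts
  used as squared distances (no substitution-model correction; the simplest
  distance consistent with standard AMOVA defaults). Negative estimates are
  retained unclamped — they are legitimate outcomes when within-population
  diversity exceeds the total. Significance by permutation of population
  labels: p = (1 + #{Φperm ≥ Φobs}) / (1 + n_perm).
* **Tajima's D** — the 1989 statistic from S and mean pairwise diversity
  with the standard a₁…e₂ constants. D is *undefined* (not zero) when S = 0
  or n < 4; undefined values are excluded from cross-locus aggregates with
  a reported count. Per-population values and their mean are reported
  because the dataset-level test uses D averaged between the populations.
* **Cross-locus summaries** — mean, SD with the n−1 denominator (the
  convention matching the published ±SD values the packaged table
  reproduces), and CV = SD/|mean|.

## Simulator

A Hudson-style structured coalescent written for this package (an external
simulator is used only as a cross-validation oracle in one test, never in
the pipeline). Unit conventions:

* time in units of 4N₀ generations, N₀ anchored to the present-day
  reference deme (deme 0, "OW");
* deme sizes relative to N₀; coalescence at rate k(k−1)/x among k lineages
  in a deme of relative size x;
* `migration[i][j]` is the backward per-lineage rate of movement i→j; a
  forward rate "into deme i" reported by an inference program becomes a
  backward out-rate of deme i, with 4N₀mᵢ = Θ_ref·Mᵢ (per-site scale) or
  θ_OW·Mᵢ (per-locus scale) — the rate scalings cancel;
* exponential growth g means size x(t) = x(0)·e^(−gt) pastward;
* mutation is infinite-sites on continuous positions in [0,1): with this
  time unit a lineage accumulates θ_locus mutations per unit branch length
  (θ/2 would be correct only on a 2N₀ time scale — the E[S] = θ·a₁ and
  E[π] = θ identities pin the factor, and the analytic acceptance checks
  enforce it);
* recombination at rate ρ_locus × (span of ancestral material) per lineage,
  with ρ_locus = r·Θ_site·(L−1) from a per-site rate r relative to μ.

The implementation tracks, per lineage, the intervals of ancestral material
and the set of sampled alleles descending through each interval; intervals
whose descendant set reaches the full sample have found their MRCA and are
dropped, so mutations are laid down only where they can segregate.
Mutations are drawn lazily when a lineage dies (Poisson over its lifetime ×
interval length), which keeps the event loop allocation-free. Per-locus
scalings: θ_locus = θ_site·L·μ_R·ploidy. The Z-linked locus uses ploidy
0.75 on θ and ρ; times are left unadjusted (the 0.75 adjustment applies to
the mutation and recombination supply, not the time scale — a documented
choice).

Model builders convert program-scale draws to these conventions. The
isolation-migration model solves the exponential growth rate of each
daughter so that its size at the split equals its founding fraction of the
ancestor (s founds NW, 1−s founds OW) and its present size equals the
drawn θ. The bottleneck model extends the ancestor's shrink (the OW
daughter's growth rate) from t to a recovery time t_B ~ U(t, 2t), then
instantaneously restores the long-term size taken from the two-island fit;
the builder expects that size already expressed in simulator units and
stores it verbatim in the event list. The hybridization model adds a third
deme exchanging migrants with deme 0 only (structural zeros to deme 1) that
joins the ancestor at t_fd > t; migration with the ancestor continues
through (t, t_fd) — a configurable choice, since either convention is
defensible. The selection scenario is not a different simulator: it is the
same machinery run on a locus subset, with the demographic family detected
from the draw's keys.

Degenerate inputs are rejected before simulating: a two-island model with
both migration rates zero, or any event schedule whose final epoch leaves
occupied demes unable to reach a common ancestor.

## Histories and posterior tables

Demographic draws are sampled as whole rows — without replacement when the
table is large enough — so within-row parameter correlations survive into
the history set (verified by rank correlation). μ_R rows are kept intact,
preserving the exact mean-1 constraint (tolerance 1e−6 on read), and are
paired with histories by a seeded random permutation; recombination rates
are drawn independently per locus. Per-locus θ on the im scale:
θᵢ = θ/geomean(L)·Lᵢ·μ_Rᵢ·ploidyᵢ.

Joint multilocus estimates multiply biweight-kernel (quartic) smoothed
densities across loci on a 512-point grid spanning the pooled 0.1–99.9%
quantiles, in log space. Bandwidth is a Silverman-style rule,
h = 0.9·min(sd, IQR/1.34)·n^(−1/5), configurable because the reference
implementation's bandwidth is unpublished. The narrowest-interval scan
returns the 95% interval; with k identical samples it contracts ≈ 1/√k.

## Goodness-of-fit tests

Two-tailed empirical-quantile p-values:
p = 2·min(#sim ≤ obs, #sim ≥ obs)/n_hist, capped at 1 and floored at
2/n_hist — a finite simulation cannot claim p = 0, and "within the 2.5%
tails" is equivalent to p ≤ 0.05. Equal-tailed rather than highest-density
intervals, the plainer reading of tail-based testing; configurable. CV is
computed per history across its loci (not pooled), matching the
dataset-level definition of heterogeneity. Undefined simulated D values
(S = 0 replicates) are dropped from that locus's predictive column with a
count, mirroring the empirical aggregation rule. Locus-specific tests use
Benjamini–Hochberg FDR across loci per statistic; decisions are checked
against an exhaustive step-up oracle.

## The HKA branch

Moment-equation fit: E[Sᵢ] = θᵢ·a(nᵢ) and E[Dᵢ] = θᵢ(T+1) with the 1987
sample-size variance terms Var[S] = θa + θ²b and Var[D] = E[D] + θ² (the θ²
is the ancestral-coalescence depth variance; the outgroup contributes one
sequence and the ancestral population is assumed equal in size to the focal
one). The fit iterates θᵢ = (Sᵢ+Dᵢ)/(aᵢ+T+1), T = ΣD/Σθ − 1 with 0.5
damping to tolerance 1e−10. X² sums (obs−exp)²/var over both cells of each
locus; df = L−1 (2L cells, L+1 parameters). Two exactly proportional loci
fit perfectly (X² ≈ 0), the anchor case for the solver. Iterative removal
drops the locus with the largest summed contribution while p ≤ α, ties
broken by input order with a warning; loci removed in strictly more than
half of the per-outgroup comparisons are consensus outliers.

## Synthetic data: what it emulates and what it does not

Generators produce every input class with controlled truth: coalescent
alignments (50 alleles per population by default, 22-locus panels with
lengths U[150,500] bp and one Z-linked locus), pseudo-posterior tables, μ_R
draw-sets (lognormal, CV 25% by default, renormalised to mean 1 per row),
and HKA polymorphism/divergence tables. Default demographic truths sit at
the published joint estimates for the duck system the package was built
around (two-island Θ_OW = 0.0092, Θ_NW = 0.0042, M_OW = 1010, M_NW = 1480;
isolation-migration θ_OW = 2.53, θ_NW = 2.98, θ_A = 1.69, M_OW = 0.13,
M_NW = 12.2, t = 0.032, s = 0.022).

Pseudo-posteriors are lognormal perturbations around truth with a Gaussian
copula (logit-normal for s) — location, spread, and correlation are
controlled; MCMC autocorrelation, multimodality, and real base
composition/indel/alignment artifacts are *not* emulated. Passing
calibration on these inputs therefore demonstrates that the test machinery
is correct and calibrated under its own assumptions, not that any
particular empirical dataset fits any particular model.

HKA divergence counts are Poisson with mean 2·d·L·μ_R plus a
θ·Exp(1) ancestral-depth term. The depth term matters: without it the
generated divergence is under-dispersed relative to the neutral model the
test assumes, and the type-I error calibration comes out conservative
(≈0.02 instead of ≈0.05). The within-species S vector is simulated once and
shared across outgroup comparisons, as in a real study where polymorphism
is measured once.

## Calibration experiments: problem sizes and their rationale

All experiments live in `hetfit.calibration` and are run both by the test
suite and by `scripts/acceptance.py`.

* **GOF type-I error** — 200 trials; per trial a fresh pseudo-posterior,
  100 assembled histories, a 5-locus panel at 8 alleles per deme, and one
  held-out history playing the empirical role. Rejection of the π-mean test
  at α = 0.05 stays in the binomial 95% band around 5%. (The plug-in p with
  floor makes the test slightly conservative, ≈4% — expected behaviour.)
* **Planted-locus FDR power** — 50 trials, 500 histories, 6 loci, 12
  alleles per deme, one locus simulated at θ/20. Twelve alleles rather than
  eight: with very small samples the predictive distribution of π has an
  atom at zero, ties inflate the planted locus's tail p above the BH
  rank-one threshold, and the experiment measures a discreteness artifact
  instead of power. At 12+12 the detection rate is ≈0.96.
* **HKA type-I error** — 22-locus neutral panels at the study-like
  θ_site = 0.0092, 100 alleles, divergence levels 0.05/0.1/0.2
  substitutions per site. The X²-to-chi-square approximation is slightly
  anticonservative for skewed S cells (measured ≈0.05–0.07, worse at small
  within-species sample sizes), which is why the full 100-allele sampling
  is used here.
* **HKA sweep recovery** — sweep detection by HKA requires a large
  *expected* number of segregating sites at the swept locus; the planted
  deviation saturates near a(n)²/b(n) however extreme the sweep. A
  10×-suppressed locus on the 22-locus θ_site = 0.0092 panel ranks first in
  deviation almost always but leaves the omnibus X² (df 21) non-significant
  in roughly half the runs, so the consensus rule recovers it only ~45% of
  the time. The power experiment therefore uses a compact high-diversity
  panel (10 loci, θ_site = 0.015, 100 alleles, sweep planted on the locus
  with the largest L·μ_R), the regime where a single sweep is identifiable;
  recovery there is ≈0.9. Both facts are scientific results about the
  procedure, and the degradation at low diversity is expected behaviour,
  not a defect.
* **Wright–Fisher oracle** — a vectorised discrete haploid two-deme WF
  simulation of pairwise coalescence times (N = 100, m = 0.005). First-step
  analysis of the discrete chain gives within ≈ 200 and between ≈ 298.5
  generations; the continuous-time simulator matches within Monte-Carlo
  error (5% band at 12,000+ replicates).
* **Watterson recovery** — 1,500 replicates per locus; at the
  study-like θ_locus ≈ 2.8 the per-locus Monte-Carlo SE of the mean
  estimate is ~1.2%, keeping the 5% bias band meaningful. The Z-linked
  versus matched-autosome diversity ratio is checked against 0.75.

## Numerical choices and degenerate inputs

Tie-breaks and tolerances are stated where they bite: HKA removal ties by
input order (warned); μ_R row-mean tolerance 1e−6; HKA solver tolerance
1e−10 with damping; KDE grid 512 points; p-value floor 2/n_hist; Φst
denominator zero returns 0. Errors are raised early for: ragged or empty
alignments, unknown samples in the population map, populations below
minimum size, all-gap columns, non-numeric posterior cells, insufficient
posterior rows without the replacement flag, unreachable ancestry,
S > L at sequence realisation, disjoint KDE supports, and all-zero or
divergence-free HKA inputs.

## Known limitations

* The simulator is not optimised for very long loci or high ρ; it targets
  sub-kilobase non-coding fragments.
* The HKA p-value relies on the chi-square approximation; a parametric
  bootstrap would be better calibrated at high divergence but is not the
  default for cost reasons.
* Published empirical P-values from any particular study are not
  reproduction targets: they depend on the original MCMC posterior chains,
  which the package consumes but does not re-estimate.
* The "Tajima's D" column of an ingested summary table is treated as given;
  when computing from alignments the package reports both the total-sample
  D and the between-population average, since published tables are often
  ambiguous between the two.
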