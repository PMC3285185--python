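# hetfit

Test whether multilocus genetic diversity fits neutral coalescent models of
population history.

Phylogeographic inference programs fit simple demographic models — constant
sizes, constant migration, selective neutrality — to multilocus sequence
data. `hetfit` asks the follow-up question those fits leave open: *do the
data actually fit the model?* Given per-locus summary statistics from a
two-population sample (for example, a Holarctic duck panel of ~22 non-coding
nuclear loci with 50 phased alleles per population) and posterior samples of
demographic parameters from coalescent inference, the package:

1. simulates neutral genetic diversity under the inferred model with **full
   propagation of posterior uncertainty** — each simulated 22-locus dataset
   uses its own draw of demographic parameters, locus-specific relative
   substitution rates (μ_R, constrained to mean 1), locus-specific
   recombination rates, and the real fragment lengths;
2. compares the empirical mean **and coefficient of variation** of π
   (nucleotide diversity), Φst (AMOVA-based population differentiation), and
   Tajima's *D* with their posterior predictive distributions, plus
   locus-specific tests with a Benjamini–Hochberg FDR correction;
3. runs a multilocus **HKA neutrality test** against one or more outgroups,
   with iterative removal of the highest-deviation locus and a >50%
   cross-outgroup consensus rule for calling significant outliers.

Five demographic scenarios are built in: a two-island equilibrium model
(parameters Θ=4Nₑμ per site, M=m/μ), an isolation-with-migration model
(per-locus θ=4Nₑu, divergence time t=Tu, founding fraction s, ancestral
θ_A, exponential size change), a pre-divergence bottleneck (recovery time
t_B ~ U(t, 2t), pre-bottleneck size from the two-island fit), gene flow from
a third unsampled population ("hybridization": migration allowed only
through the sampled population it is sympatric with), and a selection
scenario (the same machinery on a locus subset chosen by the HKA test).

The structured-coalescent simulator is written here: Hudson-style
competing-exponential ancestry with migration, exponential growth,
time-ordered demographic events, recombination over an ancestral
recombination graph, and infinite-sites mutation. It follows ms unit
conventions (time in 4N₀ generations, sizes relative to the present-day
reference deme, per-lineage backward migration rates). Sex-linked loci are
handled with a 0.75 ploidy factor on θ and ρ.

## Worked example

Summarise the packaged 22-locus empirical table and simulate a posterior
predictive check on synthetic inputs:

```python
import numpy as np
from hetfit import (
    multilocus_summary, assemble_histories, posterior_predictive,
    gof_dataset, table1_fixture,
)
from hetfit.synthetic_data import (
    default_scenario, gen_history_posterior, gen_rate_posterior,
)

summary = multilocus_summary(table1_fixture())
print(summary.table.round(4))
```

```
          mean      sd      cv     min     max  n_loci  n_undefined
pi      0.0101  0.0102  1.0104  0.0004  0.0295    22.0          0.0
phi_st  0.0650  0.0755  1.1606 -0.0140  0.2920    22.0          0.0
tajd   -0.3732  0.7990  2.1411 -2.1400  1.1100    22.0          0.0
```

Mean nucleotide diversity is 0.010 ± 0.010 SD per site but ranges over
nearly two orders of magnitude (0.0004–0.0295) — the among-locus
heterogeneity (CV ≈ 101%) is the quantity the goodness-of-fit machinery
tests against neutral expectations. On average 6.5% of diversity (Φst)
separates the two populations, and the mean Tajima's *D* of −0.37 indicates
a genome-wide excess of rare variants.

```python
scen = default_scenario(model="two_island", n_loci=6, seed=1)
rng = np.random.default_rng(1)
tables = {
    "lamarc": gen_history_posterior(scen, "lamarc", 400, rng),
    "rates": gen_rate_posterior(scen, 400, rng),
}
histories = assemble_histories(tables, scen.panel, n=300, rng=rng)
pred = posterior_predictive(histories, "two_island", n_per_deme=(12, 12), rng=rng)
emp = {"pi": {"mean": 0.010, "cv": 1.01}}
print(gof_dataset(emp, pred).table[["statistic", "summary", "empirical", "p", "significant"]])
```

```
  statistic summary  empirical     p  significant
0        pi    mean       0.01  0.38        False
1        pi      cv       1.01  0.06        False
```

Here the empirical mean and CV of π sit inside the predictive distribution
(two-tailed p = 0.38 and 0.06), so this synthetic dataset is consistent
with its generating model — the outcome the calibration experiments verify
at scale. Note the CV test runs close to its 2.5% tail even on matched
data: the small 6-locus panel makes the empirical CV noisy.

A command-line interface mirrors the library:
`hetfit stats`, `hetfit simulate`, `hetfit synth`, `hetfit hka`,
`hetfit joint`, and
`hetfit run --config run.yaml` for the full multi-model pipeline with a
reproducibility manifest.

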