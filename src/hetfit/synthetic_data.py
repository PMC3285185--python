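"""Synthetic inputs for every stage of the pipeline.

Generators emulate the four input classes the analysis consumes: phased
per-locus alignments with a population map, pseudo-posterior tables in the
two-island (per-site) and isolation-migration (per-locus) dialects,
relative-substitution-rate draw sets constrained to mean 1, and
polymorphism/divergence tables for the HKA test. Pseudo-posteriors are
independent lognormal (logit-normal for the founding fraction) perturbations
around a known truth — location and spread are controlled, MCMC
autocorrelation is not emulated.

Default scenario conditions mirror the empirical study design: a 22-locus
panel of non-coding nuclear fragments with lengths drawn uniformly from
150–500 bp, one Z-linked locus (ploidy factor 0.75), 50 sampled alleles per
population, and relative substitution rates with a 25% coefficient of
variation among loci. Default demographic truths sit at the joint posterior
point estimates of the empirical analysis (two-island: Theta_OW = 0.0092,
Theta_NW = 0.0042, M_OW = 1010, M_NW = 1480; isolation-migration:
theta_OW = 2.53, theta_NW = 2.98, theta_A = 1.69, M_OW = 0.13, M_NW = 12.2,
t = 0.032, s = 0.022).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import coalsim
from .hka import HKAInput, HKALocus
from .paramspace import LocusDef, PosteriorTable, geometric_mean
from .popgen_stats import LocusAlignment, read_table1

__all__ = [
    "SyntheticScenario",
    "default_scenario",
    "gen_rate_posterior",
    "gen_history_posterior",
    "gen_multilocus_dataset",
    "gen_hka_inputs",
    "table1_fixture",
    "table1_path",
]

TWO_ISLAND_TRUTH = {
    "Theta_OW": 0.0092,
    "Theta_NW": 0.0042,
    "M_OW": 1010.0,
    "M_NW": 1480.0,
}

IM_TRUTH = {
    "theta_OW": 2.53,
    "theta_NW": 2.98,
    "theta_A": 1.69,
    "M_OW": 0.13,
    "M_NW": 12.2,
    "t": 0.032,
    "s": 0.022,
}


@dataclass
class SyntheticScenario:
    """A fully specified ground truth for generating pipeline inputs.

    Regeneration from (scenario, seed) is bit-identical: every generator
    takes the scenario plus an explicit seeded rng.
    """

    model: str = "two_island"
    truth: dict[str, float] = field(default_factory=lambda: dict(TWO_ISLAND_TRUTH))
    panel: list[LocusDef] = field(default_factory=list)
    mu_R_truth: dict[str, float] = field(default_factory=dict)
    rho_site_truth: dict[str, float] = field(default_factory=dict)
    mu_R_cv: float = 0.25
    posterior_dispersion: float = 0.1  # lognormal sigma of pseudo-posterior noise
    posterior_correlation: float = 0.3  # rank correlation among demographic draws
    n_per_deme: tuple[int, int] = (50, 50)
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["panel"] = [dataclasses.asdict(l) for l in self.panel]
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticScenario":
        d = json.loads(text)
        d["panel"] = [LocusDef(**l) for l in d["panel"]]
        d["n_per_deme"] = tuple(d["n_per_deme"])
        return cls(**d)


def _lognormal_mean1(cv: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Lognormal draws with mean 1 and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv**2)
    return rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), size=size)


def default_scenario(
    model: str = "two_island",
    n_loci: int = 22,
    seed: int = 0,
    mu_R_cv: float = 0.25,
    mean_rho_site: float = 0.5,
    n_per_deme: tuple[int, int] = (50, 50),
    truth: Mapping[str, float] | None = None,
    length_range: tuple[int, int] = (150, 500),
    posterior_dispersion: float = 0.1,
    posterior_correlation: float = 0.3,
) -> SyntheticScenario:
    """Build a scenario with a locus panel, one Z-linked locus, mean-1
    mu_R truths, and per-locus recombination truths (r relative to mu)."""
    rng = np.random.default_rng(seed)
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_loci)
    panel = [
        LocusDef(
            locus_id=f"L{str(i + 1).zfill(2)}",
            length=int(lengths[i]),
            ploidy_factor=0.75 if i == 0 else 1.0,  # one Z-linked locus
        )
        for i in range(n_loci)
    ]
    mu = _lognormal_mean1(mu_R_cv, n_loci, rng)
    mu = mu / mu.mean()  # constrain the truth itself to mean exactly 1
    rho = rng.gamma(2.0, mean_rho_site / 2.0, size=n_loci)
    if truth is None:
        truth = TWO_ISLAND_TRUTH if model == "two_island" else IM_TRUTH
    return SyntheticScenario(
        model=model,
        truth=dict(truth),
        panel=panel,
        mu_R_truth={l.locus_id: float(m) for l, m in zip(panel, mu)},
        rho_site_truth={l.locus_id: float(r) for l, r in zip(panel, rho)},
        mu_R_cv=mu_R_cv,
        posterior_dispersion=posterior_dispersion,
        posterior_correlation=posterior_correlation,
        n_per_deme=n_per_deme,
        seed=seed,
    )


def gen_rate_posterior(
    scenario: SyntheticScenario, n_rows: int, rng: np.random.Generator
) -> PosteriorTable:
    """Pseudo-posterior of relative substitution rates: lognormal noise
    around the per-locus truth, renormalised so each row averages 1."""
    ids = [l.locus_id for l in scenario.panel]
    truth = np.array([scenario.mu_R_truth[i] for i in ids])
    sigma = scenario.posterior_dispersion
    rows = truth[None, :] * rng.lognormal(0.0, sigma, size=(n_rows, len(ids)))
    rows = rows / rows.mean(axis=1, keepdims=True)
    return PosteriorTable(source="rates", draws=pd.DataFrame(rows, columns=ids))


def gen_recomb_posterior(
    scenario: SyntheticScenario, n_rows: int, rng: np.random.Generator
) -> PosteriorTable:
    """Pseudo-posterior of per-site recombination rates (relative to mu)."""
    ids = [l.locus_id for l in scenario.panel]
    truth = np.array([scenario.rho_site_truth[i] for i in ids])
    sigma = scenario.posterior_dispersion
    rows = truth[None, :] * rng.lognormal(
        -(sigma**2) / 2.0, sigma, size=(n_rows, len(ids))
    )
    return PosteriorTable(source="recomb", draws=pd.DataFrame(rows, columns=ids))


def gen_history_posterior(
    scenario: SyntheticScenario,
    source: str,
    n_rows: int,
    rng: np.random.Generator,
    dispersion: float | None = None,
    correlation: float | None = None,
) -> PosteriorTable:
    """Correlated pseudo-posterior of demographic parameters.

    Draws share a Gaussian copula with exchangeable correlation; margins are
    lognormal around the truth with median = truth (logit-normal for the
    founding fraction s). dispersion 0 reproduces the truth in every row.
    """
    if source not in ("lamarc", "im"):
        raise ValueError("source must be 'lamarc' or 'im'")
    truth = scenario.truth
    keys = (
        ["Theta_OW", "Theta_NW", "M_OW", "M_NW"]
        if source == "lamarc"
        else ["theta_OW", "theta_NW", "theta_A", "M_OW", "M_NW", "t", "s"]
    )
    missing = [k for k in keys if k not in truth]
    if missing:
        raise ValueError(f"scenario truth missing {missing} for source {source!r}")
    sigma = scenario.posterior_dispersion if dispersion is None else dispersion
    corr = scenario.posterior_correlation if correlation is None else correlation
    k = len(keys)
    cov = np.full((k, k), corr)
    np.fill_diagonal(cov, 1.0)
    z = rng.multivariate_normal(np.zeros(k), cov, size=n_rows, method="cholesky")
    cols = {}
    for j, key in enumerate(keys):
        mu = truth[key]
        if key == "s":
            logit = math.log(mu / (1 - mu)) + sigma * z[:, j]
            cols[key] = 1.0 / (1.0 + np.exp(-logit))
        elif mu == 0:
            cols[key] = np.zeros(n_rows)
        else:
            cols[key] = mu * np.exp(sigma * z[:, j])
    return PosteriorTable(source=source, draws=pd.DataFrame(cols))


def _truth_model(scenario: SyntheticScenario, rng: np.random.Generator):
    return coalsim.build_model(scenario.model, scenario.truth, rng=rng)


def _theta_site_ref(scenario: SyntheticScenario) -> float:
    if scenario.model == "two_island":
        return scenario.truth["Theta_OW"]
    gm = geometric_mean([l.length for l in scenario.panel])
    return scenario.truth["theta_OW"] / gm


def gen_multilocus_dataset(
    scenario: SyntheticScenario,
    rng: np.random.Generator,
    out_dir: str | Path | None = None,
    pop_names: Sequence[str] = ("OW", "NW"),
) -> tuple[list[LocusAlignment], dict]:
    """Simulate one multilocus dataset under the scenario truth.

    Returns realised alignments plus ground truth (per-locus theta, tmrca,
    S) for recovery tests. With ``out_dir`` set, writes per-locus FASTA
    files and a sample->population map TSV.
    """
    theta_site = _theta_site_ref(scenario)
    model = _truth_model(scenario, rng)
    n_per = list(scenario.n_per_deme) + [0] * (model.n_demes - len(scenario.n_per_deme))
    alignments = []
    truth_rows = []
    names = {i: p for i, p in enumerate(pop_names)}
    for locus in scenario.panel:
        mu = scenario.mu_R_truth[locus.locus_id]
        rho_locus = scenario.rho_site_truth[locus.locus_id] * theta_site * (locus.length - 1)
        spec = coalsim.LocusSimSpec(
            locus.locus_id,
            L=locus.length,
            mu_R=mu,
            rho_locus=rho_locus,
            ploidy_factor=locus.ploidy_factor,
        )
        sim = coalsim.simulate_locus(model, spec, n_per, rng, theta_site=theta_site)
        aln = coalsim.realize_sequences(
            sim, locus.length, rng, pop_names=names, ploidy_factor=locus.ploidy_factor
        )
        alignments.append(aln)
        truth_rows.append(
            {
                "locus": locus.locus_id,
                "theta_locus": theta_site * locus.length * mu * locus.ploidy_factor,
                "S": sim.S,
                "tmrca": sim.tmrca,
                "length": locus.length,
                "ploidy_factor": locus.ploidy_factor,
            }
        )
    truth = {"per_locus": truth_rows, "theta_site_ref": theta_site, "model": scenario.model}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from .popgen_stats import write_locus_fasta

        popmap = []
        for aln in alignments:
            write_locus_fasta(aln, out_dir / f"{aln.locus_id}.fasta")
            for i, p in enumerate(aln.pop_labels):
                popmap.append((f"{aln.locus_id}_{i}_{p}", p))
        with open(out_dir / "popmap.tsv", "w") as fh:
            for sample, pop in popmap:
                fh.write(f"{sample}\t{pop}\n")
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
    return alignments, truth


def gen_hka_inputs(
    scenario: SyntheticScenario,
    divergence: float | Sequence[float],
    rng: np.random.Generator,
    n_within: int = 100,
    outgroup_id: str | Sequence[str] | None = None,
    planted_locus: str | None = None,
    suppression: float = 10.0,
    genealogical_variance: bool = True,
) -> list[HKAInput]:
    """Neutral polymorphism/divergence inputs for the HKA test, one input
    per outgroup comparison.

    The within-species segregating sites are simulated once from a
    panmictic coalescent at each locus's theta and shared across all
    outgroup comparisons, mirroring a design where polymorphism is measured
    once and divergence is recomputed against each outgroup. Divergence to
    an outgroup at distance d (substitutions/site on the focal branch) is
    Poisson with mean 2 * d * L * mu_R (substitutions accumulate on both
    branches) plus, when ``genealogical_variance`` is set, the ancestral
    coalescent contribution theta_locus * Exp(1) assumed by the HKA null
    model. A planted sweep locus has its within-species theta suppressed by
    ``suppression``; its divergence is untouched (sweeps do not change the
    substitution rate).
    """
    divergences = (
        [float(divergence)] if np.isscalar(divergence) else [float(d) for d in divergence]
    )
    if outgroup_id is None:
        names = [f"outgroup{i + 1}" for i in range(len(divergences))]
    elif isinstance(outgroup_id, str):
        names = [outgroup_id]
    else:
        names = list(outgroup_id)
    if len(names) != len(divergences):
        raise ValueError("need one outgroup id per divergence level")

    theta_site = _theta_site_ref(scenario)
    one = coalsim.DemographicModel(demes=[(1.0, 0.0)], migration=np.zeros((1, 1)))
    S_within: dict[str, float] = {}
    for locus in scenario.panel:
        mu = scenario.mu_R_truth[locus.locus_id]
        theta_locus = theta_site * locus.length * mu * locus.ploidy_factor
        if planted_locus == locus.locus_id:
            theta_locus /= suppression
        spec = coalsim.LocusSimSpec(locus.locus_id, L=locus.length, mu_R=mu)
        sim = coalsim.simulate_locus(one, spec, [n_within], rng, theta_locus=theta_locus)
        S_within[locus.locus_id] = float(sim.S)

    inputs = []
    for d, name in zip(divergences, names):
        loci = []
        for locus in scenario.panel:
            mu = scenario.mu_R_truth[locus.locus_id]
            lam = 2.0 * d * locus.length * mu
            if genealogical_variance:
                lam += (
                    theta_site
                    * locus.length
                    * mu
                    * locus.ploidy_factor
                    * rng.exponential()
                )
            loci.append(
                HKALocus(
                    locus_id=locus.locus_id,
                    S_within=S_within[locus.locus_id],
                    D_out=float(rng.poisson(lam)),
                    n_within=n_within,
                    L=locus.length,
                )
            )
        inputs.append(HKAInput(loci=loci, outgroup_id=name))
    return inputs


def table1_path() -> Path:
    """Path of the packaged 22-locus empirical summary table."""
    return Path(importlib.resources.files("hetfit") / "data" / "table1.tsv")


def table1_fixture() -> pd.DataFrame:
    """The 22-locus empirical per-locus summary statistics table."""
    return read_table1(table1_path())
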