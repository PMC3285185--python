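"""Calibration and power experiments for the pipeline's statistical tests.

These experiments validate the machinery end to end on synthetic data with
known truth: type-I error of the dataset-level goodness-of-fit test when
the empirical data really come from the generating model, power of the
locus-specific FDR test against a planted low-diversity locus, type-I
error and planted-sweep recovery of the HKA branch, estimator recovery on
simulated panels, and a brute-force discrete Wright–Fisher check of the
continuous-time simulator's coalescence times.
"""

from __future__ import annotations

import numpy as np

from . import gof, paramspace
from .coalsim import DemographicModel, LocusSimSpec, simulate_locus
from .hka import consensus_outliers, hka_test, iterative_removal
from .popgen_stats import locus_stats_from_matrix, multilocus_summary
from .synthetic_data import (
    SyntheticScenario,
    default_scenario,
    gen_history_posterior,
    gen_hka_inputs,
    gen_rate_posterior,
    gen_recomb_posterior,
)

__all__ = [
    "gof_dataset_calibration",
    "planted_locus_power",
    "hka_null_calibration",
    "hka_planted_recovery",
    "watterson_recovery",
    "wf_pair_coalescence_times",
    "coalescent_pair_times",
]

# Divergence levels (substitutions/site) emulating seven outgroups of
# increasing depth.
OUTGROUP_DIVERGENCES = (0.05, 0.07, 0.09, 0.11, 0.14, 0.17, 0.2)


def _tables(scen: SyntheticScenario, n_rows: int, rng: np.random.Generator):
    source = "lamarc" if scen.model == "two_island" else "im"
    return {
        source: gen_history_posterior(scen, source, n_rows, rng),
        "rates": gen_rate_posterior(scen, n_rows, rng),
        "recomb": gen_recomb_posterior(scen, n_rows, rng),
    }


def _simulate_empirical(
    scen: SyntheticScenario,
    history: paramspace.History,
    n_per_deme,
    rng: np.random.Generator,
    deflate: dict[str, float] | None = None,
):
    """One 'empirical' multilocus dataset from a given history; ``deflate``
    maps locus id -> factor by which to shrink that locus's theta."""
    stats = []
    draw = history.demographic
    from .coalsim import build_model

    model = build_model(scen.model, draw, rng=rng)
    if scen.model == "two_island":
        theta_site = draw["Theta_OW"]
    else:
        gm = paramspace.geometric_mean([l.length for l in scen.panel])
        theta_site = draw["theta_OW"] / gm
    n_per = list(n_per_deme) + [0] * (model.n_demes - len(n_per_deme))
    for locus in scen.panel:
        mu = history.mu_R[locus.locus_id]
        rho_locus = history.rho_site[locus.locus_id] * theta_site * (locus.length - 1)
        theta_locus = theta_site * locus.length * mu * locus.ploidy_factor
        if deflate and locus.locus_id in deflate:
            theta_locus /= deflate[locus.locus_id]
        spec = LocusSimSpec(
            locus.locus_id, L=locus.length, mu_R=mu,
            rho_locus=rho_locus, ploidy_factor=locus.ploidy_factor,
        )
        sim = simulate_locus(model, spec, n_per, rng, theta_locus=theta_locus)
        stats.append(
            locus_stats_from_matrix(sim.matrix, sim.deme_of, locus.length, locus.locus_id)
        )
    return stats


def gof_dataset_calibration(
    n_trials: int = 200,
    n_histories: int = 100,
    n_loci: int = 5,
    n_per_deme=(8, 8),
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate of the dataset-level test when the empirical summary
    is itself a draw from the generating model (should be ~alpha)."""
    scen = default_scenario(model="two_island", n_loci=n_loci, seed=seed)
    reject = {("pi", "mean"): 0, ("pi", "cv"): 0}
    n_done = 0
    for trial in range(n_trials):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1000 + trial]))
        tables = _tables(scen, n_histories + 50, rng)
        hs = paramspace.assemble_histories(
            tables, scen.panel, n=n_histories + 1, rng=rng
        )
        emp_history = hs.histories.pop()  # held-out draw plays the empirical role
        pred = gof.posterior_predictive(hs, scen.model, n_per_deme=n_per_deme, rng=rng)
        stats = _simulate_empirical(scen, emp_history, n_per_deme, rng)
        try:
            summary = multilocus_summary(stats)
        except ValueError:
            continue  # all-undefined statistic in a tiny trial; skip
        res = gof.gof_dataset(summary, pred, alpha=alpha)
        n_done += 1
        for (stat, which) in reject:
            row = res.table[
                (res.table["statistic"] == stat) & (res.table["summary"] == which)
            ]
            reject[(stat, which)] += int(row["significant"].iloc[0])
    return {
        "n_trials": n_done,
        "rejection_rate_pi_mean": reject[("pi", "mean")] / n_done,
        "rejection_rate_pi_cv": reject[("pi", "cv")] / n_done,
    }


def planted_locus_power(
    n_trials: int = 50,
    n_histories: int = 500,
    n_loci: int = 6,
    n_per_deme=(12, 12),
    deflation: float = 20.0,
    q: float = 0.05,
    seed: int = 0,
) -> dict:
    """Detection rate of a single locus whose empirical theta is deflated
    ``deflation``-fold relative to its history value, via the
    locus-specific FDR test on pi.

    Uses 12 alleles per deme: with very small samples the predictive
    distribution of pi piles probability on exactly zero, the tied draws
    push the deflated locus's tail p above the Benjamini–Hochberg rank-one
    threshold, and detection reflects the discreteness artifact rather
    than the test's power."""
    scen = default_scenario(model="two_island", n_loci=n_loci, seed=seed)
    planted = scen.panel[n_loci // 2].locus_id
    hits = 0
    only = 0
    for trial in range(n_trials):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2000 + trial]))
        tables = _tables(scen, n_histories + 50, rng)
        hs = paramspace.assemble_histories(
            tables, scen.panel, n=n_histories + 1, rng=rng
        )
        emp_history = hs.histories.pop()
        pred = gof.posterior_predictive(hs, scen.model, n_per_deme=n_per_deme, rng=rng)
        stats = _simulate_empirical(
            scen, emp_history, n_per_deme, rng, deflate={planted: deflation}
        )
        emp_pi = {s.locus_id: s.pi for s in stats}
        res = gof.gof_locus_fdr(emp_pi, pred, stat="pi", q=q)
        flagged = set(res.table.loc[res.table["significant"], "locus"])
        hits += planted in flagged
        only += flagged == {planted}
    return {
        "n_trials": n_trials,
        "planted_locus": planted,
        "detection_rate": hits / n_trials,
        "exclusive_detection_rate": only / n_trials,
    }


def hka_null_calibration(
    divergence: float = 0.1,
    n_reps: int = 300,
    n_loci: int = 22,
    n_within: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the HKA test on strictly neutral synthetic inputs."""
    scen = default_scenario(model="two_island", n_loci=n_loci, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3000]))
    rej = 0
    for _ in range(n_reps):
        (inp,) = gen_hka_inputs(scen, divergence, rng, n_within=n_within)
        rej += hka_test(inp).p_value <= alpha
    return {"n_reps": n_reps, "divergence": divergence, "rejection_rate": rej / n_reps}


def hka_planted_recovery(
    n_trials: int = 25,
    n_loci: int = 10,
    theta_site: float = 0.015,
    n_within: int = 100,
    suppression: float = 10.0,
    threshold: float = 0.5,
    seed: int = 0,
) -> dict:
    """Recovery rate of a planted 10x polymorphism-suppressed locus by the
    iterative-removal + cross-outgroup consensus procedure.

    Uses a compact panel of high-diversity loci: sweep detection by HKA
    needs appreciable expected polymorphism at the swept locus, so the
    sweep is planted on the locus with the largest length x mu_R.
    """
    scen = default_scenario(model="two_island", n_loci=n_loci, seed=seed)
    scen.truth["Theta_OW"] = theta_site
    planted = max(
        scen.panel, key=lambda l: l.length * scen.mu_R_truth[l.locus_id]
    ).locus_id
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4000]))
    hits = 0
    for _ in range(n_trials):
        inputs = gen_hka_inputs(
            scen,
            OUTGROUP_DIVERGENCES,
            rng,
            n_within=n_within,
            planted_locus=planted,
            suppression=suppression,
        )
        lists = []
        for inp in inputs:
            try:
                lists.append(iterative_removal(inp).removed)
            except ValueError:  # significant down to 2 loci: count all removed
                lists.append([l.locus_id for l in inp.loci])
        hits += planted in consensus_outliers(lists, threshold=threshold)
    return {
        "n_trials": n_trials,
        "planted_locus": planted,
        "recovery_rate": hits / n_trials,
    }


def watterson_recovery(
    n_reps: int = 200,
    n_loci: int = 8,
    n_sample: int = 20,
    seed: int = 0,
) -> dict:
    """Relative bias of per-locus Watterson estimates on panmictic panels,
    plus the Z-linked vs autosomal diversity ratio (expected 0.75).

    The Z-linked check uses a dedicated pair of loci with identical length
    and mu_R so the ratio isolates the ploidy factor.
    """
    scen = default_scenario(model="two_island", n_loci=n_loci, seed=seed)
    theta_site = scen.truth["Theta_OW"]
    one = DemographicModel(demes=[(1.0, 0.0)], migration=np.zeros((1, 1)))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5000]))
    a1 = sum(1.0 / i for i in range(1, n_sample))
    est = {l.locus_id: [] for l in scen.panel}
    pi_z, pi_auto = [], []
    L_pair = 300
    for _ in range(n_reps):
        for locus in scen.panel:
            mu = scen.mu_R_truth[locus.locus_id]
            spec = LocusSimSpec(locus.locus_id, L=locus.length, mu_R=mu)
            theta_locus = theta_site * locus.length * mu * locus.ploidy_factor
            sim = simulate_locus(one, spec, [n_sample], rng, theta_locus=theta_locus)
            est[locus.locus_id].append(sim.S / a1)
        # matched Z/autosome pair
        for store, ploidy in ((pi_z, 0.75), (pi_auto, 1.0)):
            spec = LocusSimSpec("pair", L=L_pair, ploidy_factor=ploidy)
            sim = simulate_locus(one, spec, [n_sample], rng, theta_site=theta_site)
            n = n_sample
            c = sim.matrix.sum(axis=0)
            store.append(float((c * (n - c)).sum()) / (n * (n - 1) / 2))
    bias = {}
    for locus in scen.panel:
        truth = theta_site * locus.length * scen.mu_R_truth[locus.locus_id] * locus.ploidy_factor
        bias[locus.locus_id] = float(np.mean(est[locus.locus_id])) / truth - 1.0
    return {
        "n_reps": n_reps,
        "relative_bias": bias,
        "max_abs_relative_bias": max(abs(b) for b in bias.values()),
        "z_autosome_ratio": float(np.mean(pi_z) / np.mean(pi_auto)),
    }


# ---------------------------------------------------------------------------
# Discrete Wright–Fisher oracle

def wf_pair_coalescence_times(
    N: int = 100,
    m: float = 0.005,
    n_reps: int = 10_000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Brute-force pairwise coalescence times (in generations) under a
    discrete haploid two-deme Wright–Fisher model with symmetric migration.

    Each generation a lineage migrates with probability m and picks a
    parent uniformly among the N haploids of its deme; two lineages in the
    same deme coalesce when they pick the same parent. Vectorised across
    replicates. Returns mean within-deme and between-deme pair times.
    """
    rng = np.random.default_rng() if rng is None else rng
    out = {}
    for label, demes0 in (("within", (0, 0)), ("between", (0, 1))):
        d1 = np.full(n_reps, demes0[0], dtype=np.int8)
        d2 = np.full(n_reps, demes0[1], dtype=np.int8)
        alive = np.ones(n_reps, dtype=bool)
        times = np.zeros(n_reps, dtype=np.int64)
        gen = 0
        while alive.any():
            gen += 1
            k = int(alive.sum())
            mig1 = rng.random(k) < m
            mig2 = rng.random(k) < m
            d1a = d1[alive] ^ mig1
            d2a = d2[alive] ^ mig2
            p1 = rng.integers(0, N, size=k)
            p2 = rng.integers(0, N, size=k)
            coal = (d1a == d2a) & (p1 == p2)
            idx = np.flatnonzero(alive)
            times[idx[coal]] = gen
            d1[idx] = d1a
            d2[idx] = d2a
            alive[idx[coal]] = False
        out[label] = float(times.mean())
    return out


def coalescent_pair_times(
    N: int = 100,
    m: float = 0.005,
    n_reps: int = 10_000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Pairwise coalescence times from the continuous-time simulator under
    the matching two-deme model, converted to generations (one coalescent
    unit = 4*N0 generations with N0 = N haploids => 2*N diploid-equivalent
    ... the unit conversion used is time_gens = t * 2 * N for a haploid
    Wright–Fisher deme of size N, since the pair rate 2/x per unit matches
    1/N per generation when one unit is 2*N generations).

    Migration: per-generation probability m => scaled rate 2*N*m per unit.
    """
    rng = np.random.default_rng() if rng is None else rng
    M = 2 * N * m
    model = DemographicModel(
        demes=[(1.0, 0.0), (1.0, 0.0)],
        migration=np.array([[0.0, M], [M, 0.0]]),
    )
    spec = LocusSimSpec("pair", L=100)
    out = {}
    for label, n_per in (("within", (2, 0)), ("between", (1, 1))):
        times = [
            simulate_locus(model, spec, n_per, rng, theta_locus=0.0).tmrca
            for _ in range(n_reps)
        ]
        out[label] = float(np.mean(times)) * 2 * N
    return out
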