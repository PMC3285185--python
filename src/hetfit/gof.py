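"""Posterior predictive distributions and goodness-of-fit tests.

For each sampled history the simulator generates one value of every summary
statistic (pi, Phi_st, Tajima's D averaged over populations) at every locus.
Dataset-level tests compare the empirical cross-locus mean and coefficient
of variation with their posterior predictive distributions; locus-specific
tests compare each locus's empirical value with its own predictive column,
with a Benjamini–Hochberg false-discovery-rate correction across loci.

Empirical-tail p-values are two-tailed plug-ins,
p = 2 * min(#sim <= obs, #sim >= obs) / n_hist, capped at 1 and floored at
2/n_hist (a finite simulation cannot claim p = 0), so "within the 2.5%
tails" corresponds to p <= 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import coalsim
from .paramspace import HistorySet, geometric_mean
from .popgen_stats import MultiLocusSummary, locus_stats_from_matrix

__all__ = [
    "PredictiveDistribution",
    "GOFResult",
    "posterior_predictive",
    "gof_dataset",
    "gof_locus_fdr",
    "simulate_history",
]

STATS = ("pi", "phi_st", "tajd")


@dataclass
class PredictiveDistribution:
    """Simulated statistic values: one matrix (n_histories x n_loci) per
    statistic, plus per-history dataset-level mean and CV vectors."""

    locus_ids: list[str]
    values: dict[str, np.ndarray]  # stat -> (H, L) with NaN where undefined
    model: str = ""

    @property
    def n_histories(self) -> int:
        return next(iter(self.values.values())).shape[0]

    def dataset_mean(self, stat: str) -> np.ndarray:
        return np.nanmean(self.values[stat], axis=1)

    def dataset_cv(self, stat: str) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.nanmean(self.values[stat], axis=1)
            s = np.nanstd(self.values[stat], axis=1, ddof=1)
            return s / np.abs(m)

    def undefined_counts(self, stat: str) -> np.ndarray:
        return np.isnan(self.values[stat]).sum(axis=0)


@dataclass
class GOFResult:
    table: pd.DataFrame
    alpha: float
    kind: str  # dataset | locus

    @property
    def significant(self) -> pd.DataFrame:
        col = "significant"
        return self.table[self.table[col]]


def simulate_history(
    history,
    panel,
    model_name: str,
    n_per_deme: Sequence[int],
    rng: np.random.Generator,
    sample_pops: Sequence[int] = (0, 1),
) -> dict[str, dict[str, float]]:
    """Simulate every locus of one history; returns stat -> locus -> value."""
    draw = history.demographic
    model = coalsim.build_model(model_name, draw, rng=rng)
    if "Theta_OW" in draw:  # two-island family: already per site
        theta_site_ref = draw["Theta_OW"]
    else:  # im family: per-locus theta over the geometric-mean length
        gm = geometric_mean([l.length for l in panel])
        theta_site_ref = draw["theta_OW"] / gm
    if model.n_demes > len(n_per_deme):
        n_per_deme = list(n_per_deme) + [0] * (model.n_demes - len(n_per_deme))
    out: dict[str, dict[str, float]] = {s: {} for s in STATS}
    for locus in panel:
        mu = history.mu_R[locus.locus_id]
        r_site = history.rho_site[locus.locus_id]
        rho_locus = r_site * theta_site_ref * (locus.length - 1)
        spec = coalsim.LocusSimSpec(
            locus.locus_id,
            L=locus.length,
            mu_R=mu,
            rho_locus=rho_locus,
            ploidy_factor=locus.ploidy_factor,
        )
        sim = coalsim.simulate_locus(
            model, spec, n_per_deme, rng, theta_site=theta_site_ref
        )
        st = locus_stats_from_matrix(
            sim.matrix, sim.deme_of, locus.length, locus_id=locus.locus_id
        )
        out["pi"][locus.locus_id] = st.pi
        out["phi_st"][locus.locus_id] = (
            math.nan if st.phi_st is None else st.phi_st
        )
        out["tajd"][locus.locus_id] = (
            math.nan if st.tajd_mean is None else st.tajd_mean
        )
    return out


def posterior_predictive(
    history_set: HistorySet,
    model_name: str,
    n_per_deme: Sequence[int] = (50, 50),
    rng: np.random.Generator | None = None,
) -> PredictiveDistribution:
    """Simulate every locus under every history of the set.

    Tajima's D is averaged between the sampled populations per locus;
    histories where a statistic is undefined (e.g. S = 0) contribute NaN to
    that locus's predictive column and are excluded from tail counts.
    """
    rng = np.random.default_rng() if rng is None else rng
    locus_ids = history_set.locus_ids
    H, L = len(history_set), len(locus_ids)
    values = {s: np.full((H, L), np.nan) for s in STATS}
    for h, history in enumerate(history_set):
        res = simulate_history(history, history_set.panel, model_name, n_per_deme, rng)
        for s in STATS:
            for j, lid in enumerate(locus_ids):
                values[s][h, j] = res[s][lid]
    return PredictiveDistribution(locus_ids=locus_ids, values=values, model=model_name)


def tail_p(simulated: np.ndarray, observed: float) -> float:
    """Two-tailed empirical-quantile p against a predictive sample."""
    sim = simulated[~np.isnan(simulated)]
    n = len(sim)
    if n == 0:
        raise ValueError("no defined simulated values to compare against")
    lo = int((sim <= observed).sum())
    hi = int((sim >= observed).sum())
    p = 2.0 * min(lo, hi) / n
    return float(min(max(p, 2.0 / n), 1.0))


def gof_dataset(
    empirical: MultiLocusSummary | Mapping[str, Mapping[str, float]],
    predictive: PredictiveDistribution,
    alpha: float = 0.05,
) -> GOFResult:
    """Compare empirical cross-locus means and CVs against their posterior
    predictive distributions (two-tailed)."""
    if predictive.n_histories < 100:
        raise ValueError("need >= 100 histories for dataset-level tests")
    rows = []
    for stat in STATS:
        if isinstance(empirical, MultiLocusSummary):
            if stat not in empirical.table.index:
                continue
            emp_mean = float(empirical.table.loc[stat, "mean"])
            emp_cv = float(empirical.table.loc[stat, "cv"])
        else:
            if stat not in empirical:
                continue
            emp_mean = float(empirical[stat]["mean"])
            emp_cv = float(empirical[stat]["cv"])
        for which, emp, sim in (
            ("mean", emp_mean, predictive.dataset_mean(stat)),
            ("cv", emp_cv, predictive.dataset_cv(stat)),
        ):
            if not np.isfinite(emp):
                raise ValueError(f"empirical {stat} {which} is undefined")
            p = tail_p(sim, emp)
            rows.append(
                {
                    "statistic": stat,
                    "summary": which,
                    "empirical": emp,
                    "predictive_median": float(np.nanmedian(sim)),
                    "p": p,
                    "significant": p <= alpha,
                }
            )
    return GOFResult(table=pd.DataFrame(rows), alpha=alpha, kind="dataset")


def gof_locus_fdr(
    empirical_locus_values: Mapping[str, float] | pd.Series,
    predictive: PredictiveDistribution,
    stat: str = "pi",
    q: float = 0.05,
) -> GOFResult:
    """Locus-specific two-tailed tests with Benjamini–Hochberg correction.

    ``empirical_locus_values`` maps locus id -> empirical value of ``stat``;
    ids must match the predictive columns exactly.
    """
    emp = dict(empirical_locus_values)
    missing = set(emp) ^ set(predictive.locus_ids)
    if missing:
        raise ValueError(f"locus ids do not match predictive columns: {sorted(missing)}")
    mat = predictive.values[stat]
    ps, rows = [], []
    for j, lid in enumerate(predictive.locus_ids):
        p = tail_p(mat[:, j], float(emp[lid]))
        ps.append(p)
        rows.append(
            {
                "locus": lid,
                "statistic": stat,
                "empirical": float(emp[lid]),
                "predictive_median": float(np.nanmedian(mat[:, j])),
                "n_undefined": int(np.isnan(mat[:, j]).sum()),
                "p": p,
            }
        )
    reject, p_adj, _, _ = multipletests(ps, alpha=q, method="fdr_bh")
    df = pd.DataFrame(rows)
    df["p_adjusted"] = p_adj
    df["significant"] = reject
    return GOFResult(table=df, alpha=q, kind="locus")
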