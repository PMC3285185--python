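"""Hudson–Kreitman–Aguadé neutrality test across loci, with iterative
outlier removal and a cross-outgroup consensus rule.

The test compares within-species polymorphism (segregating sites S_i) to
divergence from an outgroup (mean pairwise differences D_i) across L loci.
Under neutrality both quantities are proportional to the locus mutation
rate, so their ratio should be homogeneous across loci. The model has L+1
free parameters — a per-locus theta_i (4*N*mu_i, per locus) and a shared
divergence time T (in units of 2*N generations) — fitted by the method of
moments:

    E[S_i] = theta_i * a(n_i)          a(n) = sum_{k=1}^{n-1} 1/k
    E[D_i] = theta_i * (T + 1)

with variances including the genealogical terms of the 1987 test

    Var[S_i] = theta_i * a(n_i) + theta_i^2 * b(n_i)
    Var[D_i] = theta_i * (T + 1) + theta_i^2

(the +theta_i^2 in the divergence cell is the variance of the ancestral
coalescence time; the outgroup contributes a single sequence, and the
ancestral population is assumed to equal the focal one in size). The
goodness-of-fit statistic sums (obs - exp)^2 / var over both cells of every
locus and is referred to a chi-square distribution with L - 1 degrees of
freedom (2L cells minus L+1 fitted parameters).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HKAInput",
    "HKAResult",
    "hka_test",
    "iterative_removal",
    "consensus_outliers",
]


@dataclass(frozen=True)
class HKALocus:
    locus_id: str
    S_within: float
    D_out: float
    n_within: int
    L: int

    def __post_init__(self) -> None:
        if self.S_within < 0 or self.D_out < 0:
            raise ValueError(f"locus {self.locus_id}: S and D must be >= 0")
        if self.L <= 0:
            raise ValueError(f"locus {self.locus_id}: L must be > 0")
        if self.n_within < 2:
            raise ValueError(f"locus {self.locus_id}: need n_within >= 2")


@dataclass
class HKAInput:
    loci: list[HKALocus]
    outgroup_id: str = ""

    def __post_init__(self) -> None:
        if len(self.loci) < 2:
            raise ValueError("HKA test needs at least 2 loci")
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus ids in HKA input")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, outgroup_id: str = "") -> "HKAInput":
        required = {"locus", "n_within", "L", "S_within", "D_out"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"HKA table missing columns {sorted(missing)}")
        loci = [
            HKALocus(
                str(r.locus),
                float(r.S_within),
                float(r.D_out),
                int(r.n_within),
                int(r.L),
            )
            for r in df.itertuples()
        ]
        return cls(loci=loci, outgroup_id=outgroup_id)

    def drop(self, locus_id: str) -> "HKAInput":
        return HKAInput(
            [l for l in self.loci if l.locus_id != locus_id], self.outgroup_id
        )


@dataclass
class HKAResult:
    theta: dict[str, float]
    T: float
    expected: pd.DataFrame  # per locus: exp_S, var_S, exp_D, var_D, dev_S, dev_D, dev_total
    X2_total: float
    df: int
    p_value: float
    outgroup_id: str = ""

    @property
    def deviations(self) -> pd.Series:
        return self.expected["dev_total"]


def _a1(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def _b1(n: int) -> float:
    return sum(1.0 / i**2 for i in range(1, n))


def hka_test(inp: HKAInput, tol: float = 1e-10, max_iter: int = 10_000) -> HKAResult:
    """Fit the neutral model by damped fixed-point iteration and return the
    goodness-of-fit decomposition."""
    S = np.array([l.S_within for l in inp.loci], dtype=float)
    D = np.array([l.D_out for l in inp.loci], dtype=float)
    a = np.array([_a1(l.n_within) for l in inp.loci])
    b = np.array([_b1(l.n_within) for l in inp.loci])
    ids = [l.locus_id for l in inp.loci]
    if S.sum() == 0 and D.sum() == 0:
        raise ValueError("all-zero HKA input: no polymorphism or divergence")
    if D.sum() == 0:
        raise ValueError("HKA input has zero total divergence; T is undefined")

    # moment equations: S_i + D_i = theta_i * (a_i + T + 1)
    #                   sum(D)    = (T + 1) * sum(theta)
    T = 1.0
    for it in range(max_iter):
        theta = (S + D) / (a + T + 1.0)
        T_new = D.sum() / theta.sum() - 1.0
        T_new = max(T_new, -1.0 + 1e-12)
        if abs(T_new - T) < tol:
            T = T_new
            break
        T = 0.5 * (T + T_new)  # damping
    else:
        raise RuntimeError(
            f"HKA moment equations failed to converge after {max_iter} "
            f"iterations (last T = {T:.6g})"
        )
    theta = (S + D) / (a + T + 1.0)

    exp_S = theta * a
    var_S = theta * a + theta**2 * b
    exp_D = theta * (T + 1.0)
    var_D = exp_D + theta**2
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_S = np.where(var_S > 0, (S - exp_S) ** 2 / var_S, 0.0)
        dev_D = np.where(var_D > 0, (D - exp_D) ** 2 / var_D, 0.0)
    dev_total = dev_S + dev_D
    X2 = float(dev_total.sum())
    df = len(inp.loci) - 1
    p = float(stats.chi2.sf(X2, df))
    expected = pd.DataFrame(
        {
            "S_obs": S,
            "exp_S": exp_S,
            "var_S": var_S,
            "D_obs": D,
            "exp_D": exp_D,
            "var_D": var_D,
            "dev_S": dev_S,
            "dev_D": dev_D,
            "dev_total": dev_total,
        },
        index=pd.Index(ids, name="locus"),
    )
    return HKAResult(
        theta=dict(zip(ids, theta.tolist())),
        T=float(T),
        expected=expected,
        X2_total=X2,
        df=df,
        p_value=p,
        outgroup_id=inp.outgroup_id,
    )


@dataclass
class RemovalTrace:
    removed: list[str]
    results: list[HKAResult]
    final_p: float


def iterative_removal(inp: HKAInput, alpha: float = 0.05) -> RemovalTrace:
    """Repeatedly remove the locus with the highest overall deviation until
    the test is no longer significant at ``alpha``.

    Returns the ordered removal list together with every intermediate test
    result. Deterministic: ties on the deviation break by input order (with
    a warning).
    """
    removed: list[str] = []
    results: list[HKAResult] = []
    current = inp
    while True:
        res = hka_test(current)
        results.append(res)
        if res.p_value > alpha:
            return RemovalTrace(removed=removed, results=results, final_p=res.p_value)
        if len(current.loci) <= 2:
            raise ValueError(
                "HKA still significant with only 2 loci left; cannot remove further"
            )
        dev = res.deviations
        top = dev.max()
        ties = dev.index[dev == top].tolist()
        if len(ties) > 1:
            warnings.warn(
                f"HKA deviation tie between {ties}; removing {ties[0]} (input order)"
            )
        worst = ties[0]
        removed.append(worst)
        current = current.drop(worst)


def consensus_outliers(
    removal_lists: Sequence[Sequence[str]], threshold: float = 0.5
) -> set[str]:
    """Loci removed in strictly more than ``threshold`` of the per-outgroup
    iterative tests (e.g. >50% = at least 4 of 7) are consensus outliers."""
    if not removal_lists:
        return set()
    n = len(removal_lists)
    counts = Counter(l for lst in removal_lists for l in set(lst))
    return {l for l, c in counts.items() if c / n > threshold}
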