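"""Posterior-sample tables, parameter rescaling, history assembly, and
biweight-kernel joint estimates.

Two posterior dialects are consumed. Two-island (lamarc-style) draws are
scaled per site: Theta = 4*Ne*mu with mu the per-site substitution rate, and
M = m/mu. Isolation-migration (im-style) draws are scaled per locus:
theta = 4*Ne*u with u the geometric-mean per-locus rate, t = T*u, and s the
fraction of the ancestral population founding the NW daughter. Relative
substitution rates mu_R are constrained to average exactly 1 across loci
within every draw, and per-site recombination rates r are expressed relative
to mu.

A "history" is one fully specified parameter set for a whole multilocus
simulation: a demographic draw, a per-locus mu_R vector (kept intact as a
row so the mean-1 constraint survives), a per-locus recombination rate, and
the locus panel (lengths and ploidy factors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import iqr

__all__ = [
    "PosteriorTable",
    "LocusDef",
    "History",
    "HistorySet",
    "JointEstimate",
    "read_posterior",
    "rescale_lamarc_draw",
    "rescale_im_draw",
    "assemble_histories",
    "joint_estimate",
    "geometric_mean",
]

REQUIRED_COLUMNS = {
    "lamarc": ["Theta_OW", "Theta_NW", "M_OW", "M_NW"],
    "im": ["theta_OW", "theta_NW", "theta_A", "M_OW", "M_NW", "t", "s"],
}

_SCALING = {"lamarc": "per_site", "im": "per_locus", "rates": "relative", "recomb": "per_site"}

RATE_MEAN_TOL = 1e-6


@dataclass
class PosteriorTable:
    source: str  # lamarc | im | rates | recomb
    draws: pd.DataFrame

    @property
    def scaling(self) -> str:
        return _SCALING[self.source]

    @property
    def n_rows(self) -> int:
        return len(self.draws)


@dataclass(frozen=True)
class LocusDef:
    locus_id: str
    length: int
    ploidy_factor: float = 1.0


@dataclass
class History:
    """One joint draw: demography plus per-locus nuisance parameters."""

    demographic: dict[str, float]
    mu_R: dict[str, float]
    rho_site: dict[str, float]  # per-site recombination rate relative to mu
    provenance: dict[str, int] = field(default_factory=dict)


@dataclass
class HistorySet:
    histories: list[History]
    panel: list[LocusDef]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.histories)

    def __iter__(self):
        return iter(self.histories)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.panel]


def read_posterior(path: str | Path, source: str) -> PosteriorTable:
    """Read and validate a TSV of posterior draws for the given source."""
    if source not in _SCALING:
        raise ValueError(f"unknown posterior source {source!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty posterior table") from None
    if df.empty:
        raise ValueError(f"{path}: posterior table has no rows")
    required = REQUIRED_COLUMNS.get(source, [])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing} for source {source!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() | ~np.isfinite(vals)]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric or non-finite value at row {bad[0]}, column {col!r}"
            )
        df[col] = vals
    if source == "rates":
        row_means = df.mean(axis=1)
        off = (row_means - 1.0).abs()
        if (off > RATE_MEAN_TOL).any():
            i = int(off.idxmax())
            raise ValueError(
                f"{path}: relative-rate rows must average 1 across loci "
                f"(row {i} averages {row_means[i]:.6g})"
            )
    return PosteriorTable(source=source, draws=df)


def rescale_lamarc_draw(
    draw: Mapping[str, float], mu_R: float, ploidy: float = 1.0
) -> dict[str, float]:
    """Standardise a per-site two-island draw by a relative rate draw.

    Theta is divided by mu_R (placing loci on the shared per-site scale;
    locus-specific L * mu_R * ploidy multipliers re-enter at simulation
    time), M is multiplied by mu_R, and Z linkage scales Theta by 0.75.
    """
    if mu_R <= 0 or ploidy <= 0:
        raise ValueError("mu_R and ploidy must be > 0")
    out = dict(draw)
    for key in ("Theta_OW", "Theta_NW"):
        if out[key] <= 0:
            raise ValueError(f"{key} must be > 0")
        out[key] = out[key] / mu_R * ploidy
    for key in ("M_OW", "M_NW"):
        if out[key] < 0:
            raise ValueError(f"{key} must be >= 0")
        out[key] = out[key] * mu_R
    return out


def geometric_mean(values: Sequence[float]) -> float:
    v = np.asarray(values, dtype=float)
    if (v <= 0).any():
        raise ValueError("geometric mean requires positive values")
    return float(np.exp(np.log(v).mean()))


def rescale_im_draw(
    theta: float,
    fragment_lengths: Mapping[str, int],
    mu_R: Mapping[str, float],
    ploidy: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Convert a per-locus-scaled theta draw to per-locus simulator thetas:
    theta_i = theta / geomean(L) * L_i * mu_R_i * ploidy_i.
    """
    if set(fragment_lengths) != set(mu_R):
        raise ValueError("fragment_lengths and mu_R must cover the same loci")
    gm = geometric_mean(list(fragment_lengths.values()))
    out = {}
    for locus, L in fragment_lengths.items():
        p = 1.0 if ploidy is None else ploidy.get(locus, 1.0)
        out[locus] = theta / gm * L * mu_R[locus] * p
    return out


def assemble_histories(
    tables: Mapping[str, PosteriorTable],
    panel: Sequence[LocusDef],
    n: int = 1000,
    rng: np.random.Generator | None = None,
    replace: bool = False,
) -> HistorySet:
    """Assemble n joint histories from posterior tables.

    Demographic draws are sampled as whole rows (without replacement when
    the table is large enough, preserving within-row correlations), mu_R
    rows are kept intact and paired with histories by a random permutation,
    and recombination rates are drawn independently per locus.
    """
    rng = np.random.default_rng() if rng is None else rng
    demo_key = "im" if "im" in tables else "lamarc"
    if demo_key not in tables:
        raise ValueError("need a 'lamarc' or 'im' posterior table")
    demo = tables[demo_key].draws
    locus_ids = [l.locus_id for l in panel]

    def sample_rows(df: pd.DataFrame, what: str) -> np.ndarray:
        if len(df) >= n and not replace:
            return rng.choice(len(df), size=n, replace=False)
        if not replace:
            raise ValueError(
                f"{what} table has {len(df)} rows < n={n}; pass replace=True "
                "to sample with replacement"
            )
        return rng.choice(len(df), size=n, replace=True)

    demo_idx = sample_rows(demo, "demographic")

    if "rates" in tables:
        rates = tables["rates"].draws
        missing = [l for l in locus_ids if l not in rates.columns]
        if missing:
            raise ValueError(f"rates table missing loci {missing}")
        rate_idx = sample_rows(rates, "rates")
        rate_idx = rate_idx[rng.permutation(n)]  # arbitrary pairing with histories
    else:
        rates = None
        rate_idx = np.zeros(n, dtype=int)

    if "recomb" in tables:
        recomb = tables["recomb"].draws
        missing = [l for l in locus_ids if l not in recomb.columns]
        if missing:
            raise ValueError(f"recombination table missing loci {missing}")
        rec_idx = {
            l: rng.choice(len(recomb), size=n, replace=(len(recomb) < n or replace))
            for l in locus_ids
        }
    else:
        recomb = None
        rec_idx = {}

    histories = []
    for k in range(n):
        di = int(demo_idx[k])
        demo_draw = {c: float(demo.iloc[di][c]) for c in demo.columns}
        if rates is not None:
            ri = int(rate_idx[k])
            mu = {l: float(rates.iloc[ri][l]) for l in locus_ids}
        else:
            ri = -1
            mu = {l: 1.0 for l in locus_ids}
        if recomb is not None:
            rho = {l: float(recomb.iloc[int(rec_idx[l][k])][l]) for l in locus_ids}
        else:
            rho = {l: 0.0 for l in locus_ids}
        histories.append(
            History(
                demographic=demo_draw,
                mu_R=mu,
                rho_site=rho,
                provenance={"demo_row": di, "rates_row": ri},
            )
        )
    return HistorySet(histories=histories, panel=list(panel))


# ---------------------------------------------------------------------------
# Joint estimates across loci

@dataclass
class JointEstimate:
    grid: np.ndarray
    density: np.ndarray  # normalised joint density on the grid
    mode: float
    interval: tuple[float, float]  # narrowest 95% interval
    per_locus_density: np.ndarray | None = None


def _biweight_kde(sample: np.ndarray, grid: np.ndarray, bw: float) -> np.ndarray:
    u = (grid[:, None] - sample[None, :]) / bw
    k = np.where(np.abs(u) <= 1, (15.0 / 16.0) * (1 - u**2) ** 2, 0.0)
    return k.sum(axis=1) / (len(sample) * bw)


def _bandwidth(sample: np.ndarray, scale: float = 0.9) -> float:
    sd = sample.std(ddof=1)
    spread = min(sd, iqr(sample) / 1.34) if iqr(sample) > 0 else sd
    if spread == 0:
        spread = max(abs(sample.mean()) * 1e-3, 1e-12)
    return scale * spread * len(sample) ** (-0.2)


def joint_estimate(
    per_locus_samples: Sequence[np.ndarray],
    n_grid: int = 512,
    bw_scale: float = 0.9,
    mass: float = 0.95,
) -> JointEstimate:
    """Combine per-locus posterior samples by multiplying biweight-kernel
    smoothed densities on a common grid (product in log space), as done for
    joint multilocus parameter estimates.

    Returns the normalised joint curve, its mode, and the narrowest
    interval containing ``mass`` of the joint density.
    """
    samples = [np.asarray(s, dtype=float) for s in per_locus_samples]
    if not samples:
        raise ValueError("need at least one per-locus sample")
    pooled = np.concatenate(samples)
    lo, hi = np.quantile(pooled, [0.001, 0.999])
    if lo == hi:
        lo, hi = lo - 1e-9, hi + 1e-9
    grid = np.linspace(lo, hi, n_grid)
    log_prod = np.zeros(n_grid)
    dens_all = []
    for s in samples:
        d = _biweight_kde(s, grid, _bandwidth(s, bw_scale))
        dens_all.append(d)
        with np.errstate(divide="ignore"):
            log_prod += np.log(d)
    if not np.isfinite(log_prod).any():
        raise ValueError(
            "joint density is zero everywhere on the grid: per-locus "
            "posteriors have disjoint supports"
        )
    log_prod -= np.nanmax(log_prod[np.isfinite(log_prod)])
    joint = np.exp(log_prod)
    joint[~np.isfinite(joint)] = 0.0
    dx = grid[1] - grid[0]
    joint /= joint.sum() * dx
    mode = float(grid[np.argmax(joint)])

    # narrowest interval holding `mass`: scan contiguous windows
    cum = np.concatenate([[0.0], np.cumsum(joint) * dx])
    best = (grid[0], grid[-1])
    best_w = math.inf
    j = 0
    for i in range(n_grid):
        while j < n_grid and cum[j + 1] - cum[i] < mass:
            j += 1
        if j >= n_grid:
            break
        w = grid[j] - grid[i]
        if w < best_w:
            best_w, best = w, (float(grid[i]), float(grid[j]))
    return JointEstimate(
        grid=grid,
        density=joint,
        mode=mode,
        interval=best,
        per_locus_density=np.vstack(dens_all),
    )
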