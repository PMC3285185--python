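"""Structured-coalescent simulator with recombination and infinite-sites
mutation, plus builders for the demographic models used in the pipeline.

Conventions follow Hudson's ms throughout:

* time is measured in units of 4*N0 generations, with N0 anchored to the
  present-day size of deme 0 (the Old World population);
* deme sizes are relative to N0; with k lineages in a deme of relative size
  x the coalescence rate is k*(k-1)/x;
* a deme with growth rate g has size x(t) = x(t_ref) * exp(-g*(t - t_ref))
  going pastward, so positive g means the population grew forward in time;
* ``migration[i][j]`` is the backward rate at which a single lineage in
  deme i moves to deme j (= 4*N0*m_i, where m_i is the forward fraction of
  deme i replaced by immigrants from j each generation — forward rates into
  a deme become backward rates out of it);
* the locus mutation rate is theta_locus = theta_site * L * mu_R * ploidy;
  with one time unit spanning 4*N0 generations a lineage accumulates
  mutations at rate theta_locus per unit branch length (infinite sites on
  continuous positions in [0,1));
* recombination acts at rate rho per lineage per unit time scaled by the
  span of its ancestral material, with rho = rho_locus * ploidy.

The simulation tracks, for every lineage, the intervals of ancestral
material it carries together with the set of sampled alleles descending
through each interval. A segment whose descendant set reaches the full
sample has found its most recent common ancestor and is dropped, so
mutation is applied only where it can produce a segregating site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .popgen_stats import LocusAlignment

__all__ = [
    "DemographicModel",
    "LocusSimSpec",
    "SimulatedLocus",
    "Event",
    "simulate_locus",
    "build_two_island",
    "build_isolation_migration",
    "build_bottleneck",
    "build_hybridization",
    "build_model",
    "realize_sequences",
    "write_ms",
    "read_ms",
]


# ---------------------------------------------------------------------------
# Model containers

@dataclass
class Event:
    time: float
    kind: str  # size_change | growth_change | split_join | migration_change
    payload: dict

    def __post_init__(self) -> None:
        valid = {"size_change", "growth_change", "split_join", "migration_change"}
        if self.kind not in valid:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.time < 0:
            raise ValueError("event time must be >= 0")


@dataclass
class DemographicModel:
    """Deme sizes/growth at present, backward migration matrix, and a
    time-ordered list of demographic events (ms unit conventions)."""

    demes: list[tuple[float, float]]  # (relative size at present, growth rate)
    migration: np.ndarray
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.migration = np.asarray(self.migration, dtype=float)
        nd = len(self.demes)
        if self.migration.shape != (nd, nd):
            raise ValueError("migration matrix shape must match number of demes")
        if (self.migration < 0).any():
            raise ValueError("migration rates must be >= 0")
        for x, _g in self.demes:
            if x <= 0:
                raise ValueError("deme sizes must be > 0")
        self.events = sorted(self.events, key=lambda e: e.time)

    @property
    def n_demes(self) -> int:
        return len(self.demes)


@dataclass
class LocusSimSpec:
    """Per-locus scaling of the mutation and recombination machinery."""

    locus_id: str
    L: int
    mu_R: float = 1.0
    rho_locus: float = 0.0
    ploidy_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.L <= 0 or self.mu_R <= 0 or self.rho_locus < 0:
            raise ValueError(f"locus {self.locus_id}: invalid simulation spec")
        if not (0 < self.ploidy_factor <= 1):
            raise ValueError(f"locus {self.locus_id}: ploidy_factor must be in (0,1]")


@dataclass
class SimulatedLocus:
    """Infinite-sites output: rows = sampled alleles, columns = segregating
    sites at continuous positions in [0,1)."""

    locus_id: str
    matrix: np.ndarray  # (n, S) int8
    positions: np.ndarray  # (S,) float in [0,1)
    deme_of: np.ndarray  # (n,) int deme index per row
    tmrca: float = math.nan

    @property
    def S(self) -> int:
        return int(self.matrix.shape[1])

    def counts_per_deme(self) -> dict[int, int]:
        d, c = np.unique(self.deme_of, return_counts=True)
        return dict(zip(d.tolist(), c.tolist()))


# ---------------------------------------------------------------------------
# Reachability check (no absorbing isolated demes at the final epoch)

def _check_ancestry_reachable(model: DemographicModel, n_per_deme: Sequence[int]) -> None:
    occupied = {i for i, n in enumerate(n_per_deme) if n > 0}
    mig = model.migration.copy()
    merged: dict[int, int] = {}

    def find(i: int) -> int:
        while i in merged:
            i = merged[i]
        return i

    for ev in model.events:
        if ev.kind == "split_join":
            src, dst = find(ev.payload["source"]), find(ev.payload["dest"])
            if src != dst:
                merged[src] = dst
                occupied = {find(i) for i in occupied}
        elif ev.kind == "migration_change":
            if "matrix" in ev.payload:
                mig = np.asarray(ev.payload["matrix"], dtype=float)
            else:
                mig = mig.copy()
                mig[ev.payload["i"], ev.payload["j"]] = ev.payload["rate"]
    occupied = {find(i) for i in occupied}
    if len(occupied) <= 1:
        return
    # final epoch: every occupied deme must reach one common deme
    nd = model.n_demes
    reach = [set() for _ in range(nd)]
    for i in range(nd):
        stack, seen = [find(i)], {find(i)}
        while stack:
            u = stack.pop()
            for v in range(nd):
                fv = find(v)
                if mig[u, v] > 0 and fv not in seen:
                    seen.add(fv)
                    stack.append(fv)
        reach[i] = seen
    common = set.intersection(*(reach[i] for i in occupied))
    if not common:
        raise ValueError(
            "lineages cannot reach a common ancestor: final-epoch migration "
            "leaves occupied demes disconnected"
        )


# ---------------------------------------------------------------------------
# Core simulation

class _Lineage:
    __slots__ = ("deme", "segs", "birth")

    def __init__(self, deme: int, segs: list[tuple[float, float, int]], birth: float):
        self.deme = deme
        self.segs = segs  # sorted, non-overlapping (left, right, leafmask)
        self.birth = birth

    def span(self) -> float:
        return self.segs[-1][1] - self.segs[0][0] if self.segs else 0.0


def _merge_segs(
    a: list[tuple[float, float, int]],
    b: list[tuple[float, float, int]],
    full_mask: int,
) -> list[tuple[float, float, int]]:
    """Union of two ancestral-material segment lists; overlapping intervals
    OR their descendant masks; intervals reaching the full sample (MRCA
    found) are dropped."""
    bounds = sorted({x for l, r, _ in a + b for x in (l, r)})
    out: list[tuple[float, float, int]] = []

    def mask_at(segs: list[tuple[float, float, int]], lo: float) -> int:
        for l, r, m in segs:
            if l <= lo < r:
                return m
            if l > lo:
                break
        return 0

    for lo, hi in zip(bounds[:-1], bounds[1:]):
        m = mask_at(a, lo) | mask_at(b, lo)
        if m == 0 or m == full_mask:
            continue
        if out and out[-1][1] == lo and out[-1][2] == m:
            out[-1] = (out[-1][0], hi, m)
        else:
            out.append((lo, hi, m))
    return out


def simulate_locus(
    model: DemographicModel,
    spec: LocusSimSpec,
    n_per_deme: Sequence[int],
    rng: np.random.Generator,
    theta_site: float = 0.0,
    theta_locus: float | None = None,
) -> SimulatedLocus:
    """Simulate one locus under the structured coalescent.

    ``theta_site`` is the per-site population mutation parameter of the
    reference deme; the locus rate is theta_site * L * mu_R * ploidy unless
    ``theta_locus`` overrides it directly. Deterministic for a given rng
    state.
    """
    if len(n_per_deme) != model.n_demes:
        raise ValueError("n_per_deme length must match number of demes")
    if sum(n_per_deme) < 2:
        raise ValueError("need at least 2 sampled alleles")
    _check_ancestry_reachable(model, n_per_deme)

    if theta_locus is None:
        theta_locus = theta_site * spec.L * spec.mu_R * spec.ploidy_factor
    rho = spec.rho_locus * spec.ploidy_factor
    # one time unit = 4*N0 generations, so a lineage carries 4*N0*mu =
    # theta mutations (and 4*N0*r = rho recombinations) per unit time
    mut_rate = theta_locus
    rho_rate = rho

    n = int(sum(n_per_deme))
    full_mask = (1 << n) - 1
    deme_of = np.concatenate(
        [np.full(k, d, dtype=int) for d, k in enumerate(n_per_deme)]
    )

    # per-deme state
    sizes = [x for x, _ in model.demes]
    growth = [g for _, g in model.demes]
    t_ref = [0.0] * model.n_demes
    mig = model.migration.copy()

    by_deme: list[list[_Lineage]] = [[] for _ in range(model.n_demes)]
    leaf = 0
    for d, k in enumerate(n_per_deme):
        for _ in range(k):
            by_deme[d].append(_Lineage(d, [(0.0, 1.0, 1 << leaf)], 0.0))
            leaf += 1

    sites: list[tuple[float, int]] = []  # (position, carrier mask)
    tmrca = 0.0

    def flush(lin: _Lineage, t: float) -> None:
        life = t - lin.birth
        if life <= 0 or mut_rate == 0:
            return
        for l, r, m in lin.segs:
            lam = mut_rate * life * (r - l)
            if lam <= 0:
                continue
            k = rng.poisson(lam)
            for _ in range(k):
                sites.append((rng.uniform(l, r), m))

    def size_at(d: int, t: float) -> float:
        g = growth[d]
        if g == 0.0:
            return sizes[d]
        return sizes[d] * math.exp(-g * (t - t_ref[d]))

    def coal_wait(d: int, t: float) -> float:
        k = len(by_deme[d])
        if k < 2:
            return math.inf
        rate0 = k * (k - 1) / size_at(d, t)
        g = growth[d]
        e = rng.exponential()
        if g == 0.0:
            return e / rate0
        arg = 1.0 + g * e / rate0
        if arg <= 0:
            return math.inf  # shrinking pastward: possibly no coalescence this epoch
        return math.log(arg) / g

    events = list(model.events)
    ev_idx = 0
    t = 0.0
    nd = model.n_demes
    # running totals kept in plain Python to avoid per-event array churn
    row_tot = [float(mig[d].sum()) for d in range(nd)]
    tot_span = float(sum(lin.span() for demels in by_deme for lin in demels))
    live = sum(len(v) for v in by_deme)
    rexp = rng.exponential
    runif = rng.random

    while live > 1:
        next_ev = events[ev_idx].time if ev_idx < len(events) else math.inf

        # candidate waiting times
        best_dt = math.inf
        action = -1  # deme index for coalescence, -2 migration, -3 recombination
        for d in range(nd):
            dt = coal_wait(d, t)
            if dt < best_dt:
                best_dt, action = dt, d
        tot_mig = 0.0
        for d in range(nd):
            if row_tot[d]:
                tot_mig += len(by_deme[d]) * row_tot[d]
        if tot_mig > 0.0:
            dt = rexp() / tot_mig
            if dt < best_dt:
                best_dt, action = dt, -2
        if rho_rate > 0.0 and tot_span > 0.0:
            dt = rexp() / (rho_rate * tot_span)
            if dt < best_dt:
                best_dt, action = dt, -3

        if math.isinf(best_dt) and math.isinf(next_ev):
            raise RuntimeError(
                "simulation stuck: no coalescence, migration or event can "
                "occur (check migration rates and growth signs)"
            )

        if t + best_dt >= next_ev:
            # advance to the demographic event and apply it
            ev = events[ev_idx]
            te = ev.time
            ev_idx += 1
            for d in range(nd):
                if growth[d] != 0.0:
                    sizes[d] = size_at(d, te)
                    t_ref[d] = te
            t = te
            p = ev.payload
            if ev.kind == "size_change":
                d = p["deme"]
                sizes[d] = p["size"]
                growth[d] = p.get("growth", 0.0)
                t_ref[d] = te
            elif ev.kind == "growth_change":
                d = p["deme"]
                sizes[d] = size_at(d, te)
                growth[d] = p["growth"]
                t_ref[d] = te
            elif ev.kind == "split_join":
                src, dst = p["source"], p["dest"]
                for lin in by_deme[src]:
                    lin.deme = dst
                by_deme[dst].extend(by_deme[src])
                by_deme[src] = []
                mig[src, :] = 0.0
                mig[:, src] = 0.0
                row_tot = [float(mig[d].sum()) for d in range(nd)]
            elif ev.kind == "migration_change":
                if "matrix" in p:
                    mig = np.asarray(p["matrix"], dtype=float).copy()
                else:
                    mig[p["i"], p["j"]] = p["rate"]
                row_tot = [float(mig[d].sum()) for d in range(nd)]
            continue

        t += best_dt
        if action >= 0:  # coalescence in deme `action`
            d = action
            demels = by_deme[d]
            k = len(demels)
            i = int(runif() * k)
            j = int(runif() * (k - 1))
            if j >= i:
                j += 1
            if i < j:
                i, j = j, i
            a = demels.pop(i)
            b = demels.pop(j)
            flush(a, t)
            flush(b, t)
            tmrca = t
            tot_span -= a.span() + b.span()
            merged = _merge_segs(a.segs, b.segs, full_mask)
            live -= 2
            if merged:
                child = _Lineage(d, merged, t)
                demels.append(child)
                tot_span += child.span()
                live += 1
        elif action == -2:  # migration
            u = runif() * tot_mig
            acc = 0.0
            d = nd - 1
            for dd in range(nd):
                acc += len(by_deme[dd]) * row_tot[dd]
                if u <= acc:
                    d = dd
                    break
            row = mig[d]
            u = runif() * row_tot[d]
            acc = 0.0
            dest = nd - 1
            for jj in range(nd):
                acc += row[jj]
                if u <= acc:
                    dest = jj
                    break
            i = int(runif() * len(by_deme[d]))
            lin = by_deme[d].pop(i)
            lin.deme = dest
            by_deme[dest].append(lin)
        else:  # recombination
            u = runif() * tot_span
            acc = 0.0
            lin = None
            for dd in range(nd):
                for i, cand in enumerate(by_deme[dd]):
                    acc += cand.span()
                    if u <= acc:
                        lin = by_deme[dd].pop(i)
                        break
                if lin is not None:
                    break
            if lin is None:  # float round-off at the upper edge
                continue
            flush(lin, t)
            tot_span -= lin.span()
            live -= 1
            lo, hi = lin.segs[0][0], lin.segs[-1][1]
            bp = lo + runif() * (hi - lo)
            left = [(l, min(r, bp), m) for l, r, m in lin.segs if l < bp]
            right = [(max(l, bp), r, m) for l, r, m in lin.segs if r > bp]
            for part in (left, right):
                if part:
                    child = _Lineage(lin.deme, part, t)
                    by_deme[lin.deme].append(child)
                    tot_span += child.span()
                    live += 1

    # flush whatever survived (only possible if loop exited with live <= 1;
    # any remaining material would be ancestral to the whole sample)
    if sites:
        order = np.argsort([p for p, _ in sites], kind="stable")
        positions = np.array([sites[i][0] for i in order])
        matrix = np.zeros((n, len(sites)), dtype=np.int8)
        for col, i in enumerate(order):
            m = sites[i][1]
            for row in range(n):
                if m >> row & 1:
                    matrix[row, col] = 1
    else:
        positions = np.zeros(0)
        matrix = np.zeros((n, 0), dtype=np.int8)

    return SimulatedLocus(spec.locus_id, matrix, positions, deme_of, tmrca)


# ---------------------------------------------------------------------------
# Model builders
#
# Draws arrive on the scales of the inference programs that produced them:
# two-island parameters per site (Theta = 4*Ne*mu, M = m/mu), isolation-
# migration parameters per locus (theta = 4*Ne*u, M = m/u, t = T*u).
# Builders convert everything to the ms conventions above with deme 0 (OW)
# as reference.


def build_two_island(draw: Mapping[str, float]) -> DemographicModel:
    """Two demes of constant size with migration and no events.

    Divergence lies infinitely far in the past, so the two demes must be
    connected by at least one nonzero migration rate. Expected keys:
    Theta_OW, Theta_NW (per site), M_OW, M_NW (m_i/mu, forward rates into
    each deme, transposed here into backward out-rates).
    """
    t_ow, t_nw = draw["Theta_OW"], draw["Theta_NW"]
    m_ow, m_nw = draw["M_OW"], draw["M_NW"]
    if t_ow <= 0 or t_nw <= 0:
        raise ValueError("Theta draws must be > 0")
    if m_ow < 0 or m_nw < 0:
        raise ValueError("migration draws must be >= 0")
    if m_ow == 0 and m_nw == 0:
        raise ValueError(
            "two-island model with both migration rates zero has infinite "
            "expected coalescence time"
        )
    # backward per-lineage rate out of deme i = 4*N0*m_i = Theta_ref * M_i
    mig = np.array([[0.0, t_ow * m_ow], [t_ow * m_nw, 0.0]])
    return DemographicModel(
        demes=[(1.0, 0.0), (t_nw / t_ow, 0.0)], migration=mig
    )


def build_isolation_migration(draw: Mapping[str, float]) -> DemographicModel:
    """Isolation-with-migration: an ancestor of size theta_A splits at time
    t into daughters founded by fractions s (NW) and 1-s (OW) that change
    size exponentially to their present values, with gene flow after the
    split.

    Expected keys (im per-locus scale): theta_OW, theta_NW, theta_A,
    M_OW, M_NW (forward rates into each deme), t, s.
    """
    th_ow, th_nw, th_a = draw["theta_OW"], draw["theta_NW"], draw["theta_A"]
    t_im, s = draw["t"], draw["s"]
    m_ow, m_nw = draw["M_OW"], draw["M_NW"]
    if min(th_ow, th_nw, th_a) <= 0:
        raise ValueError("theta draws must be > 0")
    if not (0 < s < 1):
        raise ValueError(f"founding fraction s must lie in (0,1), got {s}")
    if t_im <= 0:
        raise ValueError("divergence time t must be > 0")
    t_sim = t_im / th_ow  # T*u / (4*N_OW*u) = time in 4*N_OW generations
    x_nw = th_nw / th_ow
    x_a = th_a / th_ow
    # size at the split: (1-s) of the ancestor founds OW, s founds NW
    x_ow_split = (1 - s) * x_a
    x_nw_split = s * x_a
    g_ow = math.log(1.0 / x_ow_split) / t_sim
    g_nw = math.log(x_nw / x_nw_split) / t_sim
    # backward out-rate of deme i = 4*N_OW*m_i = theta_OW * M_i (per-locus
    # scales cancel)
    mig = np.array([[0.0, th_ow * m_ow], [th_ow * m_nw, 0.0]])
    events = [
        Event(t_sim, "split_join", {"source": 1, "dest": 0}),
        Event(t_sim, "size_change", {"deme": 0, "size": x_a, "growth": 0.0}),
    ]
    return DemographicModel(
        demes=[(1.0, g_ow), (x_nw, g_nw)], migration=mig, events=events
    )


def build_bottleneck(
    im_draw: Mapping[str, float],
    theta_ow_lamarc: float,
    rng: np.random.Generator,
) -> DemographicModel:
    """Isolation-migration model with a pre-divergence bottleneck.

    Pastward of the split at t the ancestor keeps shrinking along the OW
    growth trajectory until a bottleneck time t_B drawn uniformly from
    (t, 2t); at t_B the population instantaneously recovers (pastward) to
    ``theta_ow_lamarc``, the long-term OW size expressed in simulator
    relative-size units (callers rescale across program conventions).
    """
    if theta_ow_lamarc <= 0:
        raise ValueError("pre-bottleneck size must be > 0")
    base = build_isolation_migration(im_draw)
    t_sim = im_draw["t"] / im_draw["theta_OW"]
    t_b = rng.uniform(t_sim, 2 * t_sim)
    g_ow = base.demes[0][1]
    events = [e for e in base.events if not (e.kind == "size_change" and e.time == t_sim)]
    x_a = im_draw["theta_A"] / im_draw["theta_OW"]
    events += [
        # ancestor starts at theta_A and continues the OW shrink pastward
        Event(t_sim, "size_change", {"deme": 0, "size": x_a, "growth": g_ow}),
        Event(t_b, "size_change", {"deme": 0, "size": theta_ow_lamarc, "growth": 0.0}),
    ]
    return DemographicModel(demes=base.demes, migration=base.migration, events=events)


def build_hybridization(
    im_draw: Mapping[str, float], fd_draw: Mapping[str, float]
) -> DemographicModel:
    """Isolation-migration model plus gene flow with a third population
    (the falcated duck), which exchanges migrants with the OW deme only and
    joins the gadwall ancestor at t_fd > t.

    fd_draw keys, all scaled to theta_OW: theta_fd_over_ow,
    theta_ow_M_ow (migrants from fd into OW, = 4*N_OW*m), theta_ow_M_fd
    (migrants from OW into fd), t_fd_over_ow (time in 4*N_OW generations).
    """
    base = build_isolation_migration(im_draw)
    t_sim = im_draw["t"] / im_draw["theta_OW"]
    x_fd = fd_draw["theta_fd_over_ow"]
    t_fd = fd_draw["t_fd_over_ow"]
    if x_fd <= 0:
        raise ValueError("falcated-duck size must be > 0")
    if t_fd <= t_sim:
        raise ValueError(
            f"falcated duck split t_fd={t_fd:g} must predate the "
            f"gadwall split t={t_sim:g}"
        )
    mig = np.zeros((3, 3))
    mig[:2, :2] = base.migration
    # structural zeros between fd and NW: introgression must pass through OW
    mig[0, 2] = fd_draw["theta_ow_M_ow"]
    mig[2, 0] = fd_draw["theta_ow_M_fd"]
    events = list(base.events) + [
        Event(t_fd, "split_join", {"source": 2, "dest": 0})
    ]
    demes = base.demes + [(x_fd, 0.0)]
    return DemographicModel(demes=demes, migration=mig, events=events)


def build_model(
    name: str,
    draw: Mapping[str, float],
    rng: np.random.Generator | None = None,
) -> DemographicModel:
    """Dispatch a demographic draw to the right builder.

    ``two_island`` and ``selection_subset`` use the flat keys directly
    (selection is the isolation-migration machinery on a locus subset);
    ``bottleneck`` additionally expects ``theta_ow_lamarc`` in the draw,
    ``hybridization`` expects the fd_* keys.
    """
    if name == "two_island":
        return build_two_island(draw)
    if name == "selection_subset":
        # the selection scenario is the same machinery on a locus subset;
        # the draw's keys decide which demographic family it came from
        if "Theta_OW" in draw:
            return build_two_island(draw)
        return build_isolation_migration(draw)
    if name in ("isolation_migration", "im"):
        return build_isolation_migration(draw)
    if name == "bottleneck":
        if rng is None:
            raise ValueError("bottleneck model requires an rng for t_B")
        return build_bottleneck(draw, draw["theta_ow_lamarc"], rng)
    if name in ("hybridization", "hybrid"):
        fd = {
            "theta_fd_over_ow": draw["theta_fd_over_ow"],
            "theta_ow_M_ow": draw["theta_ow_M_ow"],
            "theta_ow_M_fd": draw["theta_ow_M_fd"],
            "t_fd_over_ow": draw["t_fd_over_ow"],
        }
        return build_hybridization(draw, fd)
    raise ValueError(f"unknown model {name!r}")


# ---------------------------------------------------------------------------
# Sequence realisation and ms-dialect I/O

_BASES = np.array(list("ACGT"))


def realize_sequences(
    sim: SimulatedLocus,
    L: int,
    rng: np.random.Generator,
    locus_id: str | None = None,
    pop_names: Mapping[int, str] | None = None,
    ploidy_factor: float = 1.0,
) -> LocusAlignment:
    """Place the segregating sites of a simulated locus onto a random
    ancestral sequence of length L, each site in a distinct column."""
    S = sim.S
    if S > L:
        raise ValueError(f"cannot place {S} segregating sites in {L} columns")
    anc = _BASES[rng.integers(4, size=L)]
    cols = np.sort(rng.choice(L, size=S, replace=False))
    # order sites by position so column order follows the genetic map
    order = np.argsort(sim.positions, kind="stable")
    n = sim.matrix.shape[0]
    seqs = np.tile(anc, (n, 1))
    for col, site in zip(cols, order):
        derived = _BASES[(np.flatnonzero(_BASES == anc[col])[0] + rng.integers(1, 4)) % 4]
        carriers = sim.matrix[:, site] == 1
        seqs[carriers, col] = derived
    labels = [
        pop_names[d] if pop_names else f"pop{d}" for d in sim.deme_of.tolist()
    ]
    return LocusAlignment(
        locus_id or sim.locus_id,
        ["".join(row) for row in seqs],
        labels,
        fragment_length=L,
        ploidy_factor=ploidy_factor,
    )


def write_ms(sims: Sequence[SimulatedLocus], path, header: str = "hetfit") -> None:
    """Write replicates in the ms output dialect."""
    with open(path, "w") as fh:
        fh.write(f"{header}\n\n")
        for sim in sims:
            fh.write("//\n")
            fh.write(f"segsites: {sim.S}\n")
            if sim.S:
                fh.write(
                    "positions: " + " ".join(f"{p:.5f}" for p in sim.positions) + "\n"
                )
                for row in sim.matrix:
                    fh.write("".join(str(int(x)) for x in row) + "\n")
            fh.write("\n")


def read_ms(path) -> list[SimulatedLocus]:
    """Read replicates from the ms output dialect (deme labels unknown)."""
    sims: list[SimulatedLocus] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    rep = 0
    while i < len(lines):
        if lines[i].startswith("//"):
            rep += 1
            i += 1
            if not lines[i].startswith("segsites:"):
                raise ValueError(f"{path}: malformed replicate {rep}")
            S = int(lines[i].split(":")[1])
            i += 1
            if S == 0:
                sims.append(
                    SimulatedLocus(
                        f"rep{rep}",
                        np.zeros((0, 0), dtype=np.int8),
                        np.zeros(0),
                        np.zeros(0, dtype=int),
                    )
                )
                continue
            positions = np.array(
                [float(x) for x in lines[i].split(":")[1].split()]
            )
            i += 1
            rows = []
            while i < len(lines) and lines[i] and set(lines[i]) <= {"0", "1"}:
                rows.append([int(c) for c in lines[i]])
                i += 1
            matrix = np.array(rows, dtype=np.int8)
            sims.append(
                SimulatedLocus(
                    f"rep{rep}",
                    matrix,
                    positions,
                    np.zeros(matrix.shape[0], dtype=int),
                )
            )
        else:
            i += 1
    return sims
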