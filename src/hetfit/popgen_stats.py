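"""Per-locus and cross-locus summary statistics for phased multilocus data.

Implements the three statistics used throughout the pipeline —

* pi, nucleotide diversity: mean pairwise differences per analysed site;
* Phi_st: AMOVA-based fraction of nucleotide diversity partitioned between
  populations, computed on pairwise-difference distances with a
  label-permutation significance test;
* Tajima's D: the standardised difference between the pairwise-diversity and
  segregating-sites estimators of theta (Tajima 1989).

Alignment columns containing an alignment gap ('-') or an ambiguous base
('N') are removed before any statistic is computed (complete deletion), and
per-site denominators use the surviving columns only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "LocusAlignment",
    "LocusStats",
    "MultiLocusSummary",
    "load_locus_fasta",
    "write_locus_fasta",
    "nucleotide_diversity",
    "tajimas_d",
    "tajima_constants",
    "phi_st",
    "locus_stats",
    "locus_stats_from_matrix",
    "multilocus_summary",
    "read_table1",
]

_VALID = set("ACGTN-")


@dataclass
class LocusAlignment:
    """Phased allele sequences for one locus with population labels.

    ``fragment_length`` is the ungapped reference span used for per-site
    scaling in simulations; ``ploidy_factor`` is 1.0 for autosomal loci and
    0.75 for Z-linked loci (three Z chromosomes per breeding pair).
    """

    locus_id: str
    sequences: list[str]
    pop_labels: list[str]
    fragment_length: int = 0
    ploidy_factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"locus {self.locus_id}: no sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(
                f"locus {self.locus_id}: ragged alignment, lengths {sorted(lengths)}"
            )
        if len(self.pop_labels) != len(self.sequences):
            raise ValueError(
                f"locus {self.locus_id}: {len(self.sequences)} sequences but "
                f"{len(self.pop_labels)} population labels"
            )
        self.sequences = [s.upper() for s in self.sequences]
        bad = set("".join(self.sequences)) - _VALID
        if bad:
            raise ValueError(f"locus {self.locus_id}: invalid characters {sorted(bad)}")
        if not self.fragment_length:
            self.fragment_length = len(self.sequences[0])

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pop_labels:
            seen.setdefault(p)
        return list(seen)

    def subset(self, pop: str) -> "LocusAlignment":
        idx = [i for i, p in enumerate(self.pop_labels) if p == pop]
        if not idx:
            raise ValueError(f"locus {self.locus_id}: no sequences labelled {pop!r}")
        return LocusAlignment(
            self.locus_id,
            [self.sequences[i] for i in idx],
            [pop] * len(idx),
            self.fragment_length,
            self.ploidy_factor,
        )


@dataclass
class LocusStats:
    """Summary statistics for one locus (per-site pi; D per population)."""

    locus_id: str
    pi: float
    phi_st: float | None
    tajd_per_pop: dict[str, float | None]
    tajd_mean: float | None
    S: int
    n_sites_used: int
    phi_st_p: float | None = None
    tajd_total: float | None = None


@dataclass
class MultiLocusSummary:
    """Cross-locus mean / SD / CV per statistic with undefined-value counts."""

    table: pd.DataFrame  # index: statistic; columns: mean, sd, cv, min, max, n_loci, n_undefined
    per_locus: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __getitem__(self, stat: str) -> pd.Series:
        return self.table.loc[stat]


# ---------------------------------------------------------------------------
# I/O

def load_locus_fasta(
    path: str | Path,
    pop_map: Mapping[str, str],
    locus_id: str | None = None,
    fragment_length: int = 0,
    ploidy_factor: float = 1.0,
) -> LocusAlignment:
    """Read one per-locus FASTA of phased alleles, labelling each record
    with its population from ``pop_map`` (record id -> population)."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty FASTA")
    seqs, labels = [], []
    for rec in records:
        if rec.id not in pop_map:
            raise KeyError(f"{path}: record {rec.id!r} missing from population map")
        seqs.append(str(rec.seq))
        labels.append(pop_map[rec.id])
    return LocusAlignment(
        locus_id or path.stem, seqs, labels, fragment_length, ploidy_factor
    )


def write_locus_fasta(aln: LocusAlignment, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(s), id=f"{aln.locus_id}_{i}_{p}", description="")
        for i, (s, p) in enumerate(zip(aln.sequences, aln.pop_labels))
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_popmap(path: str | Path) -> dict[str, str]:
    """Two-column TSV: sample id, population label."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "pop"], dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty population map")
    return dict(zip(df["sample"], df["pop"]))


# ---------------------------------------------------------------------------
# Core statistics

def _clean_matrix(aln: LocusAlignment) -> np.ndarray:
    """Character matrix with every column containing '-' or 'N' removed."""
    mat = np.array([list(s) for s in aln.sequences])
    keep = ~((mat == "-") | (mat == "N")).any(axis=0)
    return mat[:, keep]


def _pairwise_diff_sums(mat: np.ndarray) -> float:
    """Sum of pairwise differences over all sequence pairs.

    Uses per-column allele counts: a column with counts c_a over alleles
    contributes (n^2 - sum c_a^2)/2 mismatching pairs.
    """
    n = mat.shape[0]
    total = 0.0
    for j in range(mat.shape[1]):
        _, counts = np.unique(mat[:, j], return_counts=True)
        total += (n * n - (counts**2).sum()) / 2.0
    return total


def nucleotide_diversity(aln: LocusAlignment) -> tuple[float, int]:
    """Nucleotide diversity per analysed site, and the number of sites used.

    Mean number of pairwise differences between sequences divided by the
    number of columns surviving complete deletion of gap/N columns.
    """
    if aln.n < 2:
        raise ValueError(f"locus {aln.locus_id}: need >=2 sequences for pi")
    mat = _clean_matrix(aln)
    n_sites = mat.shape[1]
    if n_sites == 0:
        raise ValueError(f"locus {aln.locus_id}: no usable columns after gap removal")
    n = aln.n
    pairs = n * (n - 1) / 2.0
    return _pairwise_diff_sums(mat) / pairs / n_sites, n_sites


def segregating_sites(aln: LocusAlignment) -> int:
    mat = _clean_matrix(aln)
    return int(sum(len(np.unique(mat[:, j])) > 1 for j in range(mat.shape[1])))


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima (1989) for sample size n."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d_from_counts(S: int, pi_total: float, n: int) -> float | None:
    """D from segregating sites and mean pairwise differences (per locus).

    Undefined (None) when S == 0 or n < 4.
    """
    if S == 0 or n < 4:
        return None
    c = tajima_constants(n)
    theta_w = S / c["a1"]
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (pi_total - theta_w) / math.sqrt(var)


def tajimas_d(aln: LocusAlignment, pop: str | None = None) -> float | None:
    """Tajima's D for the whole sample or one population; None if undefined."""
    sub = aln if pop is None else aln.subset(pop)
    if sub.n < 4:
        return None
    mat = _clean_matrix(sub)
    if mat.shape[1] == 0:
        return None
    S = int(sum(len(np.unique(mat[:, j])) > 1 for j in range(mat.shape[1])))
    pairs = sub.n * (sub.n - 1) / 2.0
    pi_total = _pairwise_diff_sums(mat) / pairs
    return tajimas_d_from_counts(S, pi_total, sub.n)


def _amova_phi(dist: np.ndarray, labels: np.ndarray) -> float:
    """Two-level AMOVA on a squared-distance matrix; returns Phi_st.

    Negative values are retained (they arise when within-population
    diversity exceeds total diversity).
    """
    N = dist.shape[0]
    pops, inv = np.unique(labels, return_inverse=True)
    k = len(pops)
    iu = np.triu_indices(N, 1)
    ssd_total = dist[iu].sum() / N
    ssd_within = 0.0
    sizes = np.zeros(k)
    for g in range(k):
        idx = np.flatnonzero(inv == g)
        sizes[g] = len(idx)
        sub = dist[np.ix_(idx, idx)]
        ssd_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ssd_among = ssd_total - ssd_within
    df_among, df_within = k - 1, N - k
    ms_within = ssd_within / df_within
    ms_among = ssd_among / df_among
    n_prime = (N - (sizes**2).sum() / N) / (k - 1)
    sigma_a = (ms_among - ms_within) / n_prime
    denom = sigma_a + ms_within
    if denom == 0:
        return 0.0
    return float(sigma_a / denom)


def phi_st(
    aln: LocusAlignment,
    n_permutations: int = 999,
    rng: np.random.Generator | None = None,
) -> tuple[float, float | None]:
    """AMOVA Phi_st on pairwise-difference distances with permutation p.

    Returns (phi_st, p); p is None when n_permutations == 0. The null
    distribution is generated by permuting population labels.
    """
    pops = aln.populations
    if len(pops) < 2:
        raise ValueError(f"locus {aln.locus_id}: need >=2 populations for Phi_st")
    counts = {p: aln.pop_labels.count(p) for p in pops}
    small = [p for p, c in counts.items() if c < 2]
    if small:
        raise ValueError(
            f"locus {aln.locus_id}: populations {small} have <2 sequences"
        )
    mat = _clean_matrix(aln)
    if mat.shape[1] == 0:
        raise ValueError(f"locus {aln.locus_id}: no usable columns after gap removal")
    # pairwise-difference distances double as squared Euclidean distances
    dist = (mat[:, None, :] != mat[None, :, :]).sum(axis=2).astype(float)
    labels = np.asarray(aln.pop_labels)
    obs = _amova_phi(dist, labels)
    if n_permutations <= 0:
        return obs, None
    rng = np.random.default_rng() if rng is None else rng
    hits = 0
    perm = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        if _amova_phi(dist, perm) >= obs:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return obs, p


# ---------------------------------------------------------------------------
# Bundles

def locus_stats(
    aln: LocusAlignment,
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> LocusStats:
    """Bundle pi, Phi_st, per-population Tajima's D and S for one locus."""
    pi, n_sites = nucleotide_diversity(aln)
    S = segregating_sites(aln)
    pops = aln.populations
    phi: float | None = None
    phi_p: float | None = None
    if len(pops) >= 2 and all(aln.pop_labels.count(p) >= 2 for p in pops):
        phi, phi_p = phi_st(aln, n_permutations=n_permutations, rng=rng)
    d_per_pop = {p: tajimas_d(aln, pop=p) for p in pops}
    defined = [d for d in d_per_pop.values() if d is not None]
    d_mean = float(np.mean(defined)) if defined else None
    return LocusStats(
        locus_id=aln.locus_id,
        pi=pi,
        phi_st=phi,
        tajd_per_pop=d_per_pop,
        tajd_mean=d_mean,
        S=S,
        n_sites_used=n_sites,
        phi_st_p=phi_p,
        tajd_total=tajimas_d(aln),
    )


def locus_stats_from_matrix(
    matrix: np.ndarray,
    pop_of: np.ndarray,
    L: int,
    locus_id: str = "sim",
) -> LocusStats:
    """Statistics straight from a 0/1 segregating-site matrix (rows =
    alleles, columns = sites) with ``L`` total sites for per-site scaling.

    Equivalent to realising sequences and calling :func:`locus_stats`, but
    avoids building character alignments inside simulation loops.
    """
    matrix = np.asarray(matrix)
    pop_of = np.asarray(pop_of)
    n, S = matrix.shape
    pairs = n * (n - 1) / 2.0
    if S:
        c = matrix.sum(axis=0)
        pair_diffs = float((c * (n - c)).sum())
    else:
        pair_diffs = 0.0
    pi_site = pair_diffs / pairs / L if pairs else 0.0
    pops = np.unique(pop_of)
    # per-population Tajima's D
    d_per_pop: dict[str, float | None] = {}
    for p in pops:
        rows = matrix[pop_of == p]
        np_ = rows.shape[0]
        if np_ < 4:
            d_per_pop[str(p)] = None
            continue
        cp = rows.sum(axis=0) if S else np.zeros(0)
        Sp = int(((cp > 0) & (cp < np_)).sum()) if S else 0
        pip = float((cp * (np_ - cp)).sum()) / (np_ * (np_ - 1) / 2.0) if S else 0.0
        d_per_pop[str(p)] = tajimas_d_from_counts(Sp, pip, np_)
    defined = [d for d in d_per_pop.values() if d is not None]
    d_mean = float(np.mean(defined)) if defined else None
    # Phi_st from allele counts (statistic only; no permutation test here)
    phi: float | None = None
    if len(pops) >= 2 and all((pop_of == p).sum() >= 2 for p in pops):
        if S == 0:
            phi = 0.0
        else:
            N = n
            k = len(pops)
            ssd_total = pair_diffs / N
            ssd_within = 0.0
            sizes = []
            for p in pops:
                rows = matrix[pop_of == p]
                np_ = rows.shape[0]
                sizes.append(np_)
                cp = rows.sum(axis=0)
                ssd_within += float((cp * (np_ - cp)).sum()) / np_
            ssd_among = ssd_total - ssd_within
            ms_within = ssd_within / (N - k)
            ms_among = ssd_among / (k - 1)
            sizes_arr = np.asarray(sizes, dtype=float)
            n_prime = (N - (sizes_arr**2).sum() / N) / (k - 1)
            sigma_a = (ms_among - ms_within) / n_prime
            denom = sigma_a + ms_within
            phi = 0.0 if denom == 0 else float(sigma_a / denom)
    return LocusStats(
        locus_id=locus_id,
        pi=pi_site,
        phi_st=phi,
        tajd_per_pop=d_per_pop,
        tajd_mean=d_mean,
        S=int(S),
        n_sites_used=L,
        tajd_total=tajimas_d_from_counts(
            int(S), pair_diffs / pairs if pairs else 0.0, n
        ),
    )


_SUMMARY_STATS = ("pi", "phi_st", "tajd")


def multilocus_summary(
    stats: Iterable[LocusStats] | pd.DataFrame,
) -> MultiLocusSummary:
    """Cross-locus mean, SD (n-1 denominator), CV (= sd/|mean|), min, max.

    Accepts either LocusStats objects or a table with columns
    locus, pi, phi_st, tajd. Undefined entries (NaN / None) are excluded
    per statistic and counted.
    """
    if isinstance(stats, pd.DataFrame):
        df = stats.copy()
        if "tajd" not in df and "tajd_mean" in df:
            df = df.rename(columns={"tajd_mean": "tajd"})
    else:
        rows = []
        for s in stats:
            rows.append(
                {
                    "locus": s.locus_id,
                    "pi": s.pi,
                    "phi_st": np.nan if s.phi_st is None else s.phi_st,
                    "tajd": np.nan if s.tajd_mean is None else s.tajd_mean,
                }
            )
        df = pd.DataFrame(rows)
    out = {}
    for stat in _SUMMARY_STATS:
        if stat not in df.columns:
            continue
        v = pd.to_numeric(df[stat], errors="coerce")
        vv = v.dropna().to_numpy(dtype=float)
        n_undef = int(v.isna().sum())
        if len(vv) < 2:
            raise ValueError(f"statistic {stat!r}: fewer than 2 defined values")
        mean = vv.mean()
        sd = vv.std(ddof=1)
        cv = sd / abs(mean) if mean != 0 else np.nan
        out[stat] = {
            "mean": mean,
            "sd": sd,
            "cv": cv,
            "min": vv.min(),
            "max": vv.max(),
            "n_loci": len(vv),
            "n_undefined": n_undef,
        }
    table = pd.DataFrame(out).T
    return MultiLocusSummary(table=table, per_locus=df)


def read_table1(path: str | Path) -> pd.DataFrame:
    """Read a per-locus summary table (columns: locus, length_bp, pi,
    phi_st, tajd; tab-separated, '.' decimal)."""
    df = pd.read_csv(path, sep="\t")
    required = {"locus", "length_bp", "pi", "phi_st", "tajd"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
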