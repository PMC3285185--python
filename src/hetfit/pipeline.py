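"""End-to-end orchestration: assemble histories, simulate posterior
predictive distributions, run dataset-level and locus-specific
goodness-of-fit tests for each requested model, plus the HKA branch.

A run is driven by one YAML config (see RunConfig) and writes a report
bundle: report.tsv / report.json, per-model predictive matrices, and a
manifest with package versions, the seed, and input-file hashes so any
number in the report can be regenerated. Histories and predictive matrices
are cached on disk keyed by (config hash, seed) so reruns are incremental.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, gof, hka, paramspace, popgen_stats

logger = logging.getLogger("hetfit")

KNOWN_MODELS = (
    "two_island",
    "isolation_migration",
    "bottleneck",
    "hybridization",
    "selection_subset",
)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    models: list[str]
    empirical_table: str  # per-locus summary TSV (locus, length_bp, pi, phi_st, tajd)
    posteriors: dict[str, str]  # source -> TSV path (lamarc/im/rates/recomb)
    loci: list[dict]  # [{id, length, ploidy}]
    out_dir: str
    n_histories: int = 1000
    n_per_deme: tuple[int, int] = (50, 50)
    alpha: float = 0.05
    fdr_q: float = 0.05
    seed: int = 0
    selection_exclude: list[str] = field(default_factory=list)
    hka_tables: list[str] = field(default_factory=list)  # per-outgroup TSVs
    consensus_threshold: float = 0.5

    def __post_init__(self) -> None:
        unknown = set(self.models) - set(KNOWN_MODELS)
        if unknown:
            raise ValueError(f"unknown models {sorted(unknown)}")
        if "selection_subset" in self.models and not self.selection_exclude:
            raise ValueError(
                "selection_subset requires an explicit locus-exclusion list"
            )
        for path in [self.empirical_table, *self.posteriors.values(), *self.hka_tables]:
            if not Path(path).exists():
                raise FileNotFoundError(path)

    def panel(self, exclude: Sequence[str] = ()) -> list[paramspace.LocusDef]:
        return [
            paramspace.LocusDef(
                locus_id=l["id"],
                length=int(l["length"]),
                ploidy_factor=float(l.get("ploidy", 1.0)),
            )
            for l in self.loci
            if l["id"] not in exclude
        ]

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["n_per_deme"] = tuple(raw.get("n_per_deme", (50, 50)))
    return RunConfig(**raw)


def _file_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _predictive_cache_path(out_dir: Path, model: str, key: str) -> Path:
    return out_dir / "cache" / f"predictive_{model}_{key}.npz"


def _save_predictive(pred: gof.PredictiveDistribution, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        path,
        locus_ids=np.array(pred.locus_ids),
        model=np.array(pred.model),
        **{f"stat_{s}": pred.values[s] for s in pred.values},
    )


def _load_predictive(path: Path) -> gof.PredictiveDistribution:
    z = np.load(path, allow_pickle=False)
    values = {k[5:]: z[k] for k in z.files if k.startswith("stat_")}
    return gof.PredictiveDistribution(
        locus_ids=[str(x) for x in z["locus_ids"]],
        values=values,
        model=str(z["model"]),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every requested model; a failure in one model is logged and the
    remaining models continue. Returns the report dict (also written to
    disk)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO)

    empirical_df = popgen_stats.read_table1(config.empirical_table)
    tables = {
        src: paramspace.read_posterior(path, src)
        for src, path in config.posteriors.items()
    }
    key = f"{config.config_hash()}_{config.seed}"

    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "models": {},
        "hka": None,
    }
    rows = []
    for model in config.models:
        try:
            exclude = config.selection_exclude if model == "selection_subset" else []
            panel = config.panel(exclude=exclude)
            emp = empirical_df[~empirical_df["locus"].isin(exclude)]
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, KNOWN_MODELS.index(model)])
            )
            histories = paramspace.assemble_histories(
                tables, panel, n=config.n_histories, rng=rng, replace=True
            )
            cache = _predictive_cache_path(out_dir, model, key)
            if cache.exists():
                logger.info("model %s: using cached predictive %s", model, cache)
                pred = _load_predictive(cache)
            else:
                logger.info(
                    "model %s: simulating %d histories x %d loci",
                    model,
                    len(histories),
                    len(panel),
                )
                pred = gof.posterior_predictive(
                    histories, model, n_per_deme=config.n_per_deme, rng=rng
                )
                _save_predictive(pred, cache)
            summary = popgen_stats.multilocus_summary(emp)
            ds = gof.gof_dataset(summary, pred, alpha=config.alpha)
            locus_res = {}
            for stat in gof.STATS:
                emp_vals = dict(zip(emp["locus"], emp[stat if stat != "tajd" else "tajd"]))
                locus_res[stat] = gof.gof_locus_fdr(
                    emp_vals, pred, stat=stat, q=config.fdr_q
                )
            report["models"][model] = {
                "dataset": ds.table.to_dict(orient="records"),
                "locus": {
                    s: r.table.to_dict(orient="records") for s, r in locus_res.items()
                },
            }
            for rec in ds.table.to_dict(orient="records"):
                rows.append({"model": model, "level": "dataset", **rec})
            for s, r in locus_res.items():
                for rec in r.table.to_dict(orient="records"):
                    rows.append({"model": model, "level": "locus", **rec})
        except Exception as exc:  # keep other models running
            logger.error("model %s failed: %s", model, exc)
            report["models"][model] = {"error": str(exc)}

    if config.hka_tables:
        removal_lists = []
        hka_rows = []
        for path in config.hka_tables:
            df = pd.read_csv(path, sep="\t")
            outgroup = str(df["outgroup"].iloc[0]) if "outgroup" in df else Path(path).stem
            inp = hka.HKAInput.from_frame(df, outgroup_id=outgroup)
            trace = hka.iterative_removal(inp, alpha=config.alpha)
            removal_lists.append(trace.removed)
            hka_rows.append(
                {
                    "outgroup": outgroup,
                    "initial_X2": trace.results[0].X2_total,
                    "initial_p": trace.results[0].p_value,
                    "removed": ",".join(trace.removed),
                    "final_p": trace.final_p,
                }
            )
        outliers = hka.consensus_outliers(
            removal_lists, threshold=config.consensus_threshold
        )
        report["hka"] = {
            "per_outgroup": hka_rows,
            "consensus_outliers": sorted(outliers),
        }

    manifest = {
        "hetfit_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "inputs": {
            "empirical_table": _file_hash(config.empirical_table),
            **{f"posterior_{s}": _file_hash(p) for s, p in config.posteriors.items()},
            **{f"hka_{Path(p).stem}": _file_hash(p) for p in config.hka_tables},
        },
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    report["manifest"] = manifest

    pd.DataFrame(rows).to_csv(out_dir / "report.tsv", sep="\t", index=False)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report
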