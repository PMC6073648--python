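"""Top-level pipeline: simulate -> age-adjust -> fit-elasticities -> summarize.

Driven by a small YAML/dict configuration; every stage writes versioned CSV
outputs plus a JSON run report with the package version, a config hash,
per-stage timings and diagnostics.  All randomness flows from the config
seed.  A stage failure halts the run but leaves earlier outputs and the
report on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .age_adjust import age_adjust_dataset
from .elasticity import fit_elasticities, prepare_model_frame
from .io import PopulationDataset, read_records, write_records
from .report import (
    completed_vs_over60_correlation,
    polygyny_gini_regression,
    prop_rich_contrast,
    table_report,
)
from .simulate import (
    LogNormalWealth,
    PopulationConfig,
    SimConfig,
    TwoClassWealth,
    default_sim_config,
    generate_multisite,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "age_adjust", "fit_elasticities", "summarize")

__all__ = ["STAGES", "PipelineError", "sim_config_from_dict", "run_pipeline"]


class PipelineError(RuntimeError):
    pass


def _wealth_from_dict(d: dict):
    kind = d.get("type", "two_class")
    if kind == "two_class":
        return TwoClassWealth(theta=d["theta"], m_r=d["m_r"])
    if kind == "lognormal":
        return LogNormalWealth(
            meanlog=d.get("meanlog", 0.0), sdlog=d.get("sdlog", 0.5)
        )
    raise PipelineError(f"unknown wealth model type {kind!r}")


def sim_config_from_dict(d: dict) -> SimConfig:
    """Build a :class:`SimConfig` from a config mapping.

    Either ``n_per_site`` (default archetype bundle) or an explicit
    ``populations`` list of per-site mappings.
    """
    if "populations" in d:
        pops = []
        for p in d["populations"]:
            p = dict(p)
            p["wealth"] = _wealth_from_dict(p["wealth"])
            pops.append(PopulationConfig(**p))
        return SimConfig(populations=tuple(pops))
    return default_sim_config(n_per_site=int(d.get("n_per_site", 150)))


def run_pipeline(config, out_dir=None) -> Path:
    """Execute the configured stages and return the artifact directory.

    ``config`` is a mapping or a path to a YAML file with keys ``seed``,
    ``out_dir``, ``stages`` and per-stage sections (``simulate`` or
    ``input``, ``age_adjust``, ``elasticity``).
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    stages = [str(s).replace("-", "_") for s in config.get("stages", STAGES)]
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stage name(s): {unknown}; valid stages: {STAGES}")

    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "polythresh_run"))
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package_version": __version__,
        "config_hash": cfg_hash,
        "seed": seed,
        "stages": stages,
        "timings_s": {},
        "status": "running",
    }

    def _save_report():
        (out / "run_report.json").write_text(json.dumps(report, indent=2, default=str))

    dataset: PopulationDataset | None = None
    completed = None
    try:
        if "simulate" in stages:
            t0 = time.perf_counter()
            sim_cfg = sim_config_from_dict(config.get("simulate", {}))
            dataset = generate_multisite(sim_cfg, seed)
            write_records(dataset, out / "records.csv")
            (out / "records_meta.json").write_text(
                json.dumps(
                    {
                        "seed": seed,
                        "package_version": __version__,
                        "n_populations": len(dataset.sites),
                        "n_records": len(dataset.records),
                        "config": config.get("simulate", {}),
                    },
                    indent=2,
                    default=str,
                )
            )
            report["timings_s"]["simulate"] = round(time.perf_counter() - t0, 3)
        elif "input" in config:
            dataset = read_records(config["input"])
        else:
            raise PipelineError("config needs either a 'simulate' stage or an 'input' CSV")

        if "age_adjust" in stages:
            t0 = time.perf_counter()
            aa = config.get("age_adjust", {})
            completed = age_adjust_dataset(
                dataset,
                seed=seed + 1,
                n_draws=int(aa.get("n_draws", 1000)),
                phi=float(aa.get("phi", 0.5)),
            )
            completed.per_male.to_csv(out / "completed_per_male.csv", index=False)
            completed.population_summary.to_csv(
                out / "population_summary.csv", index=False
            )
            report["timings_s"]["age_adjust"] = round(time.perf_counter() - t0, 3)

        if "fit_elasticities" in stages:
            t0 = time.perf_counter()
            el = config.get("elasticity", {})
            frame = prepare_model_frame(dataset, completed=completed)
            est = fit_elasticities(
                frame, seed=seed + 2, n_draws=int(el.get("n_draws", 1000))
            )
            est.per_population.to_csv(out / "elasticities_per_population.csv", index=False)
            est.global_summary.to_csv(out / "elasticities_global.csv", index=False)
            (out / "elasticity_diagnostics.json").write_text(
                json.dumps(est.diagnostics, indent=2, default=str)
            )
            report["timings_s"]["fit_elasticities"] = round(time.perf_counter() - t0, 3)

        if "summarize" in stages:
            t0 = time.perf_counter()
            if completed is None:
                raise PipelineError("summarize requires the age_adjust stage")
            table = table_report(dataset, completed)
            table.populations.to_csv(out / "summary_populations.csv", index=False)
            table.subsistence_means.to_csv(out / "subsistence_means.csv", index=False)

            contrasts = []
            for cat in ("foraging", "horticulture", "agropastoral"):
                try:
                    c = prop_rich_contrast(table.populations, cat)
                    contrasts.append(
                        {
                            "category": cat,
                            "difference_vs_agriculture": c.difference,
                            "lo": c.lo,
                            "hi": c.hi,
                        }
                    )
                except ValueError as exc:
                    logger.info("contrast skipped for %s: %s", cat, exc)
            pd.DataFrame(contrasts).to_csv(out / "contrasts.csv", index=False)

            extras: dict = {}
            for cat in ("horticulture", "agropastoral"):
                try:
                    r = polygyny_gini_regression(table.populations, cat)
                    extras[f"gini_polygyny_slope_{cat}"] = {
                        "slope": r.slope,
                        "lo": r.lo,
                        "hi": r.hi,
                    }
                except ValueError as exc:
                    logger.info("regression skipped for %s: %s", cat, exc)
            try:
                extras["completed_vs_over60_pearson"] = completed_vs_over60_correlation(
                    table.populations
                )
            except ValueError as exc:
                logger.info("correlation skipped: %s", exc)
            report["summary_stats"] = extras
            report["timings_s"]["summarize"] = round(time.perf_counter() - t0, 3)

        report["status"] = "ok"
    except Exception as exc:
        report["status"] = "failed"
        report["error"] = f"{type(exc).__name__}: {exc}"
        _save_report()
        raise
    _save_report()
    return out
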