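"""Pipeline orchestration, configuration and report rendering.

Ties the stages together: thermal indices from station files →
per-animal exposure features → record merge → model suite → rendered
coefficient and incidence tables. Every stage writes its artifact and
logs record counts; a failure stops the run at the failing stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import climate, exposure, models, records

logger = logging.getLogger("darkcut")

__all__ = ["RunConfig", "run_pipeline", "render_tables", "render_fit_text"]

_CONFIG_KEYS = {
    "weather", "animals", "carcasses", "out_dir", "column_maps", "hli",
    "window_days", "min_coverage", "expected_interval", "max_gap_hours",
    "models", "denominator", "seed", "log_level",
}


@dataclass
class RunConfig:
    """Validated run configuration (usually loaded from YAML).

    ``weather`` maps feedlot labels to station CSV paths; feedlots
    absent from the map are excluded from the climatic models, exactly
    as stations with unusable data were excluded in the study.
    """

    weather: dict = field(default_factory=dict)
    animals: str = ""
    carcasses: str = ""
    out_dir: str = "darkcut_out"
    column_maps: dict = field(default_factory=dict)
    hli: climate.HliParams = field(default_factory=climate.HliParams)
    window_days: int = 7
    min_coverage: float = 0.8
    expected_interval: int = 15
    max_gap_hours: float = 6.0
    models: list = field(default_factory=lambda: ["base", "climate1",
                                                  "climate2", "climate3"])
    denominator: str = "total"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        hli = climate.HliParams(**raw.pop("hli", {}))
        cfg = cls(hli=hli, **raw)
        for name in ("animals", "carcasses"):
            p = getattr(cfg, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        return cfg

    def manifest(self) -> dict:
        blob = json.dumps(
            {k: str(v) for k, v in self.__dict__.items()}, sort_keys=True
        )
        return {
            "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
            "seed": self.seed,
        }


def render_fit_text(key, fit) -> str:
    """Aligned plain-text coefficient table for one fitted model."""
    name = f"{key[0]}" + (f" / {key[1]}" if key[1] else "")
    if isinstance(fit, str):
        return f"== {name} ==\n{fit}\n"
    lines = [f"== {name} ==",
             f"{'term':<28}{'OR':>10}{'95% CI':>22}{'p':>10}"]
    for term, row in fit.terms.iterrows():
        ci = f"[{row['ci_low']:.4g}, {row['ci_high']:.4g}]"
        lines.append(
            f"{term:<28}{row['or']:>10.4g}{ci:>22}{row['p']:>10.3g}"
        )
    for g, v in fit.random_variances.items():
        lines.append(f"random intercept var({g}) = {v:.4g}")
    lines.append(f"n = {fit.n_obs}, log-lik = {fit.loglik:.2f}, "
                 f"converged = {fit.converged}")
    return "\n".join(lines) + "\n"


def render_tables(results: dict, out_dir) -> list[Path]:
    """Write one coefficient CSV + text table per fitted model.

    CSV columns are fixed: ``term,estimate,se,or,ci_low,ci_high,p``.
    Failed fits produce a ``.skipped.txt`` notice instead.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for key in sorted(results):
        fit = results[key]
        stem = "_".join(k for k in key if k)
        if isinstance(fit, str):
            p = out_dir / f"model_{stem}.skipped.txt"
            p.write_text(fit + "\n")
            written.append(p)
            continue
        csv_path = out_dir / f"model_{stem}.csv"
        tab = fit.to_frame()[["term", "estimate", "se", "or",
                              "ci_low", "ci_high", "p"]]
        tab.to_csv(csv_path, index=False, float_format="%.10g")
        txt_path = out_dir / f"model_{stem}.txt"
        txt_path.write_text(render_fit_text(key, fit))
        written += [csv_path, txt_path]
    return written


def run_pipeline(config: RunConfig) -> dict:
    """Execute indices → features → merge → fit → report.

    Returns a bundle with the merged records, exposure table, model
    results and paths of everything written. Raises at the failing
    stage; the CLI converts that to a non-zero exit status.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # stage 1: thermal indices per station
    series_by_feedlot = {}
    qc_reports = {}
    for feedlot, path in sorted(config.weather.items()):
        obs = climate.read_weather_csv(
            path, config.column_maps.get("weather")
        )
        clean, qc = climate.qc_and_resample(
            obs, config.expected_interval, config.max_gap_hours
        )
        idx = climate.index_series(clean.dropna(), config.hli)
        series_by_feedlot[feedlot] = idx
        qc_reports[feedlot] = qc.to_dict()
        idx.to_csv(out_dir / f"indices_{feedlot}.csv", index=False)
        logger.info("indices[%s]: %d points (%d masked)", feedlot,
                    len(idx), sum(qc.masked.values()))
    (out_dir / "qc_report.json").write_text(json.dumps(qc_reports, indent=2))

    # stage 2: animal records
    animals = records.read_animals_csv(
        config.animals, config.column_maps.get("animals")
    )
    animals, derive_rep = records.derive_fields(animals)
    carcasses = records.read_carcasses_csv(
        config.carcasses, config.column_maps.get("carcasses")
    )
    merged, merge_rep = records.merge_records(animals, carcasses)
    logger.info("merge: %s", merge_rep.to_dict())

    # stage 3: exposures
    exposures = None
    if series_by_feedlot:
        exposures, missing = exposure.attach_exposures(
            merged, series_by_feedlot,
            window_days=config.window_days,
            min_coverage=config.min_coverage,
            expected_interval=config.expected_interval,
        )
        exposures.to_csv(out_dir / "exposures.csv", index=False)
        missing.to_csv(out_dir / "exposures_missing.csv", index=False)
        logger.info("exposures: %d computed, %d missing",
                    len(exposures), len(missing))
        merged = merged.merge(
            exposures.rename(columns={"animal_id": "nlis"}),
            on="nlis", how="left",
        )
    merged.to_csv(out_dir / "analysis_records.csv", index=False)

    # stage 4: descriptive tables
    for by in ("feedlot", "hgp", "sex"):
        for denom in ("total", "compliant"):
            tab = records.incidence_table(merged, by, denom)
            tab.to_csv(out_dir / f"incidence_{by}_{denom}.csv", index=False)

    # stage 5: model suite
    wanted = [models.base_model_spec()] if "base" in config.models else []
    wanted += [s for s in models.climate_model_specs()
               if s.name in config.models]
    results = models.run_model_suite(merged, wanted)
    paths = render_tables(results, out_dir)

    manifest = {
        **config.manifest(),
        "derive": derive_rep,
        "merge": merge_rep.to_dict(),
        "n_model_tables": len([k for k in results]),
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "records": merged,
        "exposures": exposures,
        "results": results,
        "written": paths,
        "qc": qc_reports,
    }
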