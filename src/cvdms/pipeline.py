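"""End-to-end driver: simulate -> fit -> metrics -> standardize -> report.

Every run is fully determined by one config (YAML) plus a seed: each stage
writes plain headered CSV/JSON artifacts into the output directory, a run
log records the config hash, seed and stage timings, and the config
snapshot is copied next to the outputs so any file can be re-created from
the directory contents alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .data import PersonPeriodTable
from .estimation import STRATIFICATION_SCHEMES, TransitionModel
from .model import CVDMultistateModel
from .reporting import MetricsTable, decompose_tle_gain, disparity_report
from .states import EDUCATION_LEVELS, GENDERS, PERIODS
from .synthetic import SCENARIOS, default_config, default_true_model, simulate_individuals

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "STAGES"]

STAGES = ("simulate", "fit", "metrics", "standardize", "report")

log = logging.getLogger("cvdms")


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name for actionable CLI errors."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated run configuration."""

    seed: int
    scenario: str = "baseline"
    n_persons: int = 50_000
    scheme: str = "total"
    standardize: bool = False
    start_age_month: int = 480
    out_dir: str = "cvdms_run"
    log_level: str = "INFO"
    gap_metrics: tuple[str, ...] = ("tle", "e_free", "e_cvd")

    def validate(self) -> "PipelineConfig":
        checks = [
            ("seed", isinstance(self.seed, int)),
            ("scenario", self.scenario in SCENARIOS),
            ("n_persons", isinstance(self.n_persons, int) and self.n_persons >= 0),
            ("scheme", self.scheme in STRATIFICATION_SCHEMES),
            (
                "standardize",
                not self.standardize or self.scheme == "by_gender_education",
            ),
            ("start_age_month", 480 <= self.start_age_month < 1200),
            ("log_level", self.log_level.upper() in logging._nameToLevel),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"invalid config field {name!r}: {getattr(self, name)!r}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"invalid config field(s): {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("invalid config field 'seed': missing (mandatory)")
        if "gap_metrics" in raw:
            raw["gap_metrics"] = tuple(raw["gap_metrics"])
        return cls(**raw).validate()

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["gap_metrics"] = list(d["gap_metrics"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def digest(self) -> str:
        d = asdict(self)
        d["gap_metrics"] = list(d["gap_metrics"])
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]


# --------------------------------------------------------------------------
# stages (each reads its inputs from, and writes its outputs to, out_dir)
# --------------------------------------------------------------------------


def _out(config: PipelineConfig) -> Path:
    p = Path(config.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def stage_simulate(config: PipelineConfig) -> Path:
    model = default_true_model(config.scenario)
    scen = default_config(config.scenario, n_persons=config.n_persons, seed=config.seed)
    table = simulate_individuals(model, scen)
    path = _out(config) / "person_periods.csv"
    table.to_csv(path)
    log.info("simulate: %d person-period rows -> %s", len(table), path)
    return path


def stage_fit(config: PipelineConfig) -> list[Path]:
    out = _out(config)
    table = PersonPeriodTable.from_csv(out / "person_periods.csv")
    results = CVDMultistateModel(table, scheme=config.scheme).fit()
    paths = []
    for subgroup, tm in results.models.items():
        path = out / f"model_{subgroup.replace('/', '_')}.json"
        tm.to_json(path)
        paths.append(path)
    (out / "summary.txt").write_text(results.summary(), encoding="utf-8")
    log.info("fit: %d subgroup models (converged=%s)", len(paths), results.converged)
    return paths


def _load_results(config: PipelineConfig) -> "CVDMultistateResults":
    from .model import CVDMultistateResults

    out = _out(config)
    table = PersonPeriodTable.from_csv(out / "person_periods.csv")
    model = CVDMultistateModel(table, scheme=config.scheme)
    if config.scheme == "total":
        labels = ["total"]
    elif config.scheme == "by_gender":
        labels = list(GENDERS)
    else:
        labels = [f"{g}/{e}" for g in GENDERS for e in EDUCATION_LEVELS]
    models = {}
    for label in labels:
        path = out / f"model_{label.replace('/', '_')}.json"
        if not path.exists():
            raise FileNotFoundError(f"missing fitted model file {path}; run 'fit' first")
        models[label] = TransitionModel.from_json(path)
    return CVDMultistateResults(model=model, models=models)


def stage_metrics(config: PipelineConfig) -> Path:
    import pandas as pd

    out = _out(config)
    results = _load_results(config)
    frames = []
    for sg in results.models:
        for period in PERIODS:
            frames.append(results.transition_probs(period, sg).to_frame())
    pd.concat(frames, ignore_index=True).to_csv(out / "transition_probs.csv", index=False)
    table = results.metrics_table()
    table.to_csv(out / "metrics.csv")
    log.info("metrics: %d rows -> %s", len(table), out / "metrics.csv")
    return out / "metrics.csv"


def stage_standardize(config: PipelineConfig) -> Path:
    out = _out(config)
    results = _load_results(config)
    weights = {g: results.education_weights(g) for g in GENDERS}
    with open(out / "education_weights.json", "w", encoding="utf-8") as fh:
        json.dump({g: w.to_dict() for g, w in weights.items()}, fh, indent=2)
    table = results.standardized_metrics_table(weights=weights)
    table.to_csv(out / "metrics_standardized.csv")
    log.info("standardize: %d rows -> %s", len(table), out / "metrics_standardized.csv")
    return out / "metrics_standardized.csv"


def stage_report(config: PipelineConfig) -> list[Path]:
    import pandas as pd

    out = _out(config)
    table = MetricsTable.from_csv(out / "metrics.csv", scheme=config.scheme)
    paths = []
    if config.scheme in ("by_gender", "by_gender_education"):
        pairs = [("women", "men")]
        if config.scheme == "by_gender_education":
            pairs = [
                (f"{g}/tertiary", f"{g}/basic") for g in GENDERS
            ]
        frames = [
            disparity_report(table, metric, a, b).to_frame()
            for metric in config.gap_metrics
            for a, b in pairs
        ]
        gap_path = out / "disparities.csv"
        pd.concat(frames, ignore_index=True).to_csv(gap_path, index=False)
        paths.append(gap_path)
    rows = []
    for sg in table.subgroups:
        d = decompose_tle_gain(table, sg, PERIODS[0], PERIODS[-1])
        rows.append(
            {
                "subgroup": sg,
                "d_tle": d.d_tle,
                "d_free": d.d_free,
                "d_cvd": d.d_cvd,
                "pct_free_of_gain": d.pct_free_of_gain,
            }
        )
    dec_path = out / "tle_gain_decomposition.csv"
    pd.DataFrame(rows).to_csv(dec_path, index=False)
    paths.append(dec_path)
    log.info("report: -> %s", ", ".join(str(p) for p in paths))
    return paths


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "fit": stage_fit,
    "metrics": stage_metrics,
    "standardize": stage_standardize,
    "report": stage_report,
}


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> Path:
    """Execute the requested stages in order; returns the output directory.

    Any stage error is re-raised as :class:`PipelineError` naming the stage.
    """
    config.validate()
    out = _out(config)
    level = logging._nameToLevel[config.log_level.upper()]
    handler = logging.FileHandler(out / "run.log", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(level)
    try:
        config.to_yaml(out / "config_snapshot.yaml")
        log.info("run: config hash %s, seed %d", config.digest(), config.seed)
        todo = list(stages or STAGES)
        if not config.standardize and "standardize" in todo and stages is None:
            todo.remove("standardize")
        for name in todo:
            if name not in _STAGE_FUNCS:
                raise PipelineError(name, "unknown stage")
            t0 = time.perf_counter()
            try:
                _STAGE_FUNCS[name](config)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(name, str(err)) from err
            log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
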