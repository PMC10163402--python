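"""Pipeline orchestration: simulate -> preprocess -> fit -> respond -> stats.

A single YAML config drives every stage; unknown keys are rejected.  Each
stage writes plain-text artifacts (CSV/JSON) under ``out_dir/<stage>/``
and the run produces a checksum manifest, so a rerun with the same config
and seed is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arx import CHANNELS
from .feature_statistics import run_feature_statistics
from .preprocessing import EpochSeries, preprocess_participant
from .response_analysis import FEATURE_NAMES, analyze_model
from .synthetic_cohort import (
    SimulationConfig,
    generate_cohort,
    heterogeneous_specs,
)
from .system_identification import ArxModel, fit_participant

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "fit", "respond", "stats")


class ConfigError(ValueError):
    pass


@dataclass
class SimulateSection:
    n_participants: int = 3
    n_days: int = 28
    delivery_failure_prob: float = 0.0
    noise_sd: float = 25.0
    hr_dropout_prob: float = 0.05
    nonwear_blocks_per_week: float = 3.0
    start_date: str = "2019-06-03"


@dataclass
class FitSection:
    order: int = 5
    ridge: float = 0.0


@dataclass
class RespondSection:
    bootstrap: int = 500
    horizon: int = 40


@dataclass
class StatsSection:
    alpha: float = 0.05
    correction: str = "auto"


@dataclass
class PipelineConfig:
    out_dir: str = "runs/demo"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    simulate: SimulateSection = field(default_factory=SimulateSection)
    fit: FitSection = field(default_factory=FitSection)
    respond: RespondSection = field(default_factory=RespondSection)
    stats: StatsSection = field(default_factory=StatsSection)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")


def _build_section(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys in {path}: {sorted(unknown)}")
    return cls(**data)


def load_config(path: Path | str) -> PipelineConfig:
    """Parse and strictly validate a pipeline YAML config."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    sections = {
        "simulate": SimulateSection,
        "fit": FitSection,
        "respond": RespondSection,
        "stats": StatsSection,
    }
    kwargs = {}
    for key, value in data.items():
        if key in sections:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key} must be a mapping")
            kwargs[key] = _build_section(sections[key], value, key)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


# ---------------------------------------------------------------------------
# raw-bundle I/O
# ---------------------------------------------------------------------------


def participant_ids(raw_dir: Path) -> list[str]:
    return sorted(p.name for p in Path(raw_dir).iterdir() if p.is_dir())


def read_raw_bundle(pdir: Path) -> tuple[pd.DataFrame, pd.DataFrame, tuple[int, int]]:
    minutes = pd.read_csv(pdir / "minutes.csv")
    messages = pd.read_csv(pdir / "messages.csv")
    windows = json.loads((pdir / "windows.json").read_text())
    return minutes, messages, (windows["window_start"], windows["window_end"])


def write_epoch_series(series: list[EpochSeries], out_dir: Path) -> list[Path]:
    written = []
    for s in series:
        pdir = out_dir / s.participant_id
        pdir.mkdir(parents=True, exist_ok=True)
        path = pdir / f"epochs_{s.day_date.isoformat()}.csv"
        s.to_frame().to_csv(path, index=False)
        written.append(path)
    return written


def read_epoch_series(pdir: Path) -> list[EpochSeries]:
    series = []
    for path in sorted(pdir.glob("epochs_*.csv")):
        day = dt.date.fromisoformat(path.stem.split("_", 1)[1])
        series.append(EpochSeries.from_frame(pd.read_csv(path), pdir.name, day))
    return series


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig, out: Path) -> list[Path]:
    sim = config.simulate
    sim_config = SimulationConfig(
        n_participants=sim.n_participants,
        n_days=sim.n_days,
        seed=config.seed,
        delivery_failure_prob=sim.delivery_failure_prob,
        start_date=dt.date.fromisoformat(sim.start_date),
    )
    specs = heterogeneous_specs(
        sim.n_participants,
        seed=config.seed,
        noise_sd=sim.noise_sd,
        hr_dropout_prob=sim.hr_dropout_prob,
        nonwear_blocks_per_week=sim.nonwear_blocks_per_week,
    )
    return generate_cohort(sim_config, out, specs=specs)


def stage_preprocess(raw_dir: Path, out: Path) -> list[Path]:
    written = []
    for pid in participant_ids(raw_dir):
        minutes, messages, window = read_raw_bundle(raw_dir / pid)
        series = preprocess_participant(minutes, messages, window, pid)
        written.extend(write_epoch_series(series, out))
    return written


def stage_fit(epochs_dir: Path, out: Path, order: int, ridge: float) -> list[Path]:
    written = []
    for pid in participant_ids(epochs_dir):
        series = read_epoch_series(epochs_dir / pid)
        models = fit_participant(series, order=order, ridge=ridge)
        pdir = out / pid
        pdir.mkdir(parents=True, exist_ok=True)
        for day_type, model in models.items():
            path = pdir / f"model_{day_type}.json"
            model.save(path)
            written.append(path)
            if model.flags:
                logger.warning("%s/%s flagged: %s", pid, day_type, model.flags)
    return written


def stage_respond(models_dir: Path, out: Path, B: int, horizon: int, seed: int) -> list[Path]:
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    written = []
    for pid in participant_ids(models_dir):
        for path in sorted((models_dir / pid).glob("model_*.json")):
            day_type = path.stem.split("_", 1)[1]
            model = ArxModel.load(path)
            digest = hashlib.sha256(f"{pid}|{day_type}|{seed}".encode()).hexdigest()
            model_seed = int(digest[:8], 16)
            analyzed = analyze_model(model, B=B, seed=model_seed, horizon=horizon)
            pdir = out / pid
            pdir.mkdir(parents=True, exist_ok=True)
            for ch, (curve, features) in analyzed.items():
                cpath = pdir / f"curve_{day_type}_{ch}.json"
                cpath.write_text(json.dumps(curve.to_dict(), indent=2))
                written.append(cpath)
                row = {
                    "participant": pid,
                    "day_type": day_type,
                    "message_type": ch,
                    **features.as_dict(),
                    "flags": ";".join(features.flags),
                }
                rows.append(row)
    fpath = out / "features.csv"
    pd.DataFrame(rows).to_csv(fpath, index=False)
    written.append(fpath)
    return written


def features_to_long(features: pd.DataFrame) -> pd.DataFrame:
    """Wide per-model feature rows -> long (participant, message, day, feature)."""
    return features.melt(
        id_vars=["participant", "message_type", "day_type"],
        value_vars=list(FEATURE_NAMES),
        var_name="feature",
        value_name="value",
    )


def stage_stats(features_path: Path, out: Path, alpha: float, correction: str) -> list[Path]:
    features = pd.read_csv(features_path)
    table = features_to_long(features)
    run_feature_statistics(table, out_dir=out, alpha=alpha, correction=correction)
    return sorted(out.glob("*"))


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in order, returning a checksum manifest."""
    root = Path(config.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_seed": config.seed, "stages": {}}
    dirs = {stage: root / stage for stage in STAGES}
    dirs["simulate"] = root / "raw"

    for stage in STAGES:
        if stage not in config.stages:
            continue
        logger.info("running stage %s", stage)
        if stage == "simulate":
            files = stage_simulate(config, dirs["simulate"])
        elif stage == "preprocess":
            files = stage_preprocess(dirs["simulate"], dirs["preprocess"])
        elif stage == "fit":
            files = stage_fit(
                dirs["preprocess"], dirs["fit"], config.fit.order, config.fit.ridge
            )
        elif stage == "respond":
            files = stage_respond(
                dirs["fit"],
                dirs["respond"],
                config.respond.bootstrap,
                config.respond.horizon,
                config.seed,
            )
        else:
            files = stage_stats(
                dirs["respond"] / "features.csv",
                dirs["stats"],
                config.stats.alpha,
                config.stats.correction,
            )
        manifest["stages"][stage] = {
            str(f.relative_to(root)): _checksum(f) for f in sorted(files)
        }

    (root / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# input validation (report-only)
# ---------------------------------------------------------------------------


def validate_inputs(raw_dir: Path | str) -> list[dict]:
    """Column/type/monotonicity checks on a raw cohort directory.

    Returns a list of violation records; an empty list means the bundle is
    well formed.
    """
    raw_dir = Path(raw_dir)
    report: list[dict] = []

    def violation(pid: str, file: str, row: int | None, problem: str) -> None:
        report.append({"participant": pid, "file": file, "row": row, "problem": problem})

    if not raw_dir.is_dir():
        return [{"participant": None, "file": str(raw_dir), "row": None,
                 "problem": "raw directory does not exist"}]

    for pid in participant_ids(raw_dir):
        pdir = raw_dir / pid
        for name, required in (
            ("minutes.csv", {"timestamp", "steps", "hr_present"}),
            ("messages.csv", {"timestamp", "library", "delivered"}),
        ):
            path = pdir / name
            if not path.exists():
                violation(pid, name, None, "file missing")
                continue
            df = pd.read_csv(path)
            missing = required - set(df.columns)
            if missing:
                violation(pid, name, None, f"missing columns {sorted(missing)}")
                continue
            ts = pd.to_datetime(df["timestamp"], errors="coerce")
            for idx in np.flatnonzero(ts.isna().to_numpy()):
                violation(pid, name, int(idx), "unparseable timestamp")
            if name == "minutes.csv":
                if not ts.is_monotonic_increasing:
                    violation(pid, name, None, "timestamps not monotonically increasing")
                bad = np.flatnonzero((df["steps"].to_numpy() < 0))
                for idx in bad:
                    violation(pid, name, int(idx), "negative steps")
                if not df["hr_present"].isin([0, 1]).all():
                    violation(pid, name, None, "hr_present not 0/1")
            else:
                bad = ~df["library"].isin(CHANNELS)
                for idx in np.flatnonzero(bad.to_numpy()):
                    violation(pid, name, int(idx), "unknown library")
        wpath = pdir / "windows.json"
        if not wpath.exists():
            violation(pid, "windows.json", None, "file missing")
        else:
            w = json.loads(wpath.read_text())
            if w.get("window_end", 0) - w.get("window_start", 0) < 600:
                violation(pid, "windows.json", None, "availability window under 10 h")
    return report
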