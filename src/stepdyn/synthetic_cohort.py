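"""Synthetic cohort generator.

Produces virtual participants whose minute-level wearable traces and
message logs follow the study protocol (0-6 messages/day drawn at random,
>=15-minute spacing, availability window of >=10 h, libraries of 54
affective / 54 social-cognitive / 27 quote messages) and whose step
dynamics follow known ground-truth ARX coefficients.  Ground truth is
written next to the data so recovery tests can read it.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .arx import CHANNELS, EPOCH_MINUTES, ArxCoefficients, simulate_arx
from .preprocessing import EpochSeries, day_type_of, extended_window

MIN_WINDOW_MINUTES = 600  # availability window of at least 10 hours
MIN_MESSAGE_GAP = 15
MAX_DAILY_MESSAGES = 6


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class ParticipantSpec:
    """Ground-truth description of one virtual participant."""

    participant_id: str
    weekday_coeffs: ArxCoefficients
    weekend_coeffs: ArxCoefficients
    window_start: int  # minutes since midnight, quarter-hour aligned
    window_end: int
    baseline_rate: float  # mean steps per valid minute
    noise_sd: float  # epoch-level noise SD
    hr_dropout_prob: float
    nonwear_blocks_per_week: float
    allow_unstable: bool = False

    def __post_init__(self) -> None:
        if self.window_end - self.window_start < MIN_WINDOW_MINUTES:
            raise SpecError(
                f"availability window must be >= {MIN_WINDOW_MINUTES} minutes"
            )
        if not (0 <= self.window_start < self.window_end <= 24 * 60):
            raise SpecError("window must lie within the day")
        if self.window_start % EPOCH_MINUTES or self.window_end % EPOCH_MINUTES:
            raise SpecError("window bounds must be quarter-hour aligned")
        if self.baseline_rate < 0 or self.noise_sd < 0:
            raise SpecError("baseline_rate and noise_sd must be >= 0")
        if not 0 <= self.hr_dropout_prob <= 1:
            raise SpecError("hr_dropout_prob must be in [0, 1]")
        if self.nonwear_blocks_per_week < 0:
            raise SpecError("nonwear_blocks_per_week must be >= 0")
        if not self.allow_unstable:
            for name, c in (
                ("weekday", self.weekday_coeffs),
                ("weekend", self.weekend_coeffs),
            ):
                if not c.is_stable():
                    raise SpecError(f"{name} coefficients are unstable")

    def coeffs_for(self, day_type: str) -> ArxCoefficients:
        return self.weekend_coeffs if day_type == "weekend" else self.weekday_coeffs


@dataclass(frozen=True)
class MessageEvent:
    timestamp: dt.datetime  # minute resolution
    library: str  # one of CHANNELS
    delivered: bool

    def __post_init__(self) -> None:
        if self.library not in CHANNELS:
            raise SpecError(f"unknown library {self.library!r}")


@dataclass(frozen=True)
class SimulationConfig:
    n_participants: int = 1
    n_days: int = 7
    seed: int = 0
    library_sizes: tuple[int, int, int] = (54, 54, 27)
    delivery_failure_prob: float = 0.0
    start_date: dt.date = dt.date(2019, 6, 3)  # a Monday
    daily_count_range: tuple[int, int] = (0, MAX_DAILY_MESSAGES)

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_days < 1:
            raise SpecError("n_participants and n_days must be positive")
        if any(s < 1 for s in self.library_sizes):
            raise SpecError("library sizes must be positive")
        if not 0 <= self.delivery_failure_prob <= 1:
            raise SpecError("delivery_failure_prob must be in [0, 1]")
        lo, hi = self.daily_count_range
        if not 0 <= lo <= hi <= MAX_DAILY_MESSAGES:
            raise SpecError("daily_count_range must lie in [0, 6]")
        if isinstance(self.start_date, str):
            object.__setattr__(
                self, "start_date", dt.date.fromisoformat(self.start_date)
            )


def sample_library(config: SimulationConfig, rng: np.random.Generator) -> str:
    """Uniform draw over the pooled message library (sizes 54/54/27)."""
    sizes = np.asarray(config.library_sizes)
    idx = int(rng.integers(0, sizes.sum()))
    return CHANNELS[int(np.searchsorted(np.cumsum(sizes), idx, side="right"))]


def generate_message_schedule(
    day_index: int,
    spec: ParticipantSpec,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[MessageEvent]:
    """One day's schedule: 0-6 messages, >=15 min apart, inside the window.

    The daily count is uniform on ``config.daily_count_range``.  Times are
    uniform over the window subject to the spacing constraint (sequential
    construction: sorted uniform draws over the gap-reduced range, then
    spacing offsets added back).  Each event is independently flagged
    undelivered with ``config.delivery_failure_prob``.
    """
    lo, hi = config.daily_count_range
    count = int(rng.integers(lo, hi + 1))
    day = config.start_date + dt.timedelta(days=day_index)
    if count == 0:
        return []
    span = spec.window_end - spec.window_start
    reduced = span - MIN_MESSAGE_GAP * (count - 1)
    offsets = np.sort(rng.integers(0, reduced + 1, size=count))
    minutes = spec.window_start + offsets + MIN_MESSAGE_GAP * np.arange(count)
    events = []
    for m in minutes:
        ts = dt.datetime.combine(day, dt.time(int(m) // 60, int(m) % 60))
        delivered = bool(rng.random() >= config.delivery_failure_prob)
        events.append(
            MessageEvent(timestamp=ts, library=sample_library(config, rng), delivered=delivered)
        )
    return events


def simulate_epoch_series(
    coeffs: ArxCoefficients,
    u: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent epoch step series from the ARX recursion plus Gaussian noise.

    Pre-window lags are zero; the output is *not* clipped at zero (clipping
    happens only when minutes are emitted).
    """
    if noise_sd < 0:
        raise SpecError("noise_sd must be >= 0")
    u = np.asarray(u, dtype=float)
    n = u.shape[1]
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else None
    return simulate_arx(coeffs, u, noise)


def distribute_to_minutes(
    epoch_steps: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Split epoch totals across their 15 minutes by a uniform multinomial.

    Negative epoch values are floored at zero and totals rounded to the
    nearest integer; per-epoch minute sums reconstruct those totals exactly.
    """
    totals = np.rint(np.clip(np.asarray(epoch_steps, dtype=float), 0, None)).astype(int)
    if totals.size == 0:
        return np.zeros(0, dtype=int)
    p = np.full(EPOCH_MINUTES, 1.0 / EPOCH_MINUTES)
    minutes = rng.multinomial(totals[:, None], p).reshape(len(totals), EPOCH_MINUTES)
    return minutes.ravel()


def inject_missingness(
    minutes: pd.DataFrame,
    spec: ParticipantSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Apply heart-rate dropout and nonwear blocks to a minute table.

    Heart-rate presence is dropped per minute with ``hr_dropout_prob``.
    Nonwear blocks (steps forced to 0, heart rate absent) arrive at
    ``nonwear_blocks_per_week`` per 7 emitted days; block lengths come from
    a mixture of short runs (1-3 min, interpolation path) and long runs
    (4-45 min, exclusion path).
    """
    out = minutes.copy().reset_index(drop=True)
    n = len(out)
    if n == 0:
        return out
    hr = out["hr_present"].astype(bool).to_numpy()
    if spec.hr_dropout_prob > 0:
        hr &= rng.random(n) >= spec.hr_dropout_prob
    steps = out["steps"].to_numpy().copy()

    if spec.nonwear_blocks_per_week > 0:
        n_days = pd.to_datetime(out["timestamp"]).dt.date.nunique()
        n_blocks = int(rng.poisson(spec.nonwear_blocks_per_week * n_days / 7.0))
        for _ in range(n_blocks):
            if rng.random() < 0.4:
                length = int(rng.integers(1, 4))  # exercises interpolation
            else:
                length = int(rng.integers(4, 46))  # exercises exclusion
            start = int(rng.integers(0, n))
            end = min(n, start + length)
            steps[start:end] = 0
            hr[start:end] = False

    out["steps"] = steps
    out["hr_present"] = hr.astype(int)
    return out


# ---------------------------------------------------------------------------
# Participant presets
# ---------------------------------------------------------------------------

#: Weekend steady states are scaled up while weekend dynamics are slower,
#: mirroring the observed day-type contrast in response speed/magnitude.
WEEKEND_SS_SCALE = 2.5


def _first_order_coeffs(a1: float, steady_states: np.ndarray, a0: float) -> ArxCoefficients:
    b = np.zeros((3, 6))
    b[:, 0] = np.asarray(steady_states) * (1.0 - a1)
    a = np.zeros(5)
    a[0] = a1
    return ArxCoefficients(a0=a0, a=a, b=b)


def heterogeneous_specs(
    n_participants: int,
    seed: int,
    noise_sd: float = 25.0,
    hr_dropout_prob: float = 0.05,
    nonwear_blocks_per_week: float = 3.0,
) -> list[ParticipantSpec]:
    """Cohort presets with heterogeneous, mixed-sign steady states.

    Per-participant steady-state targets are drawn identically for the
    three message types (no systematic message effect), span roughly -270
    to +800 cumulative steps, and weekend dynamics are slower and stronger
    than weekday dynamics for every participant.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_participants):
        a_wd = float(rng.uniform(0.30, 0.50))
        a_we = float(rng.uniform(0.55, 0.75))
        mu = rng.normal(150.0, 150.0)
        ss_wd = np.clip(mu + rng.normal(0.0, 120.0, size=3), -270.0, 800.0 / WEEKEND_SS_SCALE)
        ss_we = ss_wd * WEEKEND_SS_SCALE
        baseline = float(rng.uniform(3.0, 9.0))
        a0_wd = baseline * EPOCH_MINUTES * (1.0 - a_wd)
        a0_we = baseline * EPOCH_MINUTES * (1.0 - a_we)
        window_start = int(rng.choice(np.arange(360, 541, EPOCH_MINUTES)))
        length = int(rng.choice(np.arange(MIN_WINDOW_MINUTES, 841, EPOCH_MINUTES)))
        window_end = min(window_start + length, 1410)
        specs.append(
            ParticipantSpec(
                participant_id=f"p{i:03d}",
                weekday_coeffs=_first_order_coeffs(a_wd, ss_wd, a0_wd),
                weekend_coeffs=_first_order_coeffs(a_we, ss_we, a0_we),
                window_start=window_start,
                window_end=window_end,
                baseline_rate=baseline,
                noise_sd=noise_sd,
                hr_dropout_prob=hr_dropout_prob,
                nonwear_blocks_per_week=nonwear_blocks_per_week,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Whole-cohort generation
# ---------------------------------------------------------------------------


def _epoch_grid(spec: ParticipantSpec) -> np.ndarray:
    ext_start, ext_end = extended_window(spec.window_start, spec.window_end)
    return np.arange(ext_start, ext_end - EPOCH_MINUTES + 1, EPOCH_MINUTES)


def _inputs_from_events(
    events: list[MessageEvent], starts: np.ndarray
) -> np.ndarray:
    u = np.zeros((len(CHANNELS), len(starts)), dtype=int)
    for ev in events:
        if not ev.delivered:
            continue
        mod = ev.timestamp.hour * 60 + ev.timestamp.minute
        e = (mod - int(starts[0])) // EPOCH_MINUTES
        if 0 <= e < len(starts):
            u[CHANNELS.index(ev.library), e] = 1
    return u


def simulate_participant_days(
    spec: ParticipantSpec,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[EpochSeries], list[MessageEvent]]:
    """Epoch-level fast path: latent epoch series + message log, no minutes.

    Used directly by large recovery experiments; ``generate_cohort`` adds
    the minute-level emission and missingness on top.
    """
    starts = _epoch_grid(spec)
    series: list[EpochSeries] = []
    all_events: list[MessageEvent] = []
    for day_index in range(config.n_days):
        day = config.start_date + dt.timedelta(days=day_index)
        events = generate_message_schedule(day_index, spec, config, rng)
        all_events.extend(events)
        u = _inputs_from_events(events, starts)
        coeffs = spec.coeffs_for(day_type_of(day))
        y = simulate_epoch_series(coeffs, u, spec.noise_sd, rng)
        series.append(
            EpochSeries(
                participant_id=spec.participant_id,
                day_date=day,
                day_type=day_type_of(day),
                epoch_start_times=starts,
                y=y,
                u=u,
                valid=np.ones(len(starts), dtype=bool),
            )
        )
    return series, all_events


def _emit_minutes(
    series: list[EpochSeries], rng: np.random.Generator
) -> pd.DataFrame:
    """Turn latent epoch series into a minute table (clipped at zero)."""
    frames = []
    for s in series:
        per_min = distribute_to_minutes(s.y, rng)
        base = dt.datetime.combine(s.day_date, dt.time(0, 0))
        offsets = (
            np.repeat(s.epoch_start_times, EPOCH_MINUTES)
            + np.tile(np.arange(EPOCH_MINUTES), s.n_epochs)
        )
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": [base + dt.timedelta(minutes=int(m)) for m in offsets],
                    "steps": per_min,
                    "hr_present": 1,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_participant_bundle(
    spec: ParticipantSpec,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict:
    """All in-memory artifacts for one participant."""
    series, events = simulate_participant_days(spec, config, rng)
    minutes = _emit_minutes(series, rng)
    minutes = inject_missingness(minutes, spec, rng)
    messages = pd.DataFrame(
        {
            "timestamp": [e.timestamp for e in events],
            "library": [e.library for e in events],
            "delivered": [int(e.delivered) for e in events],
        }
    )
    latent = pd.concat([s.to_frame().assign(day_date=s.day_date) for s in series])
    return {
        "spec": spec,
        "minutes": minutes,
        "messages": messages,
        "latent_epochs": latent.reset_index(drop=True),
        "series": series,
    }


def write_bundle(bundle: dict, out_dir: Path) -> list[Path]:
    spec: ParticipantSpec = bundle["spec"]
    pdir = Path(out_dir) / spec.participant_id
    pdir.mkdir(parents=True, exist_ok=True)
    written = []

    minutes = bundle["minutes"].copy()
    minutes["timestamp"] = pd.to_datetime(minutes["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    path = pdir / "minutes.csv"
    minutes.to_csv(path, index=False)
    written.append(path)

    messages = bundle["messages"].copy()
    messages["timestamp"] = pd.to_datetime(messages["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    path = pdir / "messages.csv"
    messages.to_csv(path, index=False)
    written.append(path)

    path = pdir / "windows.json"
    path.write_text(
        json.dumps(
            {"window_start": spec.window_start, "window_end": spec.window_end},
            indent=2,
        )
    )
    written.append(path)

    path = pdir / "ground_truth.json"
    path.write_text(
        json.dumps(
            {
                "participant_id": spec.participant_id,
                "weekday": spec.weekday_coeffs.to_dict(),
                "weekend": spec.weekend_coeffs.to_dict(),
                "baseline_rate": spec.baseline_rate,
                "noise_sd": spec.noise_sd,
                "hr_dropout_prob": spec.hr_dropout_prob,
                "nonwear_blocks_per_week": spec.nonwear_blocks_per_week,
            },
            indent=2,
        )
    )
    written.append(path)

    path = pdir / "latent_epochs.csv"
    bundle["latent_epochs"].to_csv(path, index=False)
    written.append(path)
    return written


def generate_cohort(
    config: SimulationConfig,
    out_dir: Path | str,
    specs: list[ParticipantSpec] | None = None,
) -> list[Path]:
    """Generate and write the full cohort; deterministic in ``config.seed``."""
    if specs is None:
        specs = heterogeneous_specs(config.n_participants, seed=config.seed)
    if len(specs) != config.n_participants:
        raise SpecError("len(specs) must equal n_participants")
    streams = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    written: list[Path] = []
    for spec, ss in zip(specs, streams):
        rng = np.random.default_rng(ss)
        bundle = generate_participant_bundle(spec, config, rng)
        written.extend(write_bundle(bundle, Path(out_dir)))
    return written
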