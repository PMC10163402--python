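"""Raw minute tables + message logs -> valid 15-minute epoch series.

Rules applied per participant-day:

* keep minutes from 2 h before the availability window to 2 h after it
  (clipped to the calendar day — days are independent);
* a minute is *missing* iff it has zero steps and no heart-rate signal;
* missing runs of <= 3 minutes with observed values on both sides are
  linearly interpolated; longer runs (and runs touching the segment edge)
  are excluded;
* minutes are summed into quarter-hour-aligned 15-minute epochs; an epoch
  is valid only if fully covered and free of excluded minutes;
* undelivered messages are dropped before building the input indicators.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arx import CHANNELS, EPOCH_MINUTES

logger = logging.getLogger(__name__)

#: Minutes added on each side of the availability window.
WINDOW_PAD_MINUTES = 120

#: Longest missing run that is filled by linear interpolation.
MAX_INTERP_RUN = 3

MINUTE_COLUMNS = ("timestamp", "steps", "hr_present")
MESSAGE_COLUMNS = ("timestamp", "library", "delivered")


class PreprocessingError(ValueError):
    pass


@dataclass
class EpochSeries:
    """One participant-day of 15-minute epochs ready for model fitting."""

    participant_id: str
    day_date: dt.date
    day_type: str  # "weekday" | "weekend"
    epoch_start_times: np.ndarray  # minutes since midnight, quarter-hour aligned
    y: np.ndarray  # step sum per epoch
    u: np.ndarray  # (3, n_epochs) binary message indicators, CHANNELS order
    valid: np.ndarray  # bool mask per epoch
    d: int = EPOCH_MINUTES

    def __post_init__(self) -> None:
        self.epoch_start_times = np.asarray(self.epoch_start_times, dtype=int)
        self.y = np.asarray(self.y, dtype=float)
        self.u = np.asarray(self.u, dtype=int)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.epoch_start_times)
        if self.y.shape != (n,) or self.valid.shape != (n,):
            raise ValueError("y/valid length mismatch with epoch_start_times")
        if self.u.shape != (len(CHANNELS), n):
            raise ValueError(f"u must have shape (3, {n}), got {self.u.shape}")
        if np.any((self.u != 0) & (self.u != 1)):
            raise ValueError("u entries must be 0/1")

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_start_times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch_start": self.epoch_start_times,
                "y": self.y,
                "u_affective": self.u[0],
                "u_social_cognitive": self.u[1],
                "u_quote": self.u[2],
                "valid": self.valid.astype(int),
            }
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, participant_id: str, day_date: dt.date
    ) -> "EpochSeries":
        return cls(
            participant_id=participant_id,
            day_date=day_date,
            day_type=day_type_of(day_date),
            epoch_start_times=df["epoch_start"].to_numpy(),
            y=df["y"].to_numpy(dtype=float),
            u=np.vstack(
                [
                    df["u_affective"].to_numpy(),
                    df["u_social_cognitive"].to_numpy(),
                    df["u_quote"].to_numpy(),
                ]
            ),
            valid=df["valid"].to_numpy(dtype=bool),
        )


def day_type_of(day: dt.date) -> str:
    """Saturday/Sunday are weekend, everything else weekday."""
    return "weekend" if day.weekday() >= 5 else "weekday"


def extended_window(window_start: int, window_end: int) -> tuple[int, int]:
    """Availability window padded by 2 h each side, clipped to [0, 1440)."""
    return (
        max(0, window_start - WINDOW_PAD_MINUTES),
        min(24 * 60, window_end + WINDOW_PAD_MINUTES),
    )


def merge_streams(
    minutes: pd.DataFrame,
    messages: pd.DataFrame,
    window: tuple[int, int],
) -> tuple[list[tuple[dt.date, pd.DataFrame]], pd.DataFrame]:
    """Merge the minute and message streams for one participant.

    Returns per-day minute segments restricted to the extended availability
    window, plus the delivered in-window messages.  Duplicate minute
    timestamps raise; days with no retained minutes are skipped (logged).
    """
    minutes = minutes.copy()
    minutes["timestamp"] = pd.to_datetime(minutes["timestamp"])
    if minutes["timestamp"].duplicated().any():
        raise PreprocessingError("duplicate minute timestamps")
    minutes = minutes.sort_values("timestamp").reset_index(drop=True)

    ext_start, ext_end = extended_window(*window)
    mod = minutes["timestamp"].dt.hour * 60 + minutes["timestamp"].dt.minute
    minutes["minute_of_day"] = mod
    in_ext = (mod >= ext_start) & (mod < ext_end)
    minutes = minutes.loc[in_ext].reset_index(drop=True)

    messages = messages.copy()
    messages["timestamp"] = pd.to_datetime(messages["timestamp"])
    messages = messages.loc[messages["delivered"].astype(bool)]
    messages = messages.sort_values("timestamp").reset_index(drop=True)
    messages["minute_of_day"] = (
        messages["timestamp"].dt.hour * 60 + messages["timestamp"].dt.minute
    )

    segments: list[tuple[dt.date, pd.DataFrame]] = []
    for day, seg in minutes.groupby(minutes["timestamp"].dt.date, sort=True):
        if seg.empty:
            logger.info("skipping empty day %s", day)
            continue
        segments.append((day, seg.reset_index(drop=True)))
    return segments, messages


def classify_and_interpolate(segment: pd.DataFrame) -> pd.DataFrame:
    """Fill short missing runs and mark long ones excluded.

    ``segment`` must be one contiguous (gap-free, minute-spaced) day slice
    with columns ``timestamp``, ``steps``, ``hr_present``.  Adds float
    ``steps`` (interpolated where filled) plus ``missing``, ``filled`` and
    ``excluded`` boolean columns.
    """
    seg = segment.copy().reset_index(drop=True)
    ts = pd.to_datetime(seg["timestamp"])
    if len(seg) > 1:
        deltas = ts.diff().dropna().dt.total_seconds()
        if not np.all(deltas == 60):
            raise PreprocessingError("minute segment is not gap-free")

    steps = seg["steps"].to_numpy(dtype=float)
    hr = seg["hr_present"].astype(bool).to_numpy()
    missing = (steps == 0) & ~hr
    filled = np.zeros(len(seg), dtype=bool)
    excluded = np.zeros(len(seg), dtype=bool)

    n = len(seg)
    i = 0
    while i < n:
        if not missing[i]:
            i += 1
            continue
        j = i
        while j < n and missing[j]:
            j += 1
        run_len = j - i
        has_flanks = i > 0 and j < n
        if run_len <= MAX_INTERP_RUN and has_flanks:
            left, right = steps[i - 1], steps[j]
            # linear ramp between the flanking observed values
            frac = np.arange(1, run_len + 1) / (run_len + 1)
            steps[i:j] = left + frac * (right - left)
            filled[i:j] = True
        else:
            excluded[i:j] = True
        i = j

    seg["steps"] = steps
    seg["missing"] = missing
    seg["filled"] = filled
    seg["excluded"] = excluded
    return seg


def aggregate_epochs(
    segment: pd.DataFrame,
    messages: pd.DataFrame,
    participant_id: str,
    day_date: dt.date,
) -> EpochSeries:
    """Sum classified minutes into quarter-hour epochs with input indicators.

    Epochs are anchored at clock quarter hours; epochs not fully covered by
    the segment are dropped, and an epoch containing any excluded minute is
    invalid.  ``u_j = 1`` iff a delivered channel-``j`` message falls inside
    the epoch (capped at 1).
    """
    mod = segment["minute_of_day"].to_numpy()
    seg_start, seg_end = int(mod[0]), int(mod[-1]) + 1  # [start, end)
    first_epoch = int(np.ceil(seg_start / EPOCH_MINUTES)) * EPOCH_MINUTES
    starts = np.arange(first_epoch, seg_end - EPOCH_MINUTES + 1, EPOCH_MINUTES)

    steps = segment["steps"].to_numpy(dtype=float)
    excluded = segment["excluded"].to_numpy(dtype=bool)

    y = np.zeros(len(starts))
    valid = np.ones(len(starts), dtype=bool)
    for e, st in enumerate(starts):
        lo = st - seg_start
        hi = lo + EPOCH_MINUTES
        y[e] = steps[lo:hi].sum()
        if excluded[lo:hi].any():
            valid[e] = False

    day_msgs = messages.loc[
        pd.to_datetime(messages["timestamp"]).dt.date == day_date
    ]
    u = np.zeros((len(CHANNELS), len(starts)), dtype=int)
    for _, msg in day_msgs.iterrows():
        j = CHANNELS.index(msg["library"])
        e = (int(msg["minute_of_day"]) - first_epoch) // EPOCH_MINUTES
        if 0 <= int(msg["minute_of_day"]) - first_epoch and e < len(starts):
            u[j, e] = 1

    return EpochSeries(
        participant_id=participant_id,
        day_date=day_date,
        day_type=day_type_of(day_date),
        epoch_start_times=starts,
        y=y,
        u=u,
        valid=valid,
    )


def split_day_type(series: list[EpochSeries]) -> dict[str, list[EpochSeries]]:
    """Partition participant-days into weekday and weekend groups."""
    out: dict[str, list[EpochSeries]] = {"weekday": [], "weekend": []}
    for s in series:
        out[s.day_type].append(s)
    return out


def preprocess_participant(
    minutes: pd.DataFrame,
    messages: pd.DataFrame,
    window: tuple[int, int],
    participant_id: str,
) -> list[EpochSeries]:
    """Full preprocessing chain for one participant."""
    segments, delivered = merge_streams(minutes, messages, window)
    series = []
    for day, seg in segments:
        seg = classify_and_interpolate(seg)
        series.append(aggregate_epochs(seg, delivered, participant_id, day))
    return series
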