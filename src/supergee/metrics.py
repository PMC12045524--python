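"""Extraction of the four per-trial skill metrics and session summaries.

From each 100 Hz trial log four performance variables are computed:

* **SR** (scaling ratio): total left-press duration over total right-press
  duration within the movement window; 1 means braking matched thrust.
* **TR** (time of reversal, ms): onset of the first left press after the
  go cue.
* **TinT** (time in target, ms): cumulative sampled time the cursor spent
  inside the target planet during the movement window; it accrues on
  failed trials too.
* **RT** (response time, ms): time at which the cursor first left the
  start planet after the final go cue.  Reported on the absolute trial
  clock (includes the 1.5 s hold), with the go-relative variant stored
  alongside.

Times are measured on the post-reset timeline: when an early-exit reset
occurred, only the final attempt is scored.  A metric that cannot be
computed for a trial (e.g. RT when the cursor never moved) is undefined
and excluded from that metric's session mean rather than imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .task import EVENT_EARLY_EXIT, SessionArrays, TaskConfig, TrialLog

__all__ = [
    "TrialMetrics",
    "SessionSummary",
    "MalformedLogError",
    "extract_trial_metrics",
    "extract_session_metrics",
    "session_metrics_from_arrays",
    "summarize_session",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ["trial_index", "sr", "tr_ms", "tint_ms", "rt_ms", "rt_go_ms", "success"]


class MalformedLogError(ValueError):
    """Trial log samples are unsorted or not on the uniform grid."""


@dataclass(frozen=True)
class TrialMetrics:
    trial_index: int
    scaling_ratio: Optional[float]
    time_of_reversal_ms: Optional[float]
    time_in_target_ms: float
    response_time_ms: Optional[float]
    response_time_go_ms: Optional[float]
    success: bool


@dataclass(frozen=True)
class SessionSummary:
    """Per-metric means over the trials where the metric is defined."""

    mean_tint: float
    mean_rt: Optional[float]
    mean_rt_go: Optional[float]
    mean_tr: Optional[float]
    mean_sr: Optional[float]
    n_success: int
    n_trials: int
    n_defined: dict[str, int]


def _check_grid(times: np.ndarray, dt: float) -> None:
    if len(times) == 0:
        raise MalformedLogError("empty sample stream")
    gaps = np.diff(times)
    if len(gaps) and (gaps.min() < 0 or np.abs(gaps - dt).max() > 1e-9):
        raise MalformedLogError("samples must be sorted and equally spaced")


def extract_trial_metrics(log: TrialLog, config: TaskConfig) -> TrialMetrics:
    """Compute the four metrics from one trial log.

    The effective trial start is the sample following the last early-exit
    reset; all reported times are relative to it.
    """
    _check_grid(log.times, config.dt)
    reset_times = [t for t, ev in log.events if ev == EVENT_EARLY_EXIT]
    if reset_times:
        t0 = reset_times[-1] + config.dt
        start = int(round((t0 - log.times[0]) * config.sample_rate))
    else:
        start = 0
    t_rel = log.times[start:] - log.times[start]
    x = log.positions[start:]
    kL = log.key_left[start:]
    kR = log.key_right[start:]

    rel_idx = np.arange(len(t_rel))
    window = rel_idx >= config.i_hold

    right_s = float(np.count_nonzero(kR & window)) * config.dt
    left_s = float(np.count_nonzero(kL & window)) * config.dt
    sr = left_s / right_s if right_s > 0 else None

    left_idx = np.flatnonzero(kL & window)
    tr_ms = float(t_rel[left_idx[0]] * 1000.0) if left_idx.size else None

    inside = np.abs(x - config.planet_distance) <= config.planet_radius
    tint_ms = float(np.count_nonzero(inside & window)) * config.dt * 1000.0

    out = np.abs(x) > config.planet_radius
    out_idx = np.flatnonzero(out & window)
    if out_idx.size:
        rt_ms = float(t_rel[out_idx[0]] * 1000.0)
        rt_go_ms = rt_ms - config.hold_duration * 1000.0
    else:
        rt_ms = rt_go_ms = None

    return TrialMetrics(
        trial_index=log.trial_index,
        scaling_ratio=sr,
        time_of_reversal_ms=tr_ms,
        time_in_target_ms=tint_ms,
        response_time_ms=rt_ms,
        response_time_go_ms=rt_go_ms,
        success=log.success,
    )


def session_metrics_from_arrays(sa: SessionArrays) -> pd.DataFrame:
    """Vectorized per-trial metrics straight from batched session arrays.

    Equivalent to running :func:`extract_trial_metrics` on every stitched
    trial log (the arrays hold exactly the post-reset timeline), but one
    pass of array arithmetic for the whole session.
    """
    cfg = sa.config
    n_tr, T = sa.x.shape
    idx = np.arange(T)
    valid = idx[None, :] <= sa.end_idx[:, None]
    window = (idx[None, :] >= cfg.i_hold) & valid

    right_s = (sa.key_right & window).sum(axis=1) * cfg.dt
    left_s = (sa.key_left & window).sum(axis=1) * cfg.dt
    with np.errstate(divide="ignore", invalid="ignore"):
        sr = np.where(right_s > 0, left_s / np.where(right_s > 0, right_s, 1.0), np.nan)

    def first_time_ms(mask: np.ndarray) -> np.ndarray:
        has = mask.any(axis=1)
        first = mask.argmax(axis=1)
        return np.where(has, first / cfg.sample_rate * 1000.0, np.nan)

    tr_ms = first_time_ms(sa.key_left & window)

    inside = np.abs(sa.x - cfg.planet_distance) <= cfg.planet_radius
    tint_ms = (inside & window).sum(axis=1) * cfg.dt * 1000.0

    rt_ms = first_time_ms((np.abs(sa.x) > cfg.planet_radius) & window)
    rt_go_ms = rt_ms - cfg.hold_duration * 1000.0

    return pd.DataFrame(
        {
            "trial_index": np.arange(n_tr),
            "sr": sr,
            "tr_ms": tr_ms,
            "tint_ms": tint_ms,
            "rt_ms": rt_ms,
            "rt_go_ms": rt_go_ms,
            "success": sa.success.astype(bool),
        }
    )


def extract_session_metrics(
    logs: Sequence[TrialLog], config: TaskConfig
) -> pd.DataFrame:
    """Per-trial metrics table for a sequence of trial logs."""
    rows = [extract_trial_metrics(log, config) for log in logs]
    return pd.DataFrame(
        {
            "trial_index": [m.trial_index for m in rows],
            "sr": [np.nan if m.scaling_ratio is None else m.scaling_ratio for m in rows],
            "tr_ms": [np.nan if m.time_of_reversal_ms is None else m.time_of_reversal_ms for m in rows],
            "tint_ms": [m.time_in_target_ms for m in rows],
            "rt_ms": [np.nan if m.response_time_ms is None else m.response_time_ms for m in rows],
            "rt_go_ms": [np.nan if m.response_time_go_ms is None else m.response_time_go_ms for m in rows],
            "success": [m.success for m in rows],
        }
    )


def _mean_defined(values: np.ndarray) -> tuple[Optional[float], int]:
    defined = values[~np.isnan(values)]
    if defined.size == 0:
        return None, 0
    return float(defined.mean()), int(defined.size)


def summarize_session(
    metrics: pd.DataFrame | Iterable[TrialMetrics],
    config: TaskConfig | None = None,
) -> SessionSummary:
    """Session means per metric, each over the trials where it is defined."""
    if not isinstance(metrics, pd.DataFrame):
        metrics = extract_session_metrics_frame(list(metrics))
    if len(metrics) == 0:
        raise ValueError("no trial metrics to summarize")
    out: dict[str, Optional[float]] = {}
    counts: dict[str, int] = {}
    for col in ("tint_ms", "rt_ms", "rt_go_ms", "tr_ms", "sr"):
        out[col], counts[col] = _mean_defined(metrics[col].to_numpy(dtype=float))
    return SessionSummary(
        mean_tint=out["tint_ms"] if out["tint_ms"] is not None else math.nan,
        mean_rt=out["rt_ms"],
        mean_rt_go=out["rt_go_ms"],
        mean_tr=out["tr_ms"],
        mean_sr=out["sr"],
        n_success=int(metrics["success"].sum()),
        n_trials=len(metrics),
        n_defined=counts,
    )


def extract_session_metrics_frame(rows: list[TrialMetrics]) -> pd.DataFrame:
    """Convert TrialMetrics objects to the standard metrics table."""
    return pd.DataFrame(
        {
            "trial_index": [m.trial_index for m in rows],
            "sr": [np.nan if m.scaling_ratio is None else m.scaling_ratio for m in rows],
            "tr_ms": [np.nan if m.time_of_reversal_ms is None else m.time_of_reversal_ms for m in rows],
            "tint_ms": [m.time_in_target_ms for m in rows],
            "rt_ms": [np.nan if m.response_time_ms is None else m.response_time_ms for m in rows],
            "rt_go_ms": [np.nan if m.response_time_go_ms is None else m.response_time_go_ms for m in rows],
            "success": [m.success for m in rows],
        }
    )
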