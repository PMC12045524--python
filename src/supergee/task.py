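"""Headless simulator of the Super G rate-control trial and session.

The task: an astronaut sits on a start planet at position 0 and must land on
a target planet whose center is ``planet_distance`` screen-units to the
right.  Holding the right arrow key applies a constant positive acceleration,
holding the left arrow key an equal negative one; with no key held the
cursor coasts at constant velocity (no gravity, no drag).  A trial lasts
``trial_duration`` seconds, the first ``hold_duration`` of which the cursor
must stay on the start planet (leaving early resets the attempt).  Landing
requires staying within the target planet's radius for
``landing_duration`` continuous seconds inside the movement window.

Dynamics are integrated with semi-implicit Euler on the 100 Hz sample grid,
which is also the logging grid, so key presses are quantized to samples.
The session core is vectorized across the 75 trials of a session; the
per-trial API (`run_trial`) and the log-producing API (`run_session`) are
thin views over the same arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Optional, Protocol, Sequence

import numpy as np

__all__ = [
    "TaskConfig",
    "TrialState",
    "TrialLog",
    "SessionLog",
    "SessionArrays",
    "ControllerPolicy",
    "TrialPlan",
    "InvalidStateError",
    "ControllerContractError",
    "step_dynamics",
    "run_trial",
    "run_session",
    "run_session_arrays",
]

PHASE_HOLD = "hold"
PHASE_GO = "go"
PHASE_DONE = "done"

EVENT_GO_CUE = "go_cue"
EVENT_EARLY_EXIT = "early_exit_reset"
EVENT_LANDED = "landed"
EVENT_TRIAL_END = "trial_end"

#: resets tolerated before pre-go key presses are suppressed so a trial
#: cannot loop forever on a systematically early exit plan
MAX_RESETS_PER_TRIAL = 50


class InvalidStateError(ValueError):
    """A trial state contains non-finite fields."""


class ControllerContractError(TypeError):
    """A controller returned key states that are not boolean arrays."""


@dataclass(frozen=True)
class TaskConfig:
    """Geometry, timing and sampling parameters of the task.

    Defaults follow the deployed game where its rules state them (4.5 s
    trial split into a 1.5 s hold and a 3 s movement window, 1 s continuous
    landing, 100 Hz sampling, 75 trials over a 16-planet chain).  The force
    magnitude, planet distance and planet radius are not published; the
    defaults are chosen so that the ideal bang-bang strategy completes with
    a comfortable margin, and all three are configurable.
    """

    hold_duration: float = 1.5
    movement_window: float = 3.0
    trial_duration: float = 4.5
    landing_duration: float = 1.0
    sample_rate: float = 100.0
    force_accel: float = 2.0
    planet_distance: float = 1.0
    planet_radius: float = 0.08
    n_trials: int = 75
    n_planets: int = 16

    def __post_init__(self) -> None:
        if not math.isclose(self.trial_duration, self.hold_duration + self.movement_window):
            raise ValueError(
                "trial_duration must equal hold_duration + movement_window "
                f"({self.trial_duration} != {self.hold_duration} + {self.movement_window})"
            )
        if self.landing_duration > self.movement_window:
            raise ValueError("landing_duration must not exceed movement_window")
        if self.planet_radius >= self.planet_distance / 2:
            raise ValueError("planet_radius must be < planet_distance / 2")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.n_trials < 1 or self.n_planets < 1:
            raise ValueError("n_trials and n_planets must be >= 1")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def n_samples(self) -> int:
        """Samples per uninterrupted attempt, including t=0."""
        return int(round(self.trial_duration * self.sample_rate)) + 1

    @property
    def i_hold(self) -> int:
        """Sample index of the go cue."""
        return int(round(self.hold_duration * self.sample_rate))

    @property
    def n_landing(self) -> int:
        """Grid steps spanning the continuous landing requirement."""
        return int(round(self.landing_duration * self.sample_rate))

    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


@dataclass
class TrialState:
    """Instantaneous state of one trial (single-step API)."""

    time: float = 0.0
    position: float = 0.0
    velocity: float = 0.0
    phase: str = PHASE_HOLD
    key_left: bool = False
    key_right: bool = False


@dataclass
class TrialLog:
    """100 Hz record of one trial, including any pre-reset segments.

    ``times`` are on the trial's continuous clock (monotone, equally spaced
    at 1/sample_rate); an ``early_exit_reset`` event marks where the attempt
    clock restarted.  Scoring (see :mod:`supergee.metrics`) uses only the
    timeline after the final reset.
    """

    trial_index: int
    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    key_left: np.ndarray
    key_right: np.ndarray
    events: list[tuple[float, str]]
    success: bool

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class SessionLog:
    """All trials of one sitting plus the planet chain actually traversed."""

    trial_logs: list[TrialLog]
    planet_sequence: list[tuple[int, int]]
    hour_played: int
    timestamp: str
    config: TaskConfig


class TrialPlan(Protocol):
    """Key schedule for one attempt: vectorized over sample times."""

    def keys(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (key_left, key_right) boolean arrays for sample times t."""
        ...


class ControllerPolicy(Protocol):
    """A synthetic participant: yields one key-press plan per attempt."""

    def plan_trial(self, trial_index: int, rng: np.random.Generator) -> TrialPlan:
        ...


def step_dynamics(state: TrialState, dt: float, config: TaskConfig) -> TrialState:
    """Advance the point-mass one step with semi-implicit Euler.

    Right key only: +force_accel; left key only: -force_accel; neither or
    both: zero net force, so velocity is exactly conserved while coasting.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    for v in (state.time, state.position, state.velocity):
        if not math.isfinite(v):
            raise InvalidStateError(f"non-finite trial state: {state}")
    accel = config.force_accel * (int(state.key_right) - int(state.key_left))
    velocity = state.velocity + accel * dt
    position = state.position + velocity * dt
    return replace(state, time=state.time + dt, position=position, velocity=velocity)


def _integrate(key_left: np.ndarray, key_right: np.ndarray, config: TaskConfig):
    """Semi-implicit Euler over the sample grid, vectorized on the last axis.

    Keys at sample i act over [t_i, t_i + dt): v[i+1] = v[i] + a[i] dt,
    x[i+1] = x[i] + v[i+1] dt, from rest at the origin.
    """
    accel = config.force_accel * (
        key_right.astype(np.float64) - key_left.astype(np.float64)
    )
    dv = accel * config.dt
    v = np.zeros_like(dv)
    np.cumsum(dv[..., :-1], axis=-1, out=v[..., 1:])
    x = np.zeros_like(v)
    np.cumsum(v[..., 1:] * config.dt, axis=-1, out=x[..., 1:])
    return x, v


def _validate_keys(kL: np.ndarray, kR: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    for arr in (kL, kR):
        a = np.asarray(arr)
        if a.dtype != np.bool_ or a.shape != (n,):
            raise ControllerContractError(
                f"controller must return boolean key arrays of shape ({n},), "
                f"got dtype={a.dtype} shape={a.shape}"
            )
    return np.asarray(kL), np.asarray(kR)


@dataclass
class _ResetSegment:
    """Samples of one aborted attempt (relative clock, ends at the exit)."""

    n: int  # samples recorded, including the violating one
    x: np.ndarray
    v: np.ndarray
    kL: np.ndarray
    kR: np.ndarray


@dataclass
class SessionArrays:
    """Batched final-attempt arrays for all trials of one session.

    ``x``, ``v``, ``key_left``, ``key_right`` have shape (n_trials,
    n_samples); ``end_idx[i]`` is the last valid sample index of trial i
    (samples beyond it were never emitted because the trial ended at the
    landed event).  ``offsets[i]`` is the continuous-clock time at which
    trial i's final attempt started (nonzero only after resets).
    """

    config: TaskConfig
    t_rel: np.ndarray
    x: np.ndarray
    v: np.ndarray
    key_left: np.ndarray
    key_right: np.ndarray
    end_idx: np.ndarray
    success: np.ndarray
    land_idx: np.ndarray  # sample index of the landed event, -1 if none
    offsets: np.ndarray
    resets: list[list[_ResetSegment]]

    @property
    def n_trials(self) -> int:
        return self.x.shape[0]


def _first_true(mask: np.ndarray) -> np.ndarray:
    """Row-wise index of the first True, -1 where a row has none."""
    any_ = mask.any(axis=-1)
    idx = mask.argmax(axis=-1)
    return np.where(any_, idx, -1)


def _detect_landing(x: np.ndarray, config: TaskConfig) -> np.ndarray:
    """Sample index at which the continuous-landing requirement completes.

    A landing completes at the first sample that ends a run of
    n_landing + 1 consecutive in-target samples (elapsed time equal to
    landing_duration); -1 where the trial never lands.  The start planet
    occupies positions near 0 so in-target samples cannot occur before the
    go cue on a reset-sound timeline.
    """
    inside = np.abs(x - config.planet_distance) <= config.planet_radius
    T = x.shape[-1]
    idx = np.arange(T)
    # index of the most recent not-inside sample (-1 if run extends to start)
    last_out = np.maximum.accumulate(np.where(~inside, idx, -1), axis=-1)
    run_len = idx - last_out  # consecutive inside samples ending here
    return _first_true(run_len >= config.n_landing + 1)


def run_session_arrays(
    config: TaskConfig,
    controller: ControllerPolicy,
    rng: np.random.Generator | int,
) -> SessionArrays:
    """Simulate every trial of a session on the batched grid.

    Each trial draws a plan from the controller; attempts that leave the
    start planet before the go cue are reset (clock restarted, plan
    redrawn, attempt not consumed) up to MAX_RESETS_PER_TRIAL, after which
    pre-go presses are suppressed so the session always terminates.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_tr, T = config.n_trials, config.n_samples
    t = config.time_grid()

    kL = np.zeros((n_tr, T), dtype=bool)
    kR = np.zeros((n_tr, T), dtype=bool)
    for i in range(n_tr):
        plan = controller.plan_trial(i, rng)
        kL[i], kR[i] = _validate_keys(*plan.keys(t), T)

    offsets = np.zeros(n_tr)
    resets: list[list[_ResetSegment]] = [[] for _ in range(n_tr)]
    x, v = _integrate(kL, kR, config)

    active = np.arange(n_tr)
    n_resets = np.zeros(n_tr, dtype=int)
    while active.size:
        pre_go = np.abs(x[active, : config.i_hold]) > config.planet_radius
        exit_idx = _first_true(pre_go)
        hit = exit_idx >= 0
        if not hit.any():
            break
        for row, j in zip(active[hit], exit_idx[hit]):
            resets[row].append(
                _ResetSegment(
                    n=j + 1,
                    x=x[row, : j + 1].copy(),
                    v=v[row, : j + 1].copy(),
                    kL=kL[row, : j + 1].copy(),
                    kR=kR[row, : j + 1].copy(),
                )
            )
            offsets[row] += (j + 1) * config.dt
            n_resets[row] += 1
            plan = controller.plan_trial(row, rng)
            kL[row], kR[row] = _validate_keys(*plan.keys(t), T)
            if n_resets[row] >= MAX_RESETS_PER_TRIAL:
                kL[row, : config.i_hold] = False
                kR[row, : config.i_hold] = False
        redo = active[hit]
        x[redo], v[redo] = _integrate(kL[redo], kR[redo], config)
        active = redo

    land_idx = _detect_landing(x, config)
    success = land_idx >= 0
    end_idx = np.where(success, land_idx, T - 1)
    return SessionArrays(
        config=config,
        t_rel=t,
        x=x,
        v=v,
        key_left=kL,
        key_right=kR,
        end_idx=end_idx,
        success=success,
        land_idx=land_idx,
        offsets=offsets,
        resets=resets,
    )


def _trial_log_from_arrays(sa: SessionArrays, i: int) -> TrialLog:
    """Stitch reset segments and the final attempt into one continuous log."""
    cfg = sa.config
    dt = cfg.dt
    parts_t, parts_x, parts_v, parts_l, parts_r = [], [], [], [], []
    events: list[tuple[float, str]] = []
    offset = 0.0
    for seg in sa.resets[i]:
        seg_t = offset + np.arange(seg.n) * dt
        parts_t.append(seg_t)
        parts_x.append(seg.x)
        parts_v.append(seg.v)
        parts_l.append(seg.kL)
        parts_r.append(seg.kR)
        events.append((float(seg_t[-1]), EVENT_EARLY_EXIT))
        offset += seg.n * dt
    end = int(sa.end_idx[i])
    final_t = offset + sa.t_rel[: end + 1]
    parts_t.append(final_t)
    parts_x.append(sa.x[i, : end + 1])
    parts_v.append(sa.v[i, : end + 1])
    parts_l.append(sa.key_left[i, : end + 1])
    parts_r.append(sa.key_right[i, : end + 1])

    events.append((offset + cfg.hold_duration, EVENT_GO_CUE))
    end_time = float(final_t[-1])
    if sa.success[i]:
        events.append((end_time, EVENT_LANDED))
    events.append((end_time, EVENT_TRIAL_END))
    events.sort(key=lambda e: e[0])
    return TrialLog(
        trial_index=i,
        times=np.concatenate(parts_t),
        positions=np.concatenate(parts_x),
        velocities=np.concatenate(parts_v),
        key_left=np.concatenate(parts_l),
        key_right=np.concatenate(parts_r),
        events=events,
        success=bool(sa.success[i]),
    )


def planet_sequence_from_successes(successes: Sequence[bool]) -> list[tuple[int, int]]:
    """(start, target) planet ids per trial under the chain progression rule.

    A success reveals a new planet: the landed target becomes the next
    start; a failure leaves the pair unchanged.  Ids increment without
    wrapping (the game's display name would be ``id % n_planets``).
    """
    seq = []
    start = 0
    for s in successes:
        seq.append((start, start + 1))
        if s:
            start += 1
    return seq


def run_trial(
    config: TaskConfig,
    controller: ControllerPolicy,
    rng_seed: int | np.random.Generator,
    trial_index: int = 0,
) -> TrialLog:
    """Simulate a single trial and return its complete log."""
    one = replace(config, n_trials=1)

    class _Shim:
        def plan_trial(self, i: int, rng: np.random.Generator) -> TrialPlan:
            return controller.plan_trial(trial_index, rng)

    sa = run_session_arrays(one, _Shim(), rng_seed)
    log = _trial_log_from_arrays(sa, 0)
    log.trial_index = trial_index
    return log


def run_session(
    config: TaskConfig,
    controller: ControllerPolicy,
    rng_seed: int | np.random.Generator,
    hour_played: int = 14,
    timestamp: Optional[str] = None,
) -> SessionLog:
    """Simulate all trials of one sitting and assemble the full log."""
    sa = run_session_arrays(config, controller, rng_seed)
    logs = [_trial_log_from_arrays(sa, i) for i in range(sa.n_trials)]
    return SessionLog(
        trial_logs=logs,
        planet_sequence=planet_sequence_from_successes(sa.success),
        hour_played=int(hour_played),
        timestamp=timestamp or datetime.now().isoformat(timespec="seconds"),
        config=config,
    )
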