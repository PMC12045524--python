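"""Independent brute-force oracles used only by the tests.

These deliberately re-derive quantities with plain Python loops and scalar
arithmetic, sharing no code with the package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np

from supergee.task import EVENT_EARLY_EXIT, TaskConfig, TrialLog


def reference_trial_metrics(log: TrialLog, config: TaskConfig) -> dict:
    """Naive full-scan extraction of the four skill metrics."""
    dt = 1.0 / config.sample_rate
    resets = [t for t, ev in log.events if ev == EVENT_EARLY_EXIT]
    if resets:
        t0 = resets[-1] + dt
        start = next(i for i, t in enumerate(log.times) if t >= t0 - 1e-9)
    else:
        start = 0
    hold_i = int(round(config.hold_duration * config.sample_rate))

    right = left = inside = 0
    tr = rt = None
    for j in range(start, len(log.times)):
        rel = j - start
        if rel < hold_i:
            continue
        t_rel_ms = rel * dt * 1000.0
        if log.key_right[j]:
            right += 1
        if log.key_left[j]:
            left += 1
            if tr is None:
                tr = t_rel_ms
        if abs(log.positions[j] - config.planet_distance) <= config.planet_radius:
            inside += 1
        if rt is None and abs(log.positions[j]) > config.planet_radius:
            rt = t_rel_ms
    return {
        "sr": (left / right) if right > 0 else None,
        "tr_ms": tr,
        "tint_ms": inside * dt * 1000.0,
        "rt_ms": rt,
        "rt_go_ms": None if rt is None else rt - config.hold_duration * 1000.0,
        "success": log.success,
    }


class RandomIntervalPolicy:
    """Uninformed participant: uniformly random press intervals, sometimes
    leaving before the go cue (exercising the reset path)."""

    def plan_trial(self, trial_index: int, rng: np.random.Generator):
        from supergee.controller import _IntervalPlan

        return _IntervalPlan(
            t_go=rng.uniform(1.2, 2.6),
            tau_r=rng.uniform(0.05, 1.2),
            t_rev=rng.uniform(1.5, 3.6),
            tau_l=rng.uniform(0.05, 1.0),
        )


def random_trial_logs(n: int, config: TaskConfig, seed: int) -> list[TrialLog]:
    """n trial logs from sessions of random-interval play."""
    from supergee.task import run_session

    logs: list[TrialLog] = []
    rng = np.random.default_rng(seed)
    policy = RandomIntervalPolicy()
    while len(logs) < n:
        session = run_session(config, policy, int(rng.integers(2**31 - 1)))
        logs.extend(session.trial_logs)
    return logs[:n]
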