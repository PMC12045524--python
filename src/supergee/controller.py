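"""Synthetic participants: stochastic open-loop key-press policies.

A participant's behavior is modeled as a planned bang-coast-bang: leave the
start planet at ``t_go`` by holding the right key for ``tau_right`` seconds,
then brake with the left key starting at ``t_rev`` for ``rho * tau_right``
seconds.  Gaussian timing jitter (``timing_sd``) perturbs all four realized
times independently on every attempt, and with probability ``lapse_prob``
an attempt contains no presses at all.  This is the simplest policy family
that spans the four skill metrics independently: ``t_go`` drives response
time, ``t_rev`` the time of reversal, ``rho`` the scaling ratio, and
``timing_sd`` (precision) the time in target.

A ``CovariateLink`` maps participant covariates (standardized age, sex,
APOE e4 carrier status, standardized verbal-learning score and its
interaction with sex) linearly onto these policy parameters, defining the
generative ground truth that the downstream regression models must recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .task import TaskConfig

__all__ = [
    "ControllerParams",
    "CovariateLink",
    "BangCoastBangPolicy",
    "IdealBangBangPolicy",
    "NullPolicy",
    "ConfigurationError",
    "make_policy",
    "link_params",
    "default_link",
    "zero_effect_link",
    "DEFAULT_PARAMS",
]


class ConfigurationError(KeyError):
    """A link references a covariate absent from the participant record."""


@dataclass(frozen=True)
class ControllerParams:
    """Mean plan of one participant; all times in seconds from trial start."""

    t_go_mean: float = 1.62
    tau_right: float = 0.72
    rho: float = 0.75
    t_rev_mean: float = 2.32
    timing_sd: float = 0.10
    lapse_prob: float = 0.02

    def __post_init__(self) -> None:
        if min(self.t_go_mean, self.tau_right, self.rho, self.t_rev_mean) < 0:
            raise ValueError("plan times and durations must be non-negative")
        if self.timing_sd < 0:
            raise ValueError("timing_sd must be non-negative")
        if not 0.0 <= self.lapse_prob <= 1.0:
            raise ValueError("lapse_prob must be a probability")


#: population-average plan: an imperfect but competent player; session means
#: come out near RT ~1.9 s, reversal ~2.3 s, scaling ratio ~0.78 and a few
#: hundred ms of time in target, the order of magnitude seen in real cohorts
DEFAULT_PARAMS = ControllerParams()


@dataclass
class _IntervalPlan:
    """Right key held on [t_go, t_go+tau_r), left on [t_rev, t_rev+tau_l)."""

    t_go: float
    tau_r: float
    t_rev: float
    tau_l: float
    lapse: bool = False

    def keys(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.lapse:
            z = np.zeros(t.shape, dtype=bool)
            return z, z.copy()
        kR = (t >= self.t_go) & (t < self.t_go + self.tau_r)
        kL = (t >= self.t_rev) & (t < self.t_rev + self.tau_l)
        return kL, kR


class BangCoastBangPolicy:
    """Open-loop planned policy with per-attempt i.i.d. Gaussian jitter."""

    def __init__(self, params: ControllerParams):
        self.params = params

    def plan_trial(self, trial_index: int, rng: np.random.Generator) -> _IntervalPlan:
        p = self.params
        if p.lapse_prob > 0 and rng.random() < p.lapse_prob:
            return _IntervalPlan(0.0, 0.0, 0.0, 0.0, lapse=True)
        eps = rng.normal(0.0, p.timing_sd, size=4) if p.timing_sd > 0 else np.zeros(4)
        t_go = max(p.t_go_mean + eps[0], 0.0)
        tau_r = max(p.tau_right + eps[1], 0.0)
        t_rev = max(p.t_rev_mean + eps[2], 0.0)
        tau_l = max(p.rho * p.tau_right + eps[3], 0.0)
        return _IntervalPlan(t_go, tau_r, t_rev, tau_l)


class IdealBangBangPolicy:
    """Deterministic time-optimal plan: exit at the go cue, accelerate for
    tau = sqrt(planet_distance / force_accel), then brake for tau, arriving
    at the target center at rest."""

    def __init__(self, config: TaskConfig):
        tau = math.sqrt(config.planet_distance / config.force_accel)
        self._plan = _IntervalPlan(
            t_go=config.hold_duration,
            tau_r=tau,
            t_rev=config.hold_duration + tau,
            tau_l=tau,
        )

    def plan_trial(self, trial_index: int, rng: np.random.Generator) -> _IntervalPlan:
        return self._plan


class NullPolicy:
    """Never presses a key."""

    def plan_trial(self, trial_index: int, rng: np.random.Generator) -> _IntervalPlan:
        return _IntervalPlan(0.0, 0.0, 0.0, 0.0, lapse=True)


def make_policy(params: ControllerParams, rng_seed: int | None = None) -> BangCoastBangPolicy:
    """Build the stochastic policy for one participant.

    Randomness is supplied by the generator passed to ``plan_trial`` by the
    engine; ``rng_seed`` is accepted for interface symmetry but unused.
    """
    return BangCoastBangPolicy(params)


_PARAM_FIELDS = ("t_go_mean", "tau_right", "rho", "t_rev_mean", "timing_sd", "lapse_prob")

#: hard validity bounds applied after the linear link
_CLAMP = {
    "t_go_mean": (0.0, 4.0),
    "tau_right": (0.05, 2.0),
    "rho": (0.0, 3.0),
    "t_rev_mean": (0.0, 4.4),
    "timing_sd": (0.01, 1.0),
    "lapse_prob": (0.0, 0.5),
}


@dataclass(frozen=True)
class CovariateLink:
    """Linear map from standardized covariates to policy parameters.

    ``coefs[param][covariate]`` adds ``coef * covariate`` to that
    parameter's intercept; ``between_sd[param]`` adds participant-level
    Gaussian noise.  Recognized covariates are whatever keys the caller
    supplies; the defaults use ``age_z``, ``male``, ``carrier``, ``pal_z``
    and ``pal_z_x_male``.
    """

    intercepts: Mapping[str, float]
    coefs: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    between_sd: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in list(self.intercepts) + list(self.coefs) + list(self.between_sd):
            if name not in _PARAM_FIELDS:
                raise ValueError(f"unknown controller parameter {name!r}")


def link_params(
    covariates: Mapping[str, float],
    link: CovariateLink,
    rng: np.random.Generator | int,
) -> tuple[ControllerParams, bool]:
    """Realize one participant's policy parameters from their covariates.

    Returns the parameters and a flag indicating whether any value had to
    be clamped into its validity range (clamping should be rare under a
    sane link; callers log and count it).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    values = {}
    clamped = False
    for name in _PARAM_FIELDS:
        val = float(link.intercepts.get(name, getattr(DEFAULT_PARAMS, name)))
        for cov_name, coef in link.coefs.get(name, {}).items():
            if cov_name not in covariates:
                raise ConfigurationError(
                    f"link requires covariate {cov_name!r} which is missing"
                )
            val += coef * float(covariates[cov_name])
        sd = link.between_sd.get(name, 0.0)
        if sd > 0:
            val += rng.normal(0.0, sd)
        lo, hi = _CLAMP[name]
        bounded = min(max(val, lo), hi)
        if bounded != val:
            clamped = True
        values[name] = bounded
    return ControllerParams(**values), clamped


def default_link() -> CovariateLink:
    """The study-condition generative link.

    Signs mirror the associations the analysis is meant to detect: age
    degrades precision (lower time in target), male improves it, carriers
    leave the start planet earlier (faster response time), and
    verbal-learning score couples to precision in males only.  Magnitudes
    are set so the standardized effects on session means are roughly
    0.5-1.0 SD, detectable by sign at a few hundred participants.
    """
    return CovariateLink(
        intercepts={
            "t_go_mean": 1.62,
            "tau_right": 0.72,
            "rho": 0.75,
            "t_rev_mean": 2.32,
            "timing_sd": 0.12,
            "lapse_prob": 0.02,
        },
        coefs={
            "timing_sd": {"age_z": 0.02, "male": -0.03, "pal_z_x_male": -0.02},
            "t_go_mean": {"carrier": -0.05},
        },
        between_sd={
            "t_go_mean": 0.05,
            "tau_right": 0.02,
            "t_rev_mean": 0.04,
            "timing_sd": 0.02,
        },
    )


def zero_effect_link() -> CovariateLink:
    """Same intercepts and between-participant noise, no covariate effects;
    the null world for type-I-error calibration."""
    base = default_link()
    return replace(base, coefs={})
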