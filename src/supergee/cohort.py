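"""Synthetic cohort generation and end-to-end study simulation.

Cohorts emulate the marginal structure of a web-based aging cohort enriched
for Alzheimer-risk covariates: age truncated-normal above 45 (mean 62.4,
SD 7.4), ~72% female, APOE genotype frequencies matching the observed
2/3 : 3/3 : 2/4 : 3/4 : 4/4 = 2 : 29 : 4 : 16 : 3 split, four education
levels, a paired-associates-learning (PAL) score on 0-36 with age and sex
effects, log-normal simple visual reaction time (right-skewed, median
~400 ms), an afternoon-centered hour of play on the 24 h clock, and a
~5.9-year delay between the PAL measurement and gameplay.

Two sampling modes are provided: ``iid`` draws categorical covariates
independently per row; ``exact`` reproduces the target integer marginals
(largest-remainder apportionment, shuffled assignment), which at n=54
yields exactly 23 carriers / 31 noncarriers and 39 female / 15 male.

`simulate_study` plays every participant through the task engine with
policy parameters derived from their covariates and returns the analysis
table (session-mean metrics joined to covariates) that all downstream
models consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .controller import BangCoastBangPolicy, CovariateLink, link_params
from .metrics import session_metrics_from_arrays, summarize_session
from .task import TaskConfig, run_session_arrays

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "simulate_study",
    "GENOTYPES",
    "EDUCATION_LEVELS",
    "ANALYSIS_COLUMNS",
]

GENOTYPES = ["2/2", "2/3", "3/3", "2/4", "3/4", "4/4"]
EDUCATION_LEVELS = [
    "high school diploma",
    "some college",
    "four-year degree",
    "postgraduate degree",
]

ANALYSIS_COLUMNS = [
    "participant_id",
    "age",
    "sex",
    "apoe_genotype",
    "education",
    "pal_raw",
    "svrt_median_ms",
    "hour_played",
    "years_since_pal",
    "mean_tint",
    "mean_rt",
    "mean_rt_go",
    "mean_tr",
    "mean_sr",
    "n_success",
]


@dataclass(frozen=True)
class CohortConfig:
    """Marginal distributions of the synthetic cohort (defaults: study sample)."""

    n: int = 54
    age_mean: float = 62.39
    age_sd: float = 7.4
    age_min: float = 45.0
    female_fraction: float = 39 / 54
    genotype_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "2/2": 0 / 54,
            "2/3": 2 / 54,
            "3/3": 29 / 54,
            "2/4": 4 / 54,
            "3/4": 16 / 54,
            "4/4": 3 / 54,
        }
    )
    education_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "high school diploma": 1 / 54,
            "some college": 9 / 54,
            "four-year degree": 21 / 54,
            "postgraduate degree": 23 / 54,
        }
    )
    # PAL score = intercept + age_coef*age_z + male_coef*male + N(0, sd), clipped to [0, 36]
    pal_intercept: float = 21.0
    pal_age_coef: float = -2.5
    pal_male_coef: float = -4.0
    pal_noise_sd: float = 7.0
    pal_max: float = 36.0
    # svRT median, log-normal: exp(N(log_median, log_sd)) in ms
    svrt_log_median: float = np.log(400.0)
    svrt_log_sd: float = 0.19
    # hour of play, truncated normal on the 24 h clock
    hour_mean: float = 14.2
    hour_sd: float = 4.3
    # years between PAL measurement and gameplay
    delay_mean: float = 5.9
    delay_sd: float = 1.4
    sampling: str = "iid"  # "iid" or "exact"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        if self.sampling not in ("iid", "exact"):
            raise ValueError("sampling must be 'iid' or 'exact'")
        for name, probs in (
            ("genotype_probs", self.genotype_probs),
            ("education_probs", self.education_probs),
        ):
            p = np.array(list(probs.values()), dtype=float)
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be in [0, 1]")


def _exact_counts(probs: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n among categories."""
    raw = probs * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    short = n - counts.sum()
    order = np.argsort(-remainder)
    counts[order[:short]] += 1
    return counts


def _draw_categorical(
    levels: list[str], probs: np.ndarray, n: int, mode: str, rng: np.random.Generator
) -> np.ndarray:
    if mode == "exact":
        counts = _exact_counts(probs, n)
        values = np.repeat(np.array(levels, dtype=object), counts)
        rng.shuffle(values)
        return values
    return rng.choice(np.array(levels, dtype=object), size=n, p=probs)


def generate_cohort(config: CohortConfig, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Draw a cohort table of participant covariates.

    Deterministic for a given (config, seed).  Rows satisfy the covariate
    invariants by construction: age >= age_min, PAL in [0, 36], positive
    svRT, hour on the 24 h clock, non-negative delay.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = config.n

    a = (config.age_min - config.age_mean) / config.age_sd
    age = sps.truncnorm.rvs(
        a, np.inf, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )

    sex = _draw_categorical(
        ["female", "male"],
        np.array([config.female_fraction, 1.0 - config.female_fraction]),
        n,
        config.sampling,
        rng,
    )
    male = (sex == "male").astype(float)

    genotype = _draw_categorical(
        list(config.genotype_probs),
        np.array(list(config.genotype_probs.values()), dtype=float),
        n,
        config.sampling,
        rng,
    )
    education = _draw_categorical(
        list(config.education_probs),
        np.array(list(config.education_probs.values()), dtype=float),
        n,
        config.sampling,
        rng,
    )

    age_z = (age - age.mean()) / age.std(ddof=1) if n > 1 else np.zeros(n)
    pal_latent = (
        config.pal_intercept
        + config.pal_age_coef * age_z
        + config.pal_male_coef * male
        + rng.normal(0.0, config.pal_noise_sd, size=n)
    )
    pal = np.clip(np.round(pal_latent), 0, config.pal_max)

    svrt = np.exp(rng.normal(config.svrt_log_median, config.svrt_log_sd, size=n))

    # bounds chosen so rounding keeps hours on the 24 h clock
    lo = (-0.49 - config.hour_mean) / config.hour_sd
    hi = (23.49 - config.hour_mean) / config.hour_sd
    hour = np.round(
        sps.truncnorm.rvs(
            lo, hi, loc=config.hour_mean, scale=config.hour_sd, size=n, random_state=rng
        )
    ).astype(int)

    delay = np.maximum(rng.normal(config.delay_mean, config.delay_sd, size=n), 0.0)

    return pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "age": age,
            "sex": sex,
            "apoe_genotype": genotype,
            "education": education,
            "pal_raw": pal,
            "svrt_median_ms": svrt,
            "hour_played": hour,
            "years_since_pal": delay,
        }
    )


def _standardize_vector(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_study(
    cohort: pd.DataFrame,
    link: CovariateLink,
    task: TaskConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Play each cohort member through a full session and build the
    analysis table (one row per participant: covariates + session means).

    Linking covariates are standardized within the cohort (age, PAL) or
    coded 0/1 (male, carrier) before entering the policy link, matching
    the preprocessing convention of the analysis stage.  Fully reproducible
    from (cohort, link, task config, seed); engine errors are re-raised
    with the participant id attached.
    """
    from .preprocess import carrier_status  # local import to avoid a cycle

    task = task or TaskConfig()
    n = len(cohort)
    if n == 0:
        raise ValueError("empty cohort")
    age_z = _standardize_vector(cohort["age"].to_numpy(dtype=float))
    pal_z = _standardize_vector(cohort["pal_raw"].to_numpy(dtype=float))
    male = (cohort["sex"].to_numpy() == "male").astype(float)
    carrier = np.array(
        [carrier_status(g) for g in cohort["apoe_genotype"]], dtype=float
    )

    seeds = np.random.SeedSequence(seed).spawn(n)
    rows = []
    n_clamped = 0
    for i in range(n):
        cov = {
            "age_z": age_z[i],
            "male": male[i],
            "carrier": carrier[i],
            "pal_z": pal_z[i],
            "pal_z_x_male": pal_z[i] * male[i],
        }
        rng = np.random.default_rng(seeds[i])
        try:
            params, clamped = link_params(cov, link, rng)
            n_clamped += clamped
            sa = run_session_arrays(task, BangCoastBangPolicy(params), rng)
            summary = summarize_session(session_metrics_from_arrays(sa))
        except Exception as exc:  # pragma: no cover - defensive context
            raise RuntimeError(
                f"simulation failed for participant {cohort['participant_id'].iloc[i]}"
            ) from exc
        rows.append(
            {
                "mean_tint": summary.mean_tint,
                "mean_rt": np.nan if summary.mean_rt is None else summary.mean_rt,
                "mean_rt_go": np.nan if summary.mean_rt_go is None else summary.mean_rt_go,
                "mean_tr": np.nan if summary.mean_tr is None else summary.mean_tr,
                "mean_sr": np.nan if summary.mean_sr is None else summary.mean_sr,
                "n_success": summary.n_success,
            }
        )
    result = pd.concat([cohort.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
    result.attrs["n_clamped"] = n_clamped
    return result[ANALYSIS_COLUMNS]
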