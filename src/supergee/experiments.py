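"""Simulation experiments that validate the pipeline end to end.

Because the study's raw participant data are not public, the fitted
coefficients themselves cannot be reproduced; what can be checked is that
the full pipeline (cohort generation -> gameplay simulation -> metric
extraction -> preprocessing -> model battery) *recovers the generative
truth*:

* sign recovery — under the default covariate link, each model's focal
  effect (carrier->RT, male->TinT, age->TinT, male:TinT->PAL) is estimated
  with the correct sign in a large fraction of replicates;
* type-I calibration — under a zero-effect link, each focal term rejects
  at the nominal 5% rate.

These functions are shared by the acceptance tests and the acceptance
script.  Experiments use Wald p-values (the rejection decision); profile
CIs are reserved for one-off model reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortConfig, generate_cohort, simulate_study
from .controller import CovariateLink, default_link, zero_effect_link
from .preprocess import standardize_analysis_table
from .stats import cohens_d, fit_model, model_spec
from .task import TaskConfig

__all__ = [
    "FOCAL_EFFECTS",
    "FocalEffect",
    "sign_recovery",
    "type1_calibration",
    "tint_sex_effect_size",
]


@dataclass(frozen=True)
class FocalEffect:
    """One generative effect and where the battery should see it."""

    label: str
    model_id: int
    performance: str  # performance predictor entering the model
    term: str  # design-matrix term whose coefficient carries the effect
    expected_sign: int


#: the four nonzero effects of the default link, as seen by models 1-4
FOCAL_EFFECTS = (
    FocalEffect("carrier_faster_rt", 1, "rt_z", "rt_z", -1),
    FocalEffect("male_higher_tint", 2, "tint_z", "tint_z", +1),
    FocalEffect("age_lower_tint", 3, "tint_z", "tint_z", -1),
    FocalEffect("pal_male_tint_interaction", 4, "tint_z", "tint_z:male", +1),
)


def _replicate_table(n: int, link: CovariateLink, task: TaskConfig, rng: np.random.Generator):
    """One replicate: fresh cohort, simulated gameplay, model-ready table."""
    cohort_seed, study_seed = rng.integers(0, 2**31 - 1, size=2)
    cohort = generate_cohort(CohortConfig(n=n), int(cohort_seed))
    analysis = simulate_study(cohort, link, task, seed=int(study_seed))
    return standardize_analysis_table(analysis)


def sign_recovery(
    n: int = 500,
    n_reps: int = 100,
    seed: int = 0,
    link: CovariateLink | None = None,
    task: TaskConfig | None = None,
) -> dict[str, float]:
    """Fraction of replicates in which each focal effect has the correct
    estimated sign.  Returns {effect label: recovery rate}."""
    link = link or default_link()
    task = task or TaskConfig()
    rng = np.random.default_rng(seed)
    hits = {fe.label: 0 for fe in FOCAL_EFFECTS}
    for _ in range(n_reps):
        table = _replicate_table(n, link, task, rng)
        for fe in FOCAL_EFFECTS:
            res = fit_model(model_spec(fe.model_id, fe.performance), table, ci_method="wald")
            coef = float(res.params.loc[fe.term, "coef"])
            hits[fe.label] += int(np.sign(coef) == fe.expected_sign)
    return {label: count / n_reps for label, count in hits.items()}


def type1_calibration(
    n: int = 200,
    n_reps: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    task: TaskConfig | None = None,
) -> dict[str, float]:
    """Per-focal-term rejection rate at ``alpha`` under the zero-effect
    link.  Well-calibrated inference keeps every rate near ``alpha``."""
    link = zero_effect_link()
    task = task or TaskConfig()
    rng = np.random.default_rng(seed)
    rejections = {fe.label: 0 for fe in FOCAL_EFFECTS}
    for _ in range(n_reps):
        table = _replicate_table(n, link, task, rng)
        for fe in FOCAL_EFFECTS:
            res = fit_model(model_spec(fe.model_id, fe.performance), table, ci_method="wald")
            rejections[fe.label] += int(float(res.params.loc[fe.term, "p"]) < alpha)
    return {label: count / n_reps for label, count in rejections.items()}


def tint_sex_effect_size(
    n: int = 500,
    seed: int = 0,
    link: CovariateLink | None = None,
    task: TaskConfig | None = None,
) -> float:
    """Cohen's d of session-mean time in target, male vs female, on one
    simulated cohort under the given link."""
    link = link or default_link()
    task = task or TaskConfig()
    rng = np.random.default_rng(seed)
    table = _replicate_table(n, link, task, rng).frame
    males = table.loc[table["male"], "mean_tint"]
    females = table.loc[~table["male"], "mean_tint"]
    return cohens_d(males, females)
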