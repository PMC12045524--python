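"""Inferential battery: rank-sum and chi-square tests, effect sizes,
collinearity and influence screens, and the five regression models.

The model battery mirrors a risk-factor analysis in which each Alzheimer
risk factor is in turn the outcome, the motor-skill metric the focal
predictor, and the remaining factors controls:

1. carrier ~ performance + age + sex + hour + education + svRT + PAL  (logistic)
2. male    ~ performance + age + hour + education + svRT + PAL + carrier  (logistic)
3. age     ~ performance + sex + hour + education + svRT + PAL + carrier  (linear)
4. PAL     ~ performance + performance:male + age + sex + hour + education + svRT + carrier  (linear)
5. PAL(delay-adjusted), same right-hand side as model 4  (linear)

All numeric variables enter standardized, education as treatment-coded
dummies with "high school diploma" as reference.  Before fitting,
predictors with variance inflation factor > 5 are removed iteratively;
after an initial fit, observations with Cook's distance > 1 are removed
and the model refitted once.  Logistic odds-ratio CIs use profile
likelihood by default (Wald available by flag); linear CIs are t-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy import stats as sps

from .cohort import EDUCATION_LEVELS
from .preprocess import StandardizedTable

__all__ = [
    "ModelSpec",
    "FitResult",
    "VifReport",
    "UndefinedStatisticError",
    "wilcoxon_rank_sum",
    "chi_square_2x2",
    "cohens_d",
    "vif_filter",
    "cooks_distances",
    "cooks_filter",
    "fit_model",
    "fit_all_models",
    "model_spec",
    "or_to_percent_change",
    "MODEL_NAMES",
    "PERFORMANCE_PREDICTORS",
]

MODEL_NAMES = {
    1: "carrier_logistic",
    2: "sex_logistic",
    3: "age_linear",
    4: "pal_linear",
    5: "pal_adjusted_linear",
}

PERFORMANCE_PREDICTORS = ("tint_z", "rt_z", "sr_z", "tr_z")

_EDU_DUMMIES = [f"edu[{lvl}]" for lvl in EDUCATION_LEVELS[1:]]  # HS diploma = reference

_CHI2_95_DF1 = float(sps.chi2.ppf(0.95, 1))


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined for the given data."""


# ---------------------------------------------------------------------------
# simple tests and effect sizes


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank sum of the first sample minus its
    minimum (the Mann-Whitney U of the first sample).  The p-value is by
    exact enumeration when n1 + n2 <= 20 and the data are untied, else by
    the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0.0:
        warnings.warn("all observations are tied; rank-sum p-value set to 1")
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(table: np.ndarray, yates: bool = True) -> tuple[float, int, float]:
    """Pearson chi-square test on a 2x2 table, optional Yates correction.

    With Yates, each |O - E| is reduced by 0.5 (floored at 0) before
    squaring.  Returns (chi2, df, p).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise UndefinedStatisticError("chi-square undefined with a zero margin")
    chi2, p, dof, _ = sps.chi2_contingency(t, correction=yates)
    return float(chi2), int(dof), float(p)


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Cohen's d with the pooled-SD (n1 + n2 - 2) denominator."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    pooled_var = (
        (x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)
    ) / (x.size + y.size - 2)
    if pooled_var == 0:
        raise UndefinedStatisticError("zero pooled SD")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def or_to_percent_change(or_value: float) -> float:
    """Express an odds ratio as a percent change in odds per +1 SD.

    An OR below 1 is reported as the percent reduction (equivalently, the
    percent increase in odds of the complementary outcome); an OR above 1
    as the percent increase.
    """
    if or_value <= 0:
        raise ValueError("odds ratio must be positive")
    if or_value < 1.0:
        return 100.0 * (1.0 - or_value)
    return 100.0 * (or_value - 1.0)


# ---------------------------------------------------------------------------
# diagnostics


@dataclass
class VifReport:
    retained: list[str]
    removed: list[str]
    vifs: dict[str, float]


def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF of column j: 1 / (1 - R^2) from regressing it on the others."""
    yj = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(yj)), others])
    sst = np.sum((yj - yj.mean()) ** 2)
    if sst == 0:
        return np.inf
    beta, *_ = np.linalg.lstsq(A, yj, rcond=None)
    ssr = np.sum((yj - A @ beta) ** 2)
    r2 = 1.0 - ssr / sst
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def vif_filter(
    table: pd.DataFrame | StandardizedTable,
    predictors: Sequence[str],
    threshold: float = 5.0,
) -> VifReport:
    """Iteratively drop the highest-VIF predictor while any exceeds the
    threshold.  Perfectly collinear (or constant) columns have infinite
    VIF and are removed first; with one predictor left, filtering stops.
    """
    df = table.frame if isinstance(table, StandardizedTable) else table
    retained = list(predictors)
    if len(retained) < 2:
        return VifReport(retained, [], {p: 1.0 for p in retained})
    removed: list[str] = []
    while len(retained) >= 2:
        X = df[retained].to_numpy(dtype=float)
        vifs = {p: _vif_one(X, j) for j, p in enumerate(retained)}
        worst = max(vifs, key=lambda p: vifs[p])
        if vifs[worst] > threshold:
            retained.remove(worst)
            removed.append(worst)
        else:
            break
    final_vifs = (
        {p: _vif_one(df[retained].to_numpy(dtype=float), j) for j, p in enumerate(retained)}
        if len(retained) >= 2
        else {p: 1.0 for p in retained}
    )
    return VifReport(retained, removed, final_vifs)


def cooks_distances(fit) -> np.ndarray:
    """Cook's distance per observation of a fitted statsmodels model.

    Exact for OLS; the standard one-step approximation for GLM fits.
    Saturated observations (leverage 1) get infinite distance.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        d = fit.get_influence().cooks_distance[0]
    return np.where(np.isfinite(d), d, np.inf)


def cooks_filter(fit, threshold: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Indices of observations to keep (Cook's D <= threshold) and the
    distances themselves, aligned with the fit's observation order."""
    d = cooks_distances(fit)
    return np.flatnonzero(d <= threshold), d


# ---------------------------------------------------------------------------
# model battery


@dataclass(frozen=True)
class ModelSpec:
    model_id: int
    name: str
    kind: str  # "logistic" | "linear"
    outcome: str
    predictors: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()

    @property
    def terms(self) -> list[str]:
        return list(self.predictors) + [f"{a}:{b}" for a, b in self.interactions]


def model_spec(model_id: int, performance: str = "tint_z") -> ModelSpec:
    """Build one of the five pre-specified models around a performance
    predictor (``tint_z``, ``rt_z``, ``sr_z`` or ``tr_z``)."""
    if performance not in PERFORMANCE_PREDICTORS:
        raise ValueError(f"performance must be one of {PERFORMANCE_PREDICTORS}")
    edu = tuple(_EDU_DUMMIES)
    if model_id == 1:
        return ModelSpec(1, MODEL_NAMES[1], "logistic", "carrier",
                         (performance, "age_z", "male", "hour_cos_z", *edu, "svrt_z", "pal_z"))
    if model_id == 2:
        return ModelSpec(2, MODEL_NAMES[2], "logistic", "male",
                         (performance, "age_z", "hour_cos_z", *edu, "svrt_z", "pal_z", "carrier"))
    if model_id == 3:
        return ModelSpec(3, MODEL_NAMES[3], "linear", "age_z",
                         (performance, "male", "hour_cos_z", *edu, "svrt_z", "pal_z", "carrier"))
    if model_id == 4:
        return ModelSpec(4, MODEL_NAMES[4], "linear", "pal_z",
                         (performance, "age_z", "male", "hour_cos_z", *edu, "svrt_z", "carrier"),
                         ((performance, "male"),))
    if model_id == 5:
        return ModelSpec(5, MODEL_NAMES[5], "linear", "pal_adj_z",
                         (performance, "age_z", "male", "hour_cos_z", *edu, "svrt_z", "carrier"),
                         ((performance, "male"),))
    raise ValueError(f"unknown model id {model_id}")


@dataclass
class FitResult:
    """Per-term estimates plus the diagnostics that shaped the fit."""

    spec: ModelSpec
    params: pd.DataFrame  # coef, se, ci_low, ci_high, p (+ or_, or_low, or_high)
    n_used: int
    removed_rows: list[int]
    removed_predictors: list[str]
    vifs: dict[str, float]
    cooks: Optional[np.ndarray]
    converged: bool
    notes: list[str] = field(default_factory=list)

    @property
    def odds_ratios(self) -> Optional[pd.Series]:
        return self.params["or"] if "or" in self.params.columns else None


def _build_design(df: pd.DataFrame, spec: ModelSpec) -> tuple[pd.Series, pd.DataFrame]:
    """Outcome vector and design-matrix columns (no constant yet)."""
    needed = {spec.outcome} | {p for p in spec.predictors if not p.startswith("edu[")}
    needed |= {a for a, _ in spec.interactions} | {b for _, b in spec.interactions}
    if "education" not in df.columns:
        raise KeyError("table must carry an 'education' column")
    missing = needed - set(df.columns)
    if missing:
        raise KeyError(f"table is missing model variables: {sorted(missing)}")

    work = df.dropna(subset=sorted(needed - set(_EDU_DUMMIES))).copy()
    X = pd.DataFrame(index=work.index)
    for p in spec.predictors:
        if p.startswith("edu["):
            level = p[4:-1]
            X[p] = work["education"].astype(str).eq(level).astype(float)
        else:
            X[p] = work[p].astype(float)
    for a, b in spec.interactions:
        X[f"{a}:{b}"] = work[a].astype(float) * work[b].astype(float)
    y = work[spec.outcome].astype(float)
    return y, X


def _profile_ci_logistic(
    model: sm.GLM, fit, term: str, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Profile-likelihood CI for one coefficient of a binomial GLM.

    Inverts the likelihood-ratio statistic with a bracketed root search in
    each direction; if the profile never crosses the critical level inside
    a wide bracket (flat likelihood under quasi-separation) that side falls
    back to the Wald bound and the fallback is flagged.
    """
    b = float(fit.params[term])
    se = float(fit.bse[term])
    if not np.isfinite(se) or se == 0:
        return np.nan, np.nan, True
    crit = _CHI2_95_DF1

    def lr_minus_crit(v: float) -> float:
        constrained = model.fit_constrained(f"{term}={v}")
        return 2.0 * (fit.llf - constrained.llf) - crit

    def side(direction: float) -> tuple[float, bool]:
        lo_k, hi_k = 0.0, 2.0
        for _ in range(8):  # expand the bracket up to ~256 SE
            v = b + direction * hi_k * se
            try:
                g = lr_minus_crit(v)
            except Exception:
                return b + direction * 1.96 * se, True
            if g > 0:
                a_, b_ = b + direction * lo_k * se, v
                lo_v, hi_v = min(a_, b_), max(a_, b_)
                root = optimize.brentq(lr_minus_crit, lo_v, hi_v, xtol=1e-6 * max(se, 1e-3))
                return float(root), False
            lo_k, hi_k = hi_k, hi_k * 2.0
        return b + direction * 1.96 * se, True

    lower, fb_lo = side(-1.0)
    upper, fb_hi = side(+1.0)
    return lower, upper, (fb_lo or fb_hi)


def fit_model(
    spec: ModelSpec,
    table: StandardizedTable | pd.DataFrame,
    vif_threshold: float = 5.0,
    cooks_threshold: float = 1.0,
    ci_method: str = "profile",
) -> FitResult:
    """Fit one model with the full screening pipeline.

    Order of operations: drop zero-variance design columns, VIF screen,
    initial fit, Cook's-distance screen, one refit.  ``ci_method`` selects
    profile-likelihood ("profile", default) or Wald ("wald") intervals for
    logistic coefficients; linear models always use t-intervals.
    """
    if ci_method not in ("profile", "wald"):
        raise ValueError("ci_method must be 'profile' or 'wald'")
    df = table.frame if isinstance(table, StandardizedTable) else table
    y, X = _build_design(df, spec)
    notes: list[str] = []

    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        notes.append(f"dropped zero-variance columns: {constant}")
        X = X.drop(columns=constant)

    vif = vif_filter(X, list(X.columns), threshold=vif_threshold)
    if vif.removed:
        notes.append(f"VIF>{vif_threshold} removed: {vif.removed}")
        X = X[vif.retained]

    def _fit(yv: pd.Series, Xv: pd.DataFrame):
        exog = sm.add_constant(Xv, has_constant="add")
        if spec.kind == "logistic":
            model = sm.GLM(yv, exog, family=sm.families.Binomial())
            return model, model.fit(maxiter=200)
        model = sm.OLS(yv, exog)
        return model, model.fit()

    model, fit = _fit(y, X)
    keep, dists = cooks_filter(fit, cooks_threshold)
    removed_rows = [int(i) for i in np.setdiff1d(np.arange(len(y)), keep)]
    if removed_rows:
        notes.append(f"Cook's D>{cooks_threshold} removed {len(removed_rows)} rows")
        y2, X2 = y.iloc[keep], X.iloc[keep]
        model, fit = _fit(y2, X2)
    n_used = int(fit.nobs)

    converged = bool(getattr(fit, "converged", True))
    if spec.kind == "logistic" and (np.abs(fit.params).max() > 15 or fit.bse.max() > 50):
        notes.append("quasi-separation suspected; penalized refit advisable")
        converged = converged and False

    terms = list(fit.params.index)
    coefs = fit.params
    ses = fit.bse
    pvals = fit.pvalues
    if spec.kind == "logistic" and ci_method == "profile" and converged:
        ci_lo, ci_hi = {}, {}
        any_fallback = False
        for t in terms:
            lo, hi, fb = _profile_ci_logistic(model, fit, t)
            ci_lo[t], ci_hi[t] = lo, hi
            any_fallback |= fb
        if any_fallback:
            notes.append("profile CI fell back to Wald on at least one side")
        ci = pd.DataFrame({"lo": ci_lo, "hi": ci_hi})
    else:
        w = fit.conf_int(alpha=0.05)
        ci = pd.DataFrame({"lo": w[0], "hi": w[1]})

    params = pd.DataFrame(
        {
            "coef": coefs,
            "se": ses,
            "ci_low": ci["lo"],
            "ci_high": ci["hi"],
            "p": pvals,
        }
    )
    if spec.kind == "logistic":
        params["or"] = np.exp(params["coef"])
        params["or_low"] = np.exp(params["ci_low"])
        params["or_high"] = np.exp(params["ci_high"])

    return FitResult(
        spec=spec,
        params=params,
        n_used=n_used,
        removed_rows=removed_rows,
        removed_predictors=vif.removed + constant,
        vifs=vif.vifs,
        cooks=dists,
        converged=converged,
        notes=notes,
    )


def fit_all_models(
    table: StandardizedTable | pd.DataFrame,
    performance: str = "tint_z",
    models: Sequence[int] = (1, 2, 3, 4, 5),
    ci_method: str = "profile",
) -> dict[int, FitResult]:
    """Fit the requested subset of the five-model battery."""
    return {
        m: fit_model(model_spec(m, performance), table, ci_method=ci_method)
        for m in models
    }
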