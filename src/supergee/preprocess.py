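"""Variable constructions used by the analysis models.

Implements APOE e4 carrier coding, the cosine transform of hour-of-day
(so hours 0 and 23 end up adjacent), projection of a historical
verbal-learning (PAL) score to the gameplay date at an expected decline of
0.2 points per year, column z-standardization (n-1 SD convention, with
stored parameters for exact inversion), and covariate-adjusted empirical
percentiles against a reference cohort stratified by age decade, sex and
education.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ANALYSIS_COLUMNS

__all__ = [
    "carrier_status",
    "cosine_hour",
    "adjust_pal",
    "standardize",
    "standardize_analysis_table",
    "percentile_vs_reference",
    "StandardizedTable",
    "GenotypeParseError",
    "DegenerateColumnError",
    "PAL_DECLINE_PER_YEAR",
    "PAL_WORD_PAIRS",
    "PAL_RECALL_TRIALS",
    "PAL_MAX_SCORE",
]

logger = logging.getLogger(__name__)

#: expected decline of the PAL score per year elapsed since it was measured
PAL_DECLINE_PER_YEAR = 0.2

#: PAL scoring: 12 word pairs recalled over 3 trials, one point per recall
PAL_WORD_PAIRS = 12
PAL_RECALL_TRIALS = 3
PAL_MAX_SCORE = PAL_WORD_PAIRS * PAL_RECALL_TRIALS

_GENOTYPE_RE = re.compile(r"^([234])/([234])$")


class GenotypeParseError(ValueError):
    """APOE genotype string is not of the form 'a/b' with alleles 2, 3 or 4."""


class DegenerateColumnError(ValueError):
    """A column slated for standardization has zero standard deviation."""


def carrier_status(apoe_genotype: str) -> bool:
    """True iff the genotype contains at least one e4 allele."""
    m = _GENOTYPE_RE.match(str(apoe_genotype).strip())
    if m is None:
        raise GenotypeParseError(f"malformed APOE genotype: {apoe_genotype!r}")
    return "4" in m.groups()


def cosine_hour(hour: float) -> float:
    """cos(2*pi*hour/24): maps the 24 h clock onto a circle so midnight-
    adjacent hours are numerically close (hour 0 -> 1, hour 12 -> -1)."""
    if not 0 <= hour < 24:
        raise ValueError(f"hour must be in [0, 24), got {hour}")
    return float(np.cos(2.0 * np.pi * hour / 24.0))


def adjust_pal(pal_raw: float, years_since_pal: float) -> float:
    """Project a historical PAL score to the gameplay date.

    Subtracts the expected 0.2-point-per-year decline, so the adjusted
    score estimates what the participant would score today.  Identity at
    zero delay; linear in the delay.
    """
    if years_since_pal < 0:
        raise ValueError("years_since_pal must be non-negative")
    return pal_raw - PAL_DECLINE_PER_YEAR * years_since_pal


@dataclass
class StandardizedTable:
    """A table with z-scored numeric columns plus the transform metadata
    needed to invert them exactly."""

    frame: pd.DataFrame
    means: dict[str, float]
    sds: dict[str, float]
    codings: dict[str, str] = field(default_factory=dict)

    def inverse(self, column: str, values: np.ndarray | pd.Series) -> np.ndarray:
        """Map z-scores of ``column`` back to the original scale."""
        return np.asarray(values, dtype=float) * self.sds[column] + self.means[column]


def standardize(table: pd.DataFrame, columns: list[str]) -> StandardizedTable:
    """Center each column at its mean and scale by its SD (ddof=1).

    Raises :class:`DegenerateColumnError` naming the first zero-variance
    column rather than silently producing NaNs.
    """
    frame = table.copy()
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for col in columns:
        x = frame[col].to_numpy(dtype=float)
        mu = float(np.nanmean(x))
        sd = float(np.nanstd(x, ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            raise DegenerateColumnError(f"column {col!r} has zero variance")
        frame[col] = (x - mu) / sd
        means[col], sds[col] = mu, sd
    return StandardizedTable(frame=frame, means=means, sds=sds)


#: analysis-table column -> standardized model column
_Z_MAP = {
    "age": "age_z",
    "svrt_median_ms": "svrt_z",
    "pal_raw": "pal_z",
    "pal_adjusted": "pal_adj_z",
    "hour_cos": "hour_cos_z",
    "mean_tint": "tint_z",
    "mean_rt": "rt_z",
    "mean_sr": "sr_z",
    "mean_tr": "tr_z",
}


def standardize_analysis_table(analysis: pd.DataFrame) -> StandardizedTable:
    """Build the model-ready table from an analysis table.

    Adds ``carrier`` (e4 carrier coded true) and ``male`` (male coded true)
    flags, the cosine hour transform, the delay-adjusted PAL, then
    z-standardizes every numeric model variable (transform-then-standardize
    for the hour).  Standardized columns get ``_z``-suffixed names; the
    original columns are retained on their raw scale.
    """
    df = analysis.copy()
    missing = [c for c in ANALYSIS_COLUMNS if c not in df.columns and c != "mean_rt_go"]
    if missing:
        raise KeyError(f"analysis table is missing columns: {missing}")
    df["carrier"] = [carrier_status(g) for g in df["apoe_genotype"]]
    df["male"] = df["sex"].astype(str).eq("male")
    df["hour_cos"] = [cosine_hour(h) for h in df["hour_played"]]
    df["pal_adjusted"] = [
        adjust_pal(p, y) for p, y in zip(df["pal_raw"], df["years_since_pal"])
    ]
    for raw, z in _Z_MAP.items():
        df[z] = df[raw]
    st = standardize(df, list(_Z_MAP.values()))
    st.codings = {
        "male": "male coded true",
        "carrier": "e4 carrier coded true",
        "pal_adjusted": f"pal_raw - {PAL_DECLINE_PER_YEAR} * years_since_pal",
        "hour": "cosine-transformed then standardized",
    }
    return st


def _age_decade(age: float) -> int:
    return int(age // 10) * 10


def percentile_vs_reference(
    value: float,
    covariates: pd.Series | dict,
    reference: pd.DataFrame,
    variable: str,
) -> float:
    """Empirical percentile of ``value`` within the matching reference
    stratum (age decade x sex x education), midpoint convention for ties.

    Falls back to the sex x education stratum (with a logged warning) when
    no reference rows share the participant's age decade.
    """
    if variable not in reference.columns:
        raise KeyError(f"reference table has no column {variable!r}")
    cov = dict(covariates)
    mask = (reference["sex"] == cov["sex"]) & (
        reference["education"] == cov["education"]
    )
    strat = mask & (reference["age"].map(_age_decade) == _age_decade(cov["age"]))
    ref = reference.loc[strat, variable].to_numpy(dtype=float)
    if ref.size == 0:
        logger.warning(
            "empty age-decade stratum for %s/%s/age %ds; falling back to sex x education",
            cov["sex"], cov["education"], _age_decade(cov["age"]),
        )
        warnings.warn("empty percentile stratum; using sex x education only")
        ref = reference.loc[mask, variable].to_numpy(dtype=float)
        if ref.size == 0:
            raise ValueError("no reference rows match even the fallback stratum")
    less = np.count_nonzero(ref < value)
    equal = np.count_nonzero(ref == value)
    return 100.0 * (less + 0.5 * equal) / ref.size
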