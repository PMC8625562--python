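"""BMI-for-age percentiles via the LMS method.

A growth reference tabulates, for each sex and age, a Box-Cox power ``L``, a
median ``M`` (kg/m^2) and a coefficient of variation ``S``.  A measurement
``X`` is converted to a z-score with

    z = ((X/M)**L - 1) / (L * S)      if L != 0
    z = ln(X/M) / S                   if L == 0

and the percentile is ``100 * Phi(z)``.  Parameters are linearly interpolated
in age between the two bracketing reference rows for the child's sex.
Percentiles are defined only for ages >= 24 months; younger visits are
dropped from percentile output.

Ages are carried in months throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

# below this |L| the Box-Cox form is numerically indistinguishable from the
# log form and switching avoids 0/0
_L_EPS = 1e-6

#: youngest age (months) at which BMI-for-age percentiles are defined
MIN_PERCENTILE_AGE = 24.0

REFERENCE_COLUMNS = ["sex", "age_months", "L", "M", "S"]


@dataclass(frozen=True)
class GrowthSeries:
    """One child's irregular visit sequence: ordered (age_months, bmi) pairs."""

    child_id: str
    sex: str
    ages: np.ndarray
    bmi: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        bmi = np.asarray(self.bmi, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "bmi", bmi)
        if ages.ndim != 1 or ages.shape != bmi.shape:
            raise ValueError("ages and bmi must be matching 1-d arrays")
        if len(ages) and (np.any(ages < 0) or np.any(np.diff(ages) <= 0)):
            raise ValueError(f"ages must be non-negative and strictly increasing ({self.child_id})")
        if np.any(bmi <= 0):
            raise ValueError(f"bmi must be positive ({self.child_id})")

    def __len__(self) -> int:
        return len(self.ages)


def lms_zscore(bmi, L, M, S):
    """LMS z-score of ``bmi`` given Box-Cox power L, median M and CV S.

    Vectorized over all arguments; continuous in L at L -> 0.
    """
    bmi = np.asarray(bmi, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("M and S must be positive")
    if np.any(bmi <= 0):
        raise ValueError("bmi must be positive")
    ratio = bmi / M
    near_zero = np.abs(L) < _L_EPS
    Lsafe = np.where(near_zero, 1.0, L)
    z = np.where(
        near_zero,
        np.log(ratio) / S,
        (np.power(ratio, Lsafe) - 1.0) / (Lsafe * S),
    )
    return z if z.ndim else float(z)


def lms_inverse(z, L, M, S):
    """Measurement at z-score ``z``: the inverse of :func:`lms_zscore`."""
    z = np.asarray(z, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    near_zero = np.abs(L) < _L_EPS
    Lsafe = np.where(near_zero, 1.0, L)
    x = np.where(
        near_zero,
        M * np.exp(S * z),
        M * np.power(1.0 + Lsafe * S * z, 1.0 / Lsafe),
    )
    return x if x.ndim else float(x)


def load_lms_reference(path) -> pd.DataFrame:
    """Read a headered delimited LMS table (columns sex, age_months, L, M, S)."""
    ref = pd.read_csv(path, sep=None, engine="python")
    return validate_reference(ref)


def validate_reference(ref: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REFERENCE_COLUMNS if c not in ref.columns]
    if missing:
        raise ValueError(f"LMS reference missing columns: {missing}")
    ref = ref[REFERENCE_COLUMNS].copy()
    if np.any(ref["M"] <= 0) or np.any(ref["S"] <= 0):
        raise ValueError("reference M and S must be positive")
    for sex, sub in ref.groupby("sex"):
        ages = sub["age_months"].to_numpy(float)
        if np.any(np.diff(ages) <= 0):
            raise ValueError(f"reference ages must be strictly increasing within sex {sex!r}")
        if ages.min() > MIN_PERCENTILE_AGE or ages.max() < 216.0:
            raise ValueError(f"reference for sex {sex!r} must span [24, 216] months")
    return ref


@dataclass
class LMSReference:
    """Interpolating wrapper around an LMS table."""

    table: pd.DataFrame
    clamp: bool = True  # out-of-range ages clamp to the boundary row
    _by_sex: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.table = validate_reference(self.table)
        for sex, sub in self.table.groupby("sex"):
            self._by_sex[sex] = (
                sub["age_months"].to_numpy(float),
                sub["L"].to_numpy(float),
                sub["M"].to_numpy(float),
                sub["S"].to_numpy(float),
            )

    def params(self, sex: str, age_months):
        """Linearly interpolated (L, M, S) at ``age_months`` for ``sex``."""
        if sex not in self._by_sex:
            raise KeyError(f"reference does not cover sex {sex!r}")
        ages, L, M, S = self._by_sex[sex]
        age = np.asarray(age_months, dtype=float)
        if not self.clamp and (np.any(age < ages[0]) or np.any(age > ages[-1])):
            raise ValueError("age outside reference range")
        return (np.interp(age, ages, L), np.interp(age, ages, M), np.interp(age, ages, S))


def bmi_percentile(series: GrowthSeries, ref: LMSReference) -> pd.DataFrame:
    """Per-visit BMI percentile (0-100) for visits at age >= 24 months.

    Returns a frame with columns age_months, bmi, bmipct.  Visits younger
    than 24 months are absent from the output (the reference does not define
    a percentile there).
    """
    keep = series.ages >= MIN_PERCENTILE_AGE
    ages = series.ages[keep]
    bmi = series.bmi[keep]
    if len(ages) == 0:
        return pd.DataFrame(columns=["age_months", "bmi", "bmipct"])
    L, M, S = ref.params(series.sex, ages)
    z = lms_zscore(bmi, L, M, S)
    return pd.DataFrame(
        {"age_months": ages, "bmi": bmi, "bmipct": 100.0 * norm.cdf(z)}
    )


def percentile_to_bmi(pct, sex: str, age_months, ref: LMSReference):
    """BMI at the given percentile for sex/age: inverse of the percentile map."""
    pct = np.asarray(pct, dtype=float)
    if np.any(pct <= 0) or np.any(pct >= 100):
        raise ValueError("percentile must lie strictly between 0 and 100")
    L, M, S = ref.params(sex, age_months)
    return lms_inverse(norm.ppf(pct / 100.0), L, M, S)
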