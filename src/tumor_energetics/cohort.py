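"""Estimating the specific tumor cost K_cost from cohort observations.

Two published routes are implemented.  The REE route regresses
REE/FFM (kcal/kg fat-free mass/day) on tumor burden/FFM (kg/kg) across a
patient cohort: since healthy liver mass tracks FFM, the slope of that
ratio regression is the marginal host expenditure per kg of tumor, i.e.
K_cost in kcal/kg tumor/day.  The oxygen-consumption route converts a
published per-kg-patient oxidative increase (kcal/kg tumor/day/kg patient)
to K_cost by multiplying by an assumed patient mass, conventionally
evaluated at 60 and 70 kg.  Either K_cost divides by the Cori multiplier
(1 + 2 X_anaerobic) to give the tumor's own specific rate K_cancer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import cost_multiplier, round_sigfigs
from .exceptions import DomainError, SingularFitError, UsageError

__all__ = [
    "CohortRecord",
    "RegressionResult",
    "fit_kcost_regression",
    "kcost_from_oxygen_slope",
    "kcost_to_kcancer_range",
    "read_cohort_csv",
    "write_cohort_csv",
]


@dataclass(frozen=True)
class CohortRecord:
    """One patient: fat-free mass, hepatic tumor burden, measured REE."""

    patient_id: str
    ffm: float  # kg
    liver_plus_met_mass: float  # kg, combined liver + liver metastases
    ree: float  # kcal/day, by indirect calorimetry

    def __post_init__(self) -> None:
        if self.ffm <= 0 or self.liver_plus_met_mass <= 0 or self.ree <= 0:
            raise DomainError(
                f"patient {self.patient_id!r}: masses and REE must be > 0"
            )


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of REE/FFM on tumor burden/FFM.

    ``slope`` is interpreted as K_cost (kcal/kg tumor/day); ``intercept``
    is per-kg-FFM baseline expenditure (kcal/kg FFM/day); the p-value is
    the two-sided t-test on the slope with n-2 degrees of freedom.
    """

    slope: float
    intercept: float
    se_slope: float
    r2: float
    p_value: float
    n: int

    def ci_slope(self, level: float = 0.95) -> tuple[float, float]:
        """t-based confidence interval for the slope."""
        from scipy import stats

        half = stats.t.ppf(0.5 + level / 2.0, self.n - 2) * self.se_slope
        return (self.slope - half, self.slope + half)

    def as_dict(self) -> dict[str, float | int]:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "se_slope": self.se_slope,
            "r2": self.r2,
            "p_value": self.p_value,
            "n": self.n,
        }


def fit_kcost_regression(cohort: Sequence[CohortRecord]) -> RegressionResult:
    """Fit the FFM-adjusted cohort regression and return K_cost with SE.

    Ordinary least squares of y = REE/FFM on x = tumor burden/FFM.  The
    response and predictor are both divided by FFM (ratio regression)
    rather than using FFM as a covariate — this mirrors the published
    fitting choice, though it is statistically debatable.
    """
    if len(cohort) < 3:
        raise UsageError(f"need at least 3 patients, got {len(cohort)}")
    x = np.array([r.liver_plus_met_mass / r.ffm for r in cohort])
    y = np.array([r.ree / r.ffm for r in cohort])
    if np.ptp(x) == 0:
        raise SingularFitError("constant predictor: tumor burden/FFM ratio")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        se_slope=float(model.bse[1]),
        r2=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=len(cohort),
    )


def kcost_from_oxygen_slope(
    slope_per_kg_patient: float, patient_mass: float
) -> tuple[float, float]:
    """Convert a per-kg-patient oxidative increase to K_cost.

    Returns ``(raw, rounded)`` in kcal/kg tumor/day, the rounded value to
    two significant figures as conventionally reported (6.67 * 70 =
    466.9 -> 470).
    """
    if slope_per_kg_patient <= 0 or patient_mass <= 0:
        raise DomainError("slope and patient mass must be > 0")
    raw = slope_per_kg_patient * patient_mass
    return raw, round_sigfigs(raw, 2)


def kcost_to_kcancer_range(
    k_cost_low: float, k_cost_high: float, x_anaerobic: float
) -> tuple[float, float]:
    """Divide a K_cost range by the Cori multiplier to bound K_cancer.

    Each endpoint is divided by (1 + 2 X_anaerobic) and rounded to two
    significant figures (400-470 at X = 0.25 -> 270-310).
    """
    if k_cost_low > k_cost_high:
        raise UsageError(
            f"inverted range: {k_cost_low} > {k_cost_high}"
        )
    if k_cost_low < 0:
        raise DomainError("K_cost must be >= 0")
    mult = cost_multiplier(x_anaerobic)
    return (
        round_sigfigs(k_cost_low / mult, 2),
        round_sigfigs(k_cost_high / mult, 2),
    )


_COHORT_COLUMNS = ("patient_id", "ffm_kg", "liver_plus_met_mass_kg", "ree_kcal_day")


def write_cohort_csv(cohort: Iterable[CohortRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "ffm_kg": r.ffm,
                "liver_plus_met_mass_kg": r.liver_plus_met_mass,
                "ree_kcal_day": r.ree,
            }
            for r in cohort
        ]
    ).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[CohortRecord]:
    df = pd.read_csv(path)
    missing = set(_COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise DomainError(f"cohort CSV missing column(s): {sorted(missing)}")
    return [
        CohortRecord(
            patient_id=str(row["patient_id"]),
            ffm=float(row["ffm_kg"]),
            liver_plus_met_mass=float(row["liver_plus_met_mass_kg"]),
            ree=float(row["ree_kcal_day"]),
        )
        for _, row in df.iterrows()
    ]
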