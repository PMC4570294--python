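"""The tumor cost model proper.

A tumor of mass ``M_cancer`` (kg) with specific metabolic rate ``K_cancer``
(kcal per kg tumor per day) generating a fraction ``X_anaerobic`` of its ATP
by glycolysis costs the host

    P_cost = K_cancer * M_cancer * (1 + 2 * X_anaerobic)   [kcal/day]

The multiplier arises from Cori-cycle bookkeeping: every anaerobic ATP the
tumor makes (2 per glucose) obliges the host to spend 3 ATP (6 per glucose)
reconverting the exported lactate, so a fully anaerobic tumor costs three
times its own metabolic rate.  The same algebra runs in reverse to split an
observed cost rate K_cost into aerobic, anaerobic and Cori components, as
when decomposing a cohort regression slope.

Patient-level accounting composes the tumor cost with a tumor-free baseline
(Kleiber allometry or the Cunningham fat-free-mass equation); indirect
calorimetry sees their sum, REE_IC = P_normal + P_cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, EnergyConstants
from .exceptions import DomainError, UsageError

__all__ = [
    "TumorEnergetics",
    "CostBreakdown",
    "PatientState",
    "cost_multiplier",
    "decompose_specific_cost",
    "tumor_cost",
    "kleiber_bmr",
    "patient_metabolic_rate",
    "cunningham_ree",
    "cost_surface",
    "cost_surface_frame",
    "round_sigfigs",
    "round_half_away",
]


@dataclass(frozen=True)
class TumorEnergetics:
    """The (K_cancer, M_cancer, X_anaerobic) triple defining a tumor."""

    k_cancer: float  # kcal/kg tumor/day
    m_cancer: float  # kg
    x_anaerobic: float  # fraction of tumor ATP from glycolysis

    def __post_init__(self) -> None:
        if self.k_cancer < 0:
            raise DomainError(f"k_cancer must be >= 0, got {self.k_cancer}")
        if self.m_cancer < 0:
            raise DomainError(f"m_cancer must be >= 0, got {self.m_cancer}")
        if not 0.0 <= self.x_anaerobic <= 1.0:
            raise DomainError(
                f"x_anaerobic must lie in [0, 1], got {self.x_anaerobic}"
            )


@dataclass(frozen=True)
class CostBreakdown:
    """Tumor metabolic rate and host cost, split by pathway.

    With ``specific=False`` the fields are absolute rates P_* in kcal/day;
    with ``specific=True`` they are per-kg-tumor rates K_* in
    kcal/kg tumor/day.  Identities (to rounding):

    - cancer  = aerobic + anaerobic          (tumor's own rate)
    - cori    = 3 * anaerobic                (lactate reconversion)
    - cost    = aerobic + cori               (what the host pays)
    - cost    = cancer * (1 + 2 x_anaerobic)

    Standard errors, when present, are exact scalar multiples of the
    driving SE (each component is a fixed multiple of the observed cost).
    """

    aerobic: float
    anaerobic: float
    cori: float
    cancer: float
    cost: float
    x_anaerobic: float
    specific: bool = False
    se_aerobic: Optional[float] = None
    se_anaerobic: Optional[float] = None
    se_cori: Optional[float] = None
    se_cancer: Optional[float] = None
    se_cost: Optional[float] = None

    def validate(self, rtol: float = 1e-9) -> None:
        """Check the pathway identities to relative tolerance ``rtol``."""
        scale = max(abs(self.cost), 1.0)
        checks = {
            "cancer = aerobic + anaerobic": self.cancer
            - (self.aerobic + self.anaerobic),
            "cori = 3 anaerobic": self.cori - 3.0 * self.anaerobic,
            "cost = aerobic + cori": self.cost - (self.aerobic + self.cori),
            "cost = cancer (1+2x)": self.cost
            - self.cancer * (1.0 + 2.0 * self.x_anaerobic),
        }
        for name, resid in checks.items():
            if abs(resid) > rtol * scale:
                raise DomainError(
                    f"cost-breakdown identity violated: {name} (residual {resid:g})"
                )

    def as_dict(self) -> dict[str, float | bool | None]:
        prefix = "k" if self.specific else "p"
        out: dict[str, float | bool | None] = {
            f"{prefix}_aerobic": self.aerobic,
            f"{prefix}_anaerobic": self.anaerobic,
            f"{prefix}_cori": self.cori,
            f"{prefix}_cancer": self.cancer,
            f"{prefix}_cost": self.cost,
            "x_anaerobic": self.x_anaerobic,
            "specific": self.specific,
        }
        if self.se_cost is not None:
            out.update(
                {
                    f"se_{prefix}_aerobic": self.se_aerobic,
                    f"se_{prefix}_anaerobic": self.se_anaerobic,
                    f"se_{prefix}_cori": self.se_cori,
                    f"se_{prefix}_cancer": self.se_cancer,
                    f"se_{prefix}_cost": self.se_cost,
                }
            )
        return out


@dataclass(frozen=True)
class PatientState:
    """Whole-body accounting for one patient.

    ``ree_ic`` is what indirect calorimetry would report: the tumor-free
    metabolic rate plus the full tumor cost (aerobic component plus Cori
    reconversion work, both of which burn oxygen somewhere in the system).
    """

    body_mass: float  # kg, tumor-free mass M_normal
    ffm: float  # kg fat-free mass
    p_normal: float  # kcal/day
    ree_ic: float  # kcal/day

    @classmethod
    def with_tumor(
        cls, body_mass: float, ffm: float, p_normal: float, cost: CostBreakdown
    ) -> "PatientState":
        if cost.specific:
            raise UsageError(
                "PatientState needs an absolute (kcal/day) cost breakdown"
            )
        return cls(body_mass, ffm, p_normal, p_normal + cost.cost)


def cost_multiplier(x_anaerobic: float) -> float:
    """Host-cost multiplier 1 + 2*X_anaerobic, in [1, 3].

    X is the fraction of tumor ATP made by glycolysis; at X=1 the host
    pays three times the tumor's own metabolic rate.
    """
    if not 0.0 <= x_anaerobic <= 1.0:
        raise DomainError(f"x_anaerobic must lie in [0, 1], got {x_anaerobic}")
    return 1.0 + 2.0 * x_anaerobic


def _propagated_se(component: float, cost: float, se_cost: float) -> float:
    # each component is an exact scalar multiple of the observed cost,
    # so its SE is the same multiple of the cost's SE (no quadrature)
    return se_cost * (component / cost) if cost > 0 else 0.0


def decompose_specific_cost(
    k_cost: float,
    x_anaerobic: float,
    se_k_cost: Optional[float] = None,
) -> CostBreakdown:
    """Split an observed specific cost K_cost into pathway components.

    K_cost is what a cohort regression of REE on tumor mass measures:
    the host's total marginal expenditure per kg tumor.  Inverting the
    multiplier gives the tumor's own rate K_cancer = K_cost/(1+2X), which
    then splits into aerobic/anaerobic parts and the Cori surcharge.

    Parameters
    ----------
    k_cost
        Observed cost, kcal/kg tumor/day.
    x_anaerobic
        Fraction of tumor ATP from glycolysis, in [0, 1].
    se_k_cost
        Optional standard error of ``k_cost``; propagated to every
        component as the exact scalar multiple.
    """
    if k_cost < 0:
        raise DomainError(f"k_cost must be >= 0, got {k_cost}")
    if se_k_cost is not None and se_k_cost < 0:
        raise DomainError(f"se_k_cost must be >= 0, got {se_k_cost}")
    mult = cost_multiplier(x_anaerobic)
    k_cancer = k_cost / mult
    k_anaerobic = x_anaerobic * k_cancer
    k_aerobic = (1.0 - x_anaerobic) * k_cancer
    k_cori = 3.0 * k_anaerobic
    ses: dict[str, Optional[float]] = dict.fromkeys(
        ("se_aerobic", "se_anaerobic", "se_cori", "se_cancer", "se_cost")
    )
    if se_k_cost is not None:
        ses = {
            "se_aerobic": _propagated_se(k_aerobic, k_cost, se_k_cost),
            "se_anaerobic": _propagated_se(k_anaerobic, k_cost, se_k_cost),
            "se_cori": _propagated_se(k_cori, k_cost, se_k_cost),
            "se_cancer": _propagated_se(k_cancer, k_cost, se_k_cost),
            "se_cost": se_k_cost,
        }
    return CostBreakdown(
        aerobic=k_aerobic,
        anaerobic=k_anaerobic,
        cori=k_cori,
        cancer=k_cancer,
        cost=k_cost,
        x_anaerobic=x_anaerobic,
        specific=True,
        **ses,
    )


def tumor_cost(t: TumorEnergetics) -> CostBreakdown:
    """Absolute daily cost of a tumor, P_cost = K M (1 + 2X), in kcal/day."""
    p_cancer = t.k_cancer * t.m_cancer
    p_anaerobic = t.x_anaerobic * p_cancer
    p_aerobic = p_cancer - p_anaerobic
    p_cori = 3.0 * p_anaerobic
    return CostBreakdown(
        aerobic=p_aerobic,
        anaerobic=p_anaerobic,
        cori=p_cori,
        cancer=p_cancer,
        cost=p_aerobic + p_cori,
        x_anaerobic=t.x_anaerobic,
        specific=False,
    )


def kleiber_bmr(
    mass: float, constants: EnergyConstants = DEFAULT_CONSTANTS
) -> float:
    """Basal metabolic rate from Kleiber's 3/4-power allometric law.

    P_normal = 69.6 * M^0.75 kcal/day under the defaults; ~1684 kcal/day
    for the 70 kg reference man.
    """
    if mass <= 0:
        raise DomainError(f"mass must be > 0, got {mass}")
    return constants.kleiber_coefficient * mass**constants.kleiber_exponent


def cunningham_ree(
    ffm: float, constants: EnergyConstants = DEFAULT_CONSTANTS
) -> float:
    """Resting energy expenditure predicted from fat-free mass.

    REE = 370 + 21.6 * FFM kcal/day (Cunningham equation).
    """
    if ffm <= 0:
        raise DomainError(f"ffm must be > 0, got {ffm}")
    return constants.cunningham_intercept + constants.cunningham_slope * ffm


def patient_metabolic_rate(
    m_normal: float,
    t: TumorEnergetics,
    k_cost: float,
    constants: EnergyConstants = DEFAULT_CONSTANTS,
) -> float:
    """Total patient metabolic rate: Kleiber baseline plus linear tumor cost.

    P = c * M_normal^0.75 + K_cost * M_cancer.  ``k_cost`` is the observed
    total cost per kg tumor (the multiplier is already inside it), so the
    rate is exactly linear in tumor mass.
    """
    if k_cost < 0:
        raise DomainError(f"k_cost must be >= 0, got {k_cost}")
    return kleiber_bmr(m_normal, constants) + k_cost * t.m_cancer


def cost_surface(
    k_cancer: float,
    m_grid: Sequence[float],
    x_grid: Sequence[float],
) -> np.ndarray:
    """Tumor-cost map over a (mass, anaerobic-fraction) grid.

    Returns an array of shape ``(len(m_grid), len(x_grid))`` holding
    P_cost = K * M * (1+2X) in kcal/day; monotone non-decreasing along
    both axes.
    """
    m = np.asarray(list(m_grid), dtype=float)
    x = np.asarray(list(x_grid), dtype=float)
    if m.size == 0 or x.size == 0:
        raise UsageError("cost_surface requires non-empty mass and X grids")
    if k_cancer < 0 or (m < 0).any():
        raise DomainError("k_cancer and tumor masses must be >= 0")
    if ((x < 0) | (x > 1)).any():
        raise DomainError("x_anaerobic grid values must lie in [0, 1]")
    return k_cancer * m[:, None] * (1.0 + 2.0 * x[None, :])


def cost_surface_frame(
    k_cancer: float,
    m_grid: Sequence[float],
    x_grid: Sequence[float],
) -> pd.DataFrame:
    """Long-format cost map: columns m_cancer_kg, x_anaerobic, p_cost_kcal_per_day."""
    grid = cost_surface(k_cancer, m_grid, x_grid)
    m = np.repeat(np.asarray(list(m_grid), float), len(list(x_grid)))
    x = np.tile(np.asarray(list(x_grid), float), grid.shape[0])
    return pd.DataFrame(
        {
            "m_cancer_kg": m,
            "x_anaerobic": x,
            "p_cost_kcal_per_day": grid.ravel(),
        }
    )


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round to ``ndigits`` decimals with halves away from zero.

    Python's built-in ``round`` is banker's rounding; reported
    percentages here follow the half-away-from-zero convention instead.
    """
    if not math.isfinite(value):
        return float(value)
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def round_sigfigs(value: float, n: int) -> float:
    """Round to ``n`` significant figures, halves away from zero.

    Reported rates in this package are conventionally printed to two
    significant figures (466.9 -> 470, 249 -> 250); internal computation
    is never rounded.
    """
    if n < 1:
        raise DomainError(f"significant figures must be >= 1, got {n}")
    if value == 0 or not math.isfinite(value):
        return float(value)
    shift = n - 1 - math.floor(math.log10(abs(value)))
    d = Decimal(repr(value)).scaleb(shift).quantize(
        Decimal(1), rounding=ROUND_HALF_UP
    )
    return float(d.scaleb(-shift))
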