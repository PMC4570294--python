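"""Glucose-fate statistics: tumor capture, recycling payout, energy lost.

A glucose molecule entering the bloodstream is captured by the tumor with
probability ``p_cancer`` (estimable from excess turnover in cancer patients
versus controls).  A captured glucose is converted to lactate with
probability ``p_anaerobic`` (estimable from excess Cori cycling), in which
case the host spends 6 ATP reconverting it and the regenerated glucose
re-enters the bloodstream to face the same fates; otherwise the tumor
oxidizes it and its energy is lost outright.  Glucose never captured yields
the host the full 30 ATP.

The expected ATP payout per glucose entering the bloodstream, g, is the
fixed point of the recycling recursion

    g = (1 - p_c) * 30 + p_c * p_a * (g - 6) + p_c * (1 - p_a) * 0
      = [30 (1 - p_c) - 6 p_c p_a] / (1 - p_c p_a)

and the fraction of glucose energy lost to the host is
p_lost = (30 - g)/30.  Near p_c * p_a -> 1 the recycling chain diverges and
p_lost may exceed 1 (net-negative payout); computation never clips.

The module also converts between the glucose-fraction ``p_anaerobic`` and
the ATP-fraction ``X_anaerobic`` (fraction of tumor ATP from glycolysis):
because oxidation yields 15x the ATP of glycolysis per glucose, a tumor
converting 84 % of its glucose to lactate still makes only ~26 % of its
ATP anaerobically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, EnergyConstants
from .exceptions import DataConsistencyError, DivergenceError, DomainError, UsageError

__all__ = [
    "TracerRates",
    "GlucoseFateParams",
    "p_cancer_from_turnover",
    "p_anaerobic_from_cori",
    "x_from_p_anaerobic",
    "p_from_x_anaerobic",
    "expected_payout",
    "p_lost",
    "plost_surface",
    "plost_surface_frame",
    "simulate_payout",
]


@dataclass(frozen=True)
class TracerRates:
    """Paired cancer/control isotope-dilution measurements.

    ``t_*`` are whole-body glucose turnover rates and ``c_*`` Cori-cycling
    rates, in any common unit (conventionally g/kg/day); only differences
    and ratios are used.
    """

    t_cancer: float
    t_control: float
    c_cancer: float
    c_control: float

    def __post_init__(self) -> None:
        if not self.t_cancer >= self.t_control >= 0:
            raise DomainError(
                f"need t_cancer >= t_control >= 0, got "
                f"({self.t_cancer}, {self.t_control})"
            )
        if not self.c_cancer >= self.c_control >= 0:
            raise DomainError(
                f"need c_cancer >= c_control >= 0, got "
                f"({self.c_cancer}, {self.c_control})"
            )
        if self.c_cancer > self.t_cancer or self.c_control > self.t_control:
            raise DomainError("Cori-cycling rate cannot exceed total turnover")


@dataclass(frozen=True)
class GlucoseFateParams:
    """Derived glucose-fate statistics for one cancer/control comparison."""

    p_cancer: float
    p_anaerobic: float
    x_anaerobic: float
    g_payout: float  # expected ATP per glucose entering the bloodstream
    p_lost: float  # fraction of glucose energy lost to the host

    @classmethod
    def from_rates(
        cls,
        rates: TracerRates,
        constants: EnergyConstants = DEFAULT_CONSTANTS,
    ) -> "GlucoseFateParams":
        pc = p_cancer_from_turnover(rates)
        pa = p_anaerobic_from_cori(rates)
        return cls(
            p_cancer=pc,
            p_anaerobic=pa,
            x_anaerobic=x_from_p_anaerobic(pa, constants),
            g_payout=expected_payout(pc, pa, constants),
            p_lost=p_lost(pc, pa, constants),
        )


def p_cancer_from_turnover(rates: TracerRates) -> float:
    """Fraction of blood glucose captured by the tumor.

    p_cancer = (t_cancer - t_control) / t_cancer: the tumor-attributed
    share of total turnover.
    """
    if rates.t_cancer <= 0:
        raise DomainError("t_cancer must be > 0 to estimate p_cancer")
    return (rates.t_cancer - rates.t_control) / rates.t_cancer


def p_anaerobic_from_cori(rates: TracerRates) -> float:
    """Fraction of tumor-consumed glucose converted to lactate.

    p_anaerobic = (C_cancer - C_control) / (t_cancer - t_control): excess
    Cori cycling relative to excess turnover.
    """
    excess_turnover = rates.t_cancer - rates.t_control
    if excess_turnover <= 0:
        raise DomainError(
            "t_cancer must exceed t_control to estimate p_anaerobic"
        )
    p = (rates.c_cancer - rates.c_control) / excess_turnover
    if not 0.0 <= p <= 1.0:
        raise DataConsistencyError(
            f"excess Cori cycling implies p_anaerobic = {p:.4f} outside [0, 1]"
        )
    return p


def x_from_p_anaerobic(
    p: float, constants: EnergyConstants = DEFAULT_CONSTANTS
) -> float:
    """ATP-fraction X_anaerobic implied by a glucose-fraction p_anaerobic.

    X = a_g p / (a_g p + a_o (1 - p)) with glycolytic yield a_g = 2 and
    oxidative yield a_o = 30; monotone increasing with X <= p.
    """
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"p_anaerobic must lie in [0, 1], got {p}")
    a_g = constants.atp_glycolysis_per_glucose
    a_o = constants.atp_aerobic_per_glucose
    return a_g * p / (a_g * p + a_o * (1.0 - p))


def p_from_x_anaerobic(
    x: float, constants: EnergyConstants = DEFAULT_CONSTANTS
) -> float:
    """Glucose-fraction p_anaerobic implied by an ATP-fraction X_anaerobic.

    Exact inverse of :func:`x_from_p_anaerobic`; under the default yields
    p = 15 X / (1 + 14 X).
    """
    if not 0.0 <= x <= 1.0:
        raise DomainError(f"x_anaerobic must lie in [0, 1], got {x}")
    a_g = constants.atp_glycolysis_per_glucose
    a_o = constants.atp_aerobic_per_glucose
    return a_o * x / (a_o * x + a_g * (1.0 - x))


def _check_fate_domain(p_cancer: float, p_anaerobic: float) -> None:
    if not 0.0 <= p_cancer <= 1.0:
        raise DomainError(f"p_cancer must lie in [0, 1], got {p_cancer}")
    if not 0.0 <= p_anaerobic <= 1.0:
        raise DomainError(f"p_anaerobic must lie in [0, 1], got {p_anaerobic}")
    if p_cancer * p_anaerobic >= 1.0:
        raise DivergenceError(
            "p_cancer * p_anaerobic = 1: the recycling chain never terminates"
        )


def expected_payout(
    p_cancer: float,
    p_anaerobic: float,
    constants: EnergyConstants = DEFAULT_CONSTANTS,
) -> float:
    """Expected ATP delivered to the host per glucose entering the blood.

    Closed form of the recycling recursion; <= 30 always, and negative
    when Cori reconversion work outruns the host's share of the glucose.
    The tumor's own 2 glycolytic ATP never appear on the host's ledger.
    """
    _check_fate_domain(p_cancer, p_anaerobic)
    a_o = constants.atp_aerobic_per_glucose
    cori = constants.atp_cori_cost_per_glucose
    pc, pa = p_cancer, p_anaerobic
    return (a_o * (1.0 - pc) - cori * pc * pa) / (1.0 - pc * pa)


def p_lost(
    p_cancer: float,
    p_anaerobic: float,
    constants: EnergyConstants = DEFAULT_CONSTANTS,
) -> float:
    """Fraction of glucose energy lost to the host, (30 - g)/30.

    May exceed 1 near the divergence boundary (net-negative payout);
    never clipped in computation.
    """
    g = expected_payout(p_cancer, p_anaerobic, constants)
    return (constants.atp_aerobic_per_glucose - g) / constants.atp_aerobic_per_glucose


def plost_surface(
    pc_grid: Sequence[float],
    pa_or_x_grid: Sequence[float],
    axis_mode: str = "x_anaerobic",
    constants: EnergyConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """p_lost map over a (p_cancer, anaerobic-fraction) grid.

    ``axis_mode`` selects whether the second axis holds the glucose
    fraction ``p_anaerobic`` directly or the ATP fraction ``x_anaerobic``
    (converted internally).  Cells where p_c * p_a >= 1 are undefined and
    returned as NaN.  Shape is ``(len(pc_grid), len(second_grid))``.
    """
    if axis_mode not in {"p_anaerobic", "x_anaerobic"}:
        raise UsageError(f"unknown axis_mode {axis_mode!r}")
    pc = np.asarray(list(pc_grid), dtype=float)
    second = np.asarray(list(pa_or_x_grid), dtype=float)
    if pc.size == 0 or second.size == 0:
        raise UsageError("plost_surface requires non-empty grids")
    if ((pc < 0) | (pc > 1)).any() or ((second < 0) | (second > 1)).any():
        raise DomainError("grid fractions must lie in [0, 1]")
    if axis_mode == "x_anaerobic":
        pa = np.array([p_from_x_anaerobic(x, constants) for x in second])
    else:
        pa = second
    a_o = constants.atp_aerobic_per_glucose
    cori = constants.atp_cori_cost_per_glucose
    pcpa = pc[:, None] * pa[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        g = (a_o * (1.0 - pc[:, None]) - cori * pcpa) / (1.0 - pcpa)
        out = (a_o - g) / a_o
    out[pcpa >= 1.0] = np.nan
    return out


def plost_surface_frame(
    pc_grid: Sequence[float],
    x_grid: Sequence[float],
    constants: EnergyConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Long-format p_lost map: columns p_cancer, x_anaerobic, p_lost.

    Undefined (divergent) cells carry NaN, which serializes to an empty
    CSV field.
    """
    grid = plost_surface(pc_grid, x_grid, "x_anaerobic", constants)
    pc = np.repeat(np.asarray(list(pc_grid), float), len(list(x_grid)))
    x = np.tile(np.asarray(list(x_grid), float), grid.shape[0])
    return pd.DataFrame(
        {"p_cancer": pc, "x_anaerobic": x, "p_lost": grid.ravel()}
    )


def simulate_payout(
    p_cancer: float,
    p_anaerobic: float,
    n_samples: int = 1_000_000,
    seed: int = 0,
    constants: EnergyConstants = DEFAULT_CONSTANTS,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the per-glucose ATP payout, (mean, sem).

    Simulates each glucose fate step by step: captured by the tumor with
    probability ``p_cancer``; a captured glucose is recycled at a cost of
    6 ATP (re-entering the pool) with probability ``p_anaerobic``, else
    terminally oxidized by the tumor for 0 host ATP; an uncaptured
    glucose terminally yields the host 30 ATP.  This direct chain
    simulation is the independent check on the closed-form recursion.
    """
    _check_fate_domain(p_cancer, p_anaerobic)
    rng = np.random.default_rng(seed)
    a_o = constants.atp_aerobic_per_glucose
    cori = constants.atp_cori_cost_per_glucose
    payout = np.zeros(n_samples)
    active = np.ones(n_samples, dtype=bool)
    while active.any():
        n_active = int(active.sum())
        captured = rng.random(n_active) < p_cancer
        recycled = captured & (rng.random(n_active) < p_anaerobic)
        idx = np.flatnonzero(active)
        payout[idx[~captured]] += a_o  # escaped to the host: full yield
        payout[idx[recycled]] -= cori  # recycled: pay Cori cost, go again
        # captured & not recycled: oxidized by tumor, 0 for the host
        still = np.zeros(n_active, dtype=bool)
        still[recycled] = True
        active[idx] = still
    return float(payout.mean()), float(payout.std(ddof=1) / np.sqrt(n_samples))
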