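"""Blood-glucose flux balance and the glucose-only component of tumor cost.

At a static blood-glucose level, inflows (food F_g, Cori recycling C_g,
de novo gluconeogenesis D_g, glycogen mobilization S_g) balance outflows
(organs O_g, tumor T_g, adipose storage A_g, glycogen storage G_g), all in
g glucose/day.  Assuming the tumor's anaerobic glucose draw is exactly what
the liver recycles (T_anaerobic = C_g) cancels those two terms, leaving the
reduced balance F_g + D_g + S_g = O_g + T_aerobic + A_g + G_g: the tumor's
aerobic draw is the irrecoverable drain on the host's glucose supply.

``glucose_cost`` prices a measured tumor-attributed excess glucose turnover
in kcal/day: aerobically consumed glucose is lost at its full combustion
energy, while anaerobically cycled glucose costs only the Cori recycling
fraction (6 of 30 ATP-equivalents under the defaults).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .constants import DEFAULT_CONSTANTS, EnergyConstants
from .exceptions import DataConsistencyError, DomainError

__all__ = [
    "GlucoseFluxState",
    "TurnoverStudy",
    "TRACER_COST_STUDIES",
    "check_balance",
    "reduce_balance_with_cori",
    "glucose_cost",
    "read_turnover_csv",
    "write_turnover_csv",
]

_RATE_FIELDS = (
    "f_g", "c_g", "d_g", "s_g",  # inflows
    "o_g", "t_g", "a_g", "g_g",  # outflows
    "t_anaerobic", "t_aerobic",
)


@dataclass(frozen=True)
class GlucoseFluxState:
    """Instantaneous blood-glucose flux rates, g glucose/day.

    ``t_g`` must equal ``t_anaerobic + t_aerobic`` (the tumor's draw split
    by fate).  No intra-day fed/fasted scheduling is modelled; fed and
    fasting narratives are encoded as alternative states.
    """

    f_g: float = 0.0  # food
    c_g: float = 0.0  # Cori recycling
    d_g: float = 0.0  # de novo gluconeogenesis
    s_g: float = 0.0  # glycogen mobilization
    o_g: float = 0.0  # organ consumption
    t_g: float = 0.0  # tumor consumption
    a_g: float = 0.0  # adipose storage
    g_g: float = 0.0  # glycogen storage
    t_anaerobic: float = 0.0
    t_aerobic: float = 0.0

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            if getattr(self, name) < 0:
                raise DomainError(f"flux rate {name} must be >= 0")
        split = self.t_anaerobic + self.t_aerobic
        if abs(self.t_g - split) > 1e-9 * max(self.t_g, split, 1.0):
            raise DataConsistencyError(
                f"t_g = {self.t_g} must equal t_anaerobic + t_aerobic = {split}"
            )

    @property
    def inflow(self) -> float:
        return self.f_g + self.c_g + self.d_g + self.s_g

    @property
    def outflow(self) -> float:
        return self.o_g + self.t_g + self.a_g + self.g_g

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GlucoseFluxState":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class TurnoverStudy:
    """One published tracer study of glucose turnover in cancer patients.

    ``delta_turnover`` is the tumor-attributed excess glucose turnover in
    g/kg patient/day; ``p_cancer`` the fraction of blood glucose captured
    by the tumor; ``x_anaerobic`` the implied fraction of tumor ATP from
    glycolysis; ``cost_glucose`` the study's published glucose-only tumor
    cost in kcal/day for the reference patient.
    """

    label: str
    delta_turnover: float  # g glucose/kg patient/day
    patient_mass: float  # kg
    p_cancer: float
    x_anaerobic: float
    cost_glucose: float  # kcal/day

    def __post_init__(self) -> None:
        if self.delta_turnover < 0:
            raise DomainError("delta_turnover must be >= 0")
        for name in ("p_cancer", "x_anaerobic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must lie in [0, 1], got {v}")


#: The three tracer comparisons used to price tumor glucose consumption
#: (metastatic carcinoma vs weight-stable; colorectal vs age-matched
#: controls; malnourished cancer vs malnourished non-cancer), with their
#: published excess turnover, capture fraction, implied glycolytic ATP
#: fraction and glucose-only cost for a 70 kg patient.
TRACER_COST_STUDIES: tuple[TurnoverStudy, ...] = (
    TurnoverStudy("C", 2.06, 70.0, 0.44, 0.26, 200.0),
    TurnoverStudy("D", 0.850, 70.0, 0.26, 0.19, 94.0),
    TurnoverStudy("E", 1.19, 70.0, 0.27, 0.04, 240.0),
)


def check_balance(
    state: GlucoseFluxState, tol: float = 1e-9
) -> tuple[bool, float]:
    """Check the static blood-glucose balance; returns (balanced, residual).

    The residual is inflow minus outflow in g/day; balance holds when its
    magnitude is within ``tol`` times the larger side.
    """
    residual = state.inflow - state.outflow
    scale = max(state.inflow, state.outflow)
    return (abs(residual) <= tol * scale if scale > 0 else True), residual


def reduce_balance_with_cori(state: GlucoseFluxState) -> GlucoseFluxState:
    """Apply the T_anaerobic = C_g identification and cancel both terms.

    The returned state has the Cori inflow and the tumor's anaerobic draw
    cancelled against each other, so its balance equation is the reduced
    form F_g + D_g + S_g = O_g + T_aerobic + A_g + G_g.  When ``c_g``
    already equals ``t_anaerobic`` (including both zero) the residual is
    unchanged, so the reduced state balances iff the original did; an
    unset (zero) ``c_g`` with a positive anaerobic draw is filled in by
    the identification first.  A pre-set conflicting ``c_g`` is an error.
    """
    if state.c_g not in (0.0, state.t_anaerobic):
        raise DataConsistencyError(
            f"c_g already set to {state.c_g}, conflicting with "
            f"t_anaerobic = {state.t_anaerobic}"
        )
    # set c_g = t_anaerobic, then drop both from their respective sides
    return dataclasses.replace(
        state,
        c_g=0.0,
        t_g=state.t_aerobic,
        t_anaerobic=0.0,
    )


def glucose_cost(
    delta_turnover: float,
    patient_mass: float,
    p_anaerobic: float,
    constants: EnergyConstants = DEFAULT_CONSTANTS,
) -> float:
    """Energetic cost (kcal/day) of tumor-attributed excess glucose turnover.

    The excess turnover is split by fate: a fraction ``1 - p_anaerobic``
    is oxidized by the tumor and lost to the host at full combustion
    energy (686 kcal/mol), while the anaerobic fraction returns as lactate
    and costs only the Cori reconversion share of that energy
    (6/30 under the default ATP yields).

    Parameters
    ----------
    delta_turnover
        Tumor-attributed excess glucose turnover, g/kg patient/day.
    patient_mass
        Patient mass, kg.
    p_anaerobic
        Fraction of tumor-consumed glucose converted to lactate.
    """
    if delta_turnover < 0 or patient_mass < 0:
        raise DomainError("delta_turnover and patient_mass must be >= 0")
    if not 0.0 <= p_anaerobic <= 1.0:
        raise DomainError(f"p_anaerobic must lie in [0, 1], got {p_anaerobic}")
    moles = delta_turnover * patient_mass / constants.glucose_molar_mass_g_per_mol
    recycle_fraction = (
        constants.atp_cori_cost_per_glucose / constants.atp_aerobic_per_glucose
    )
    energy_share = (1.0 - p_anaerobic) + p_anaerobic * recycle_fraction
    return moles * constants.glucose_energy_kcal_per_mol * energy_share


_TURNOVER_COLUMNS = {
    "study": "label",
    "delta_turnover_g_per_kg_day": "delta_turnover",
    "patient_mass_kg": "patient_mass",
    "p_cancer": "p_cancer",
    "x_anaerobic": "x_anaerobic",
    "cost_glucose_kcal_day": "cost_glucose",
}


def write_turnover_csv(
    studies: Iterable[TurnoverStudy], path: str | Path
) -> None:
    rows = [
        {col: getattr(s, attr) for col, attr in _TURNOVER_COLUMNS.items()}
        for s in studies
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_turnover_csv(path: str | Path) -> list[TurnoverStudy]:
    df = pd.read_csv(path)
    missing = set(_TURNOVER_COLUMNS) - set(df.columns)
    if missing:
        raise DomainError(f"turnover CSV missing column(s): {sorted(missing)}")
    return [
        TurnoverStudy(
            **{attr: row[col] for col, attr in _TURNOVER_COLUMNS.items()}
        )
        for _, row in df.iterrows()
    ]
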