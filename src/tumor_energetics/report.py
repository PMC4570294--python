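"""Reproduction report: recompute every published headline number.

Each entry recomputes a published quantity from the model under a given
constant set and compares it, at the published precision, with the printed
value.  With the default constants every entry matches; overriding a
constant (say the textbook 38-ATP aerobic yield) flags the downstream
entries that move.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .cohort import kcost_from_oxygen_slope, kcost_to_kcancer_range
from .constants import DEFAULT_CONSTANTS, EnergyConstants
from .core import (
    TumorEnergetics,
    round_half_away,
    decompose_specific_cost,
    kleiber_bmr,
    round_sigfigs,
    tumor_cost,
)
from .glucose_fate import p_from_x_anaerobic, p_lost, x_from_p_anaerobic

__all__ = ["ReportEntry", "reproduction_report", "report_frame"]

#: Published oxygen-consumption slope, kcal/kg tumor/day per kg patient.
OXYGEN_SLOPE = 6.67
#: Reference-man mass used for all headline conversions, kg.
REFERENCE_MASS = 70.0
#: Lower patient-mass bracket for the oxygen-consumption study, kg.
LOWER_MASS = 60.0
#: Base-case fraction of tumor ATP from glycolysis.
BASE_X = 0.25
#: REE-regression cost estimate and its standard error, kcal/kg tumor/day.
REE_KCOST, REE_KCOST_SE = 300.0, 110.0


@dataclass(frozen=True)
class ReportEntry:
    quantity: str
    computed: float
    reported: float  # value as computed, on the published rounding
    printed: float  # the published value
    units: str

    @property
    def match(self) -> bool:
        return self.reported == self.printed


def reproduction_report(
    constants: EnergyConstants = DEFAULT_CONSTANTS,
) -> list[ReportEntry]:
    """Recompute the published headline estimates under ``constants``."""
    entries: list[ReportEntry] = []

    def add(quantity, computed, reported, printed, units):
        entries.append(ReportEntry(quantity, computed, reported, printed, units))

    # REE-cohort decomposition at the base anaerobic fraction
    d = decompose_specific_cost(REE_KCOST, BASE_X, REE_KCOST_SE)
    for name, computed, printed in (
        ("K_cancer (REE cohort)", d.cancer, 200.0),
        ("K_aerobic (REE cohort)", d.aerobic, 150.0),
        ("K_anaerobic (REE cohort)", d.anaerobic, 50.0),
        ("K_Cori (REE cohort)", d.cori, 150.0),
        ("SE K_cancer (REE cohort)", d.se_cancer, 73.0),
        ("SE K_aerobic (REE cohort)", d.se_aerobic, 55.0),
        ("SE K_anaerobic (REE cohort)", d.se_anaerobic, 18.0),
        ("SE K_Cori (REE cohort)", d.se_cori, 55.0),
    ):
        add(name, computed, round_sigfigs(computed, 2), printed, "kcal/kg tumor/day")

    # oxygen-consumption study: K_cost at the 60/70 kg mass bracket
    for mass, printed in ((LOWER_MASS, 400.0), (REFERENCE_MASS, 470.0)):
        raw, rounded = kcost_from_oxygen_slope(OXYGEN_SLOPE, mass)
        add(f"K_cost (O2 study, {mass:.0f} kg)", raw, rounded, printed, "kcal/kg tumor/day")
    lo, hi = kcost_to_kcancer_range(
        OXYGEN_SLOPE * LOWER_MASS, OXYGEN_SLOPE * REFERENCE_MASS, BASE_X
    )
    add("K_cancer low (O2 study)", lo, lo, 270.0, "kcal/kg tumor/day")
    add("K_cancer high (O2 study)", hi, hi, 310.0, "kcal/kg tumor/day")

    # worked examples: disseminated 1.8 kg tumor; mean retrospective burden
    cost_18 = tumor_cost(TumorEnergetics(200.0, 1.8, BASE_X)).cost
    add("P_cost (1.8 kg tumor)", cost_18, round_sigfigs(cost_18, 2), 540.0, "kcal/day")
    pct_bmr = 100.0 * cost_18 / kleiber_bmr(REFERENCE_MASS, constants)
    add("P_cost / reference BMR", pct_bmr, round_half_away(pct_bmr), 32.0, "%")
    cost_083 = tumor_cost(TumorEnergetics(200.0, 0.83, BASE_X)).cost
    add("P_cost (0.83 kg burden)", cost_083, round_sigfigs(cost_083, 2), 250.0, "kcal/day")

    # glucose-fraction <-> ATP-fraction conversions
    for p, printed in ((0.84, 26.0), (0.40, 4.0)):
        x = 100.0 * x_from_p_anaerobic(p, constants)
        add(f"X_anaerobic at p_anaerobic={p}", x, round_half_away(x), printed, "%")

    # energy lost to the tumor for the three tracer comparisons
    for label, pc, pa, printed in (
        ("C", 0.44, 0.84, 23.0),
        ("D", 0.26, p_from_x_anaerobic(0.19, constants), 12.0),
        ("E", 0.27, p_from_x_anaerobic(0.04, constants), 21.0),
    ):
        pl = 100.0 * p_lost(pc, pa, constants)
        add(f"p_lost (study {label})", pl, round_half_away(pl), printed, "%")

    return entries


def report_frame(entries: Sequence[ReportEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "quantity": e.quantity,
                "computed": e.computed,
                "reported": e.reported,
                "printed": e.printed,
                "units": e.units,
                "match": e.match,
            }
            for e in entries
        ]
    )
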