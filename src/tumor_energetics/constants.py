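"""Fixed energy-bookkeeping constants of the host-tumor energy-balance model.

The model prices glucose fates in ATP: oxidative phosphorylation yields
~30 ATP per glucose (the modern estimate, down from the textbook 38),
glycolysis to lactate yields 2, and the Cori cycle spends 6 ATP per glucose
of lactate reconverted in liver and kidney.  The 6-vs-2 ratio is what makes
a fully anaerobic tumor cost the host three times the tumor's own metabolic
rate.  Baseline (tumor-free) metabolic rate comes from either Kleiber's
allometric law (69.6 M^0.75 kcal/day) or the Cunningham fat-free-mass
regression (370 + 21.6 FFM kcal/day).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

from .exceptions import DomainError

__all__ = ["EnergyConstants", "DEFAULT_CONSTANTS"]


@dataclass(frozen=True)
class EnergyConstants:
    """Energy and ATP bookkeeping values shared by every model component.

    All fields must be strictly positive.  Overriding the ATP yields is
    supported (e.g. the textbook 38-ATP aerobic yield) and propagates
    consistently through every downstream statistic.
    """

    #: ATP per glucose fully oxidized (oxidative phosphorylation).
    atp_aerobic_per_glucose: float = 30.0
    #: net ATP per glucose converted to lactate by glycolysis.
    atp_glycolysis_per_glucose: float = 2.0
    #: ATP spent by liver/kidney to reconvert one glucose worth of lactate.
    atp_cori_cost_per_glucose: float = 6.0
    #: combustion energy of glucose, kcal/mol.
    glucose_energy_kcal_per_mol: float = 686.0
    #: molar mass of glucose, g/mol.
    glucose_molar_mass_g_per_mol: float = 180.0
    #: Kleiber allometric coefficient, kcal/day/kg^exponent.
    kleiber_coefficient: float = 69.6
    #: Kleiber allometric exponent (3/4 law).
    kleiber_exponent: float = 0.75
    #: Cunningham REE intercept, kcal/day.
    cunningham_intercept: float = 370.0
    #: Cunningham REE slope, kcal/day per kg fat-free mass.
    cunningham_slope: float = 21.6
    #: hepatic glycogen buffer, g glucose.  Documented context for the
    #: blood-glucose flux diagram; no computation consumes it.
    liver_glycogen_buffer_g: float = 110.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise DomainError(
                    f"EnergyConstants.{f.name} must be strictly positive, got {v!r}"
                )

    @property
    def cori_multiplier_slope(self) -> float:
        """Slope of the cost multiplier 1 + slope * X_anaerobic.

        Equals cori_cost/glycolysis - 1 = 2 under the defaults: each
        anaerobic ATP obliges the host to spend 3 ATP recycling, a net
        2-ATP surcharge on top of the tumor's own unit.
        """
        return (
            self.atp_cori_cost_per_glucose / self.atp_glycolysis_per_glucose - 1.0
        )

    def replace(self, **overrides: float) -> "EnergyConstants":
        """Return a copy with the given fields overridden (type-checked)."""
        unknown = set(overrides) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise DomainError(f"unknown EnergyConstants field(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_mapping(cls, overrides: Mapping[str, Any]) -> "EnergyConstants":
        return cls().replace(**{k: float(v) for k, v in overrides.items()})

    @classmethod
    def from_file(cls, path: str | Path) -> "EnergyConstants":
        """Load overrides from a JSON or YAML config file.

        The file holds a flat mapping of field name to value; absent
        fields keep their defaults.
        """
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        if not isinstance(data, Mapping):
            raise DomainError(f"constants config {path} must be a flat mapping")
        return cls.from_mapping(data)


DEFAULT_CONSTANTS = EnergyConstants()
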