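"""Model parameters: coupling, trafficking, production, compartment geometry.

Units
-----
* coupling rate constants ``kc_*``: (molecules/um^2)^-1 s^-1 (base values;
  the per-compartment effective constant is base / membrane_area, in
  (molecules/cell)^-1 s^-1)
* uncoupling rate constants ``kd_*``: s^-1
* trafficking rate constants ``k_int/k_rec4/k_4to11/k_rec11/k_deg``: s^-1
* production rates ``k_prod_*``: molecules cell^-1 s^-1 (zeroth order, into
  surface monomers)
* membrane areas: um^2
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import yaml

RECEPTORS = ("R1", "R2", "N1")
TRAFFICKING_PROCESSES = ("k_int", "k_rec4", "k_4to11", "k_rec11", "k_deg")

#: Fit bounds for first-order trafficking rate constants, s^-1.
TRAFFICKING_BOUNDS = (1e-6, 1e-1)

TRAFFICKING_NAMES = tuple(
    f"{p}_{r}" for r in RECEPTORS for p in TRAFFICKING_PROCESSES
)
PRODUCTION_NAMES = tuple(f"k_prod_{r}" for r in RECEPTORS)
COUPLING_NAMES = ("kc_R1R1", "kc_R2R2", "kc_R1N1", "kd_R1R1", "kd_R2R2", "kd_R1N1")


@dataclass(frozen=True)
class Compartments:
    """Membrane areas of the three live compartments, um^2.

    The surface area of 1000 um^2 makes a base coupling constant of
    1e-4 (molec/um^2)^-1 s^-1 correspond to an effective surface constant of
    1e-7 (molec/cell)^-1 s^-1.  Endosomal areas are configurable model
    constants.
    """

    surface_area: float = 1000.0
    rab4_area: float = 100.0
    rab11_area: float = 100.0

    def area(self, compartment) -> float:
        from .receptors import Compartment

        return {
            Compartment.SURFACE: self.surface_area,
            Compartment.RAB4: self.rab4_area,
            Compartment.RAB11: self.rab11_area,
        }[Compartment(compartment)]

    def validate(self) -> None:
        if min(self.surface_area, self.rab4_area, self.rab11_area) <= 0:
            raise ValueError("membrane areas must be positive")


@dataclass(frozen=True)
class ParameterSet:
    """Flat named rate constants plus compartment geometry.

    ``values`` holds the 15 trafficking constants, 3 production rates and
    6 coupling/uncoupling constants keyed by canonical names such as
    ``k_int_R1`` or ``kc_R1N1``.
    """

    values: Mapping[str, float]
    compartments: Compartments = field(default_factory=Compartments)

    def __post_init__(self):
        missing = [
            n
            for n in (*TRAFFICKING_NAMES, *PRODUCTION_NAMES, *COUPLING_NAMES)
            if n not in self.values
        ]
        if missing:
            raise ValueError(f"missing parameters: {missing}")
        bad = {k: v for k, v in self.values.items() if v < 0}
        if bad:
            raise ValueError(f"negative rate constants: {bad}")
        object.__setattr__(self, "values", dict(self.values))

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def trafficking(self) -> dict[str, float]:
        return {n: self.values[n] for n in TRAFFICKING_NAMES}

    def production(self) -> dict[str, float]:
        return {n: self.values[n] for n in PRODUCTION_NAMES}

    def coupling(self) -> dict[str, float]:
        return {n: self.values[n] for n in COUPLING_NAMES}

    def with_values(self, updates: Mapping[str, float]) -> "ParameterSet":
        unknown = set(updates) - set(self.values)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        return replace(self, values={**self.values, **updates})

    def with_factors(self, factors: Mapping[str, float]) -> "ParameterSet":
        """Multiplicative edits (how perturbations are expressed)."""
        return self.with_values(
            {k: self.values[k] * f for k, f in factors.items()}
        )

    # ---- I/O -------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "parameters": {k: float(v) for k, v in self.values.items()},
            "compartments": {
                "surface_area_um2": self.compartments.surface_area,
                "rab4_area_um2": self.compartments.rab4_area,
                "rab11_area_um2": self.compartments.rab11_area,
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSet":
        comp = d.get("compartments", {})
        return cls(
            values=dict(d["parameters"]),
            compartments=Compartments(
                surface_area=comp.get("surface_area_um2", 1000.0),
                rab4_area=comp.get("rab4_area_um2", 100.0),
                rab11_area=comp.get("rab11_area_um2", 100.0),
            ),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParameterSet":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


#: Ligand-independent coupling defaults.  kd = 0.01 s^-1 throughout; the
#: VEGFR1-NRP1 base coupling constant 8e-4 (molec/um^2)^-1 s^-1 gives, with a
#: 1000 um^2 surface, an effective surface K_d of 12,500 molecules/cell.
DEFAULT_COUPLING: dict[str, float] = {
    "kc_R1R1": 1e-4,
    "kc_R2R2": 1e-4,
    "kc_R1N1": 8e-4,
    "kd_R1R1": 0.01,
    "kd_R2R2": 0.01,
    "kd_R1N1": 0.01,
}

#: Reference trafficking constants (s^-1), anchored on the measured surface
#: residence times (53 s / 50 min / 43 min for VEGFR1/VEGFR2/NRP1), the
#: ~4.9:1 VEGFR1 recycling:degradation ratio, and the observed surface
#: percentages.  They serve as documented defaults for demonstrations and as
#: the reference point for the production-rate solve; the calibration module
#: re-estimates all of them from data.
REFERENCE_TRAFFICKING: dict[str, float] = {
    # VEGFR1: fast internalization, substantial recycling via both routes
    "k_int_R1": 1.3e-2,
    "k_rec4_R1": 1.2e-3,
    "k_4to11_R1": 1.2e-3,
    "k_rec11_R1": 1.2e-3,
    "k_deg_R1": 4.9e-4,
    # VEGFR2: slow internalization, very low recycling
    "k_int_R2": 2.31e-4,
    "k_rec4_R2": 1.0e-5,
    "k_4to11_R2": 1.0e-6,
    "k_rec11_R2": 1.0e-5,
    "k_deg_R2": 2.54e-4,
    # NRP1: slow internalization, high recycling, very slow degradation
    "k_int_N1": 2.69e-4,
    "k_rec4_N1": 8.0e-4,
    "k_4to11_N1": 3.5e-4,
    "k_rec11_N1": 7.0e-4,
    "k_deg_N1": 1.0e-6,
}

#: Published HUVEC surface receptor densities, molecules/cell.
SURFACE_TARGETS: dict[str, float] = {"R1": 1800.0, "R2": 4900.0, "N1": 68000.0}


def reference_parameters(
    coupling: Mapping[str, float] | None = None,
    trafficking: Mapping[str, float] | None = None,
    production: Mapping[str, float] | None = None,
    compartments: Compartments | None = None,
) -> ParameterSet:
    """Assemble a full parameter set from the documented defaults.

    Production defaults to zero; use calibration.solve_production_rates to
    match surface densities.
    """
    values: dict[str, float] = {}
    values.update(REFERENCE_TRAFFICKING)
    if trafficking:
        values.update(trafficking)
    values.update(DEFAULT_COUPLING)
    if coupling:
        values.update(coupling)
    values.update({n: 0.0 for n in PRODUCTION_NAMES})
    if production:
        values.update(production)
    return ParameterSet(values=values, compartments=compartments or Compartments())


def trafficking_vector(params: ParameterSet | Mapping[str, float]) -> list[float]:
    vals = params.values if isinstance(params, ParameterSet) else params
    return [vals[n] for n in TRAFFICKING_NAMES]


def check_bounds(values: Iterable[float], bounds=TRAFFICKING_BOUNDS) -> bool:
    lo, hi = bounds
    return all(lo <= v <= hi for v in values)
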