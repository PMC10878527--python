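"""Rule expansion into a concrete mass-action reaction network.

Three families of rules generate exactly 85 reactions:

* 3 production reactions (zeroth order, surface monomers);
* 40 trafficking/degradation reactions: internalization, Rab4a recycling,
  Rab4a->Rab11a transfer, Rab11a recycling, and degradation, each applied to
  the 8 molecular species (complexes containing VEGFR1 traffic with VEGFR1
  rate constants, the VEGFR2 dimer with VEGFR2 constants, the NRP1 monomer
  with NRP1 constants);
* 7 coupling + 7 uncoupling rules, each instantiated in the 3 live
  compartments (21 + 21 reactions).  Coupling rate constants are base values
  per unit membrane area and are divided by the compartment's area to give
  effective per-cell constants.

Statistical factors follow microscopic site counting under the homodimer
convention (forward rate kc*[M]^2, K_d = kd/kc): NRP1 binds a VEGFR1 dimer at
twice the monomer coupling rate (two free sites) and the singly-occupied dimer
at the base rate; both NRP1s of R1R1N1N1 dissociate (factor 2).  The
VEGFR1-VEGFR1 bond between two distinguishable partners (R1N1 + R1) carries
factor 2, which is the unique choice closing every coupling cycle in detailed
balance given the [M]^2 homodimer convention.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .parameters import Compartments, ParameterSet
from .receptors import (
    COMPLEX_LABELS,
    LIVE_COMPARTMENTS,
    N_COMPLEXES,
    N_LIVE,
    N_STATE,
    STOICHIOMETRY,
    TRAFFICKING_GOVERNOR,
    Compartment,
    species_index,
)

try:  # optional compiled kernels; the numpy path is the reference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


if _HAVE_NUMBA:

    @_njit(cache=True)
    def _rhs_kernel(x, k, order, i1, i2, stoich):
        n_r = k.shape[0]
        rates = np.empty(n_r)
        for r in range(n_r):
            v = k[r]
            if order[r] >= 1:
                v *= x[i1[r]]
            if order[r] == 2:
                v *= x[i2[r]]
            rates[r] = v
        return stoich @ rates

    @_njit(cache=True)
    def _jac_kernel(x, k, order, i1, i2, stoich):
        n_s = stoich.shape[0]
        n_r = k.shape[0]
        out = np.zeros((n_s, n_s))
        for r in range(n_r):
            if order[r] == 0:
                continue
            i = i1[r]
            if order[r] == 1:
                di, j, dj = k[r], -1, 0.0
            else:
                j = i2[r]
                if i == j:
                    di, j, dj = 2.0 * k[r] * x[i], -1, 0.0
                else:
                    di, dj = k[r] * x[j], k[r] * x[i]
            for s in range(n_s):
                c = stoich[s, r]
                if c != 0.0:
                    out[s, i] += c * di
                    if j >= 0:
                        out[s, j] += c * dj
        return out


REACTION_CLASSES = (
    "production",
    "internalization",
    "recycle4",
    "transfer4to11",
    "recycle11",
    "degradation",
    "coupling",
    "uncoupling",
)

TRAFFICKING_CLASS_TO_PARAM = {
    "internalization": "k_int",
    "recycle4": "k_rec4",
    "transfer4to11": "k_4to11",
    "recycle11": "k_rec11",
    "degradation": "k_deg",
}

# (reactants, product, kc name, kd name, forward factor, reverse factor)
COUPLING_RULES = (
    (("R1", "R1"), "R1R1", "kc_R1R1", "kd_R1R1", 1.0, 1.0),
    (("R2", "R2"), "R2R2", "kc_R2R2", "kd_R2R2", 1.0, 1.0),
    (("R1", "N1"), "R1N1", "kc_R1N1", "kd_R1N1", 1.0, 1.0),
    (("R1R1", "N1"), "R1R1N1", "kc_R1N1", "kd_R1N1", 2.0, 1.0),
    (("R1N1", "R1"), "R1R1N1", "kc_R1R1", "kd_R1R1", 2.0, 1.0),
    (("R1R1N1", "N1"), "R1R1N1N1", "kc_R1N1", "kd_R1N1", 1.0, 2.0),
    (("R1N1", "R1N1"), "R1R1N1N1", "kc_R1R1", "kd_R1R1", 1.0, 1.0),
)


@dataclass(frozen=True)
class Reaction:
    rid: int
    klass: str
    compartment: Compartment
    reactants: tuple[int, ...]  # state indices, length 0..2
    products: tuple[int, ...]
    rate_name: str
    factor: float = 1.0
    area_scaled: bool = False  # divide base constant by compartment area

    def reactant_labels(self) -> list[str]:
        from .receptors import state_labels

        labels = state_labels()
        return [labels[i] for i in self.reactants]


class ReactionNetwork:
    """Concrete reaction list with precomputed mass-action machinery."""

    def __init__(self, reactions: list[Reaction], compartments: Compartments):
        compartments.validate()
        self.reactions = reactions
        self.compartments = compartments
        n_r = len(reactions)
        self.stoich = np.zeros((N_STATE, n_r))
        for r in reactions:
            for i in r.reactants:
                self.stoich[i, r.rid] -= 1
            for i in r.products:
                self.stoich[i, r.rid] += 1
        self._order = np.array([len(r.reactants) for r in reactions])
        self._i1 = np.array([r.reactants[0] if r.reactants else 0 for r in reactions])
        self._i2 = np.array(
            [r.reactants[1] if len(r.reactants) == 2 else 0 for r in reactions]
        )
        self._stoich_live = np.ascontiguousarray(self.stoich[:N_LIVE])

    # ---- structure -------------------------------------------------------
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {c: 0 for c in REACTION_CLASSES}
        for r in self.reactions:
            counts[r.klass] += 1
        return counts

    def __len__(self) -> int:
        return len(self.reactions)

    # ---- rate machinery ----------------------------------------------------
    def rate_constants(self, params: ParameterSet) -> np.ndarray:
        """Effective rate constant per reaction (factor and area applied)."""
        k = np.empty(len(self.reactions))
        for r in self.reactions:
            base = params[r.rate_name]
            if r.area_scaled:
                base /= self.compartments.area(r.compartment)
            k[r.rid] = r.factor * base
        return k

    def reaction_rates(self, state: np.ndarray, k: np.ndarray) -> np.ndarray:
        rates = k.copy()
        m1 = self._order >= 1
        rates[m1] *= state[self._i1[m1]]
        m2 = self._order == 2
        rates[m2] *= state[self._i2[m2]]
        return rates

    def rhs(self, state: np.ndarray, k: np.ndarray) -> np.ndarray:
        """Time derivative (per second) of the full 32-entry state."""
        if _HAVE_NUMBA:
            return _rhs_kernel(
                np.asarray(state, float), k, self._order, self._i1, self._i2,
                self.stoich,
            )
        return self.stoich @ self.reaction_rates(state, k)

    def jacobian(self, state: np.ndarray, k: np.ndarray) -> np.ndarray:
        if _HAVE_NUMBA:
            return _jac_kernel(
                np.asarray(state, float), k, self._order, self._i1, self._i2,
                self.stoich,
            )
        n_r = len(self.reactions)
        d = np.zeros((n_r, N_STATE))
        rows = np.arange(n_r)
        m1 = self._order == 1
        d[rows[m1], self._i1[m1]] = k[m1]
        m2 = self._order == 2
        for r in rows[m2]:
            i, j = self._i1[r], self._i2[r]
            if i == j:
                d[r, i] = 2.0 * k[r] * state[i]
            else:
                d[r, i] += k[r] * state[j]
                d[r, j] += k[r] * state[i]
        return self.stoich @ d

    # Reduced system over the 24 live entries (degraded pools are pure sinks
    # and never feed back, so they can be dropped for steady-state work).
    def rhs_live(self, live: np.ndarray, k: np.ndarray) -> np.ndarray:
        full = np.zeros(N_STATE)
        full[:N_LIVE] = live
        if _HAVE_NUMBA:
            return _rhs_kernel(full, k, self._order, self._i1, self._i2,
                               self._stoich_live)
        return self._stoich_live @ self.reaction_rates(full, k)

    def jacobian_live(self, live: np.ndarray, k: np.ndarray) -> np.ndarray:
        full = np.zeros(N_STATE)
        full[:N_LIVE] = live
        return self.jacobian(full, k)[:N_LIVE, :N_LIVE]

    # ---- export ------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        from .receptors import state_labels

        labels = state_labels()
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                [
                    "reaction_id",
                    "class",
                    "compartment",
                    "reactants",
                    "products",
                    "rate_constant_name",
                    "factor",
                    "area_scaled",
                ]
            )
            for r in self.reactions:
                w.writerow(
                    [
                        r.rid,
                        r.klass,
                        r.compartment.value,
                        "+".join(labels[i] for i in r.reactants),
                        "+".join(labels[i] for i in r.products),
                        r.rate_name,
                        r.factor,
                        int(r.area_scaled),
                    ]
                )


def expand_reactions(
    compartments: Compartments | None = None,
    coupling_enabled: bool = True,
) -> ReactionNetwork:
    """Expand the production/trafficking/coupling rules into 85 reactions.

    With ``coupling_enabled=False`` only the 43 production and trafficking
    reactions are generated (the monomer-only model).
    """
    compartments = compartments or Compartments()
    compartments.validate()
    reactions: list[Reaction] = []

    def add(klass, comp, reactants, products, rate_name, factor=1.0, area=False):
        reactions.append(
            Reaction(
                rid=len(reactions),
                klass=klass,
                compartment=comp,
                reactants=tuple(reactants),
                products=tuple(products),
                rate_name=rate_name,
                factor=factor,
                area_scaled=area,
            )
        )

    # production: zeroth order into surface monomers
    for rec in ("R1", "R2", "N1"):
        add(
            "production",
            Compartment.SURFACE,
            (),
            (species_index(rec, Compartment.SURFACE),),
            f"k_prod_{rec}",
        )

    # trafficking + degradation: 5 processes x 8 complexes
    moves = (
        ("internalization", Compartment.SURFACE, Compartment.RAB4),
        ("recycle4", Compartment.RAB4, Compartment.SURFACE),
        ("transfer4to11", Compartment.RAB4, Compartment.RAB11),
        ("recycle11", Compartment.RAB11, Compartment.SURFACE),
        ("degradation", Compartment.RAB4, Compartment.DEGRADED),
    )
    for klass, src, dst in moves:
        for ci, label in enumerate(COMPLEX_LABELS):
            governor = TRAFFICKING_GOVERNOR[ci]
            add(
                klass,
                src,
                (species_index(label, src),),
                (species_index(label, dst),),
                f"{TRAFFICKING_CLASS_TO_PARAM[klass]}_{governor}",
            )

    if coupling_enabled:
        for comp in LIVE_COMPARTMENTS:
            for (a, b), prod, kc, kd, ffwd, frev in COUPLING_RULES:
                add(
                    "coupling",
                    comp,
                    (species_index(a, comp), species_index(b, comp)),
                    (species_index(prod, comp),),
                    kc,
                    factor=ffwd,
                    area=True,
                )
        for comp in LIVE_COMPARTMENTS:
            for (a, b), prod, kc, kd, ffwd, frev in COUPLING_RULES:
                add(
                    "uncoupling",
                    comp,
                    (species_index(prod, comp),),
                    (species_index(a, comp), species_index(b, comp)),
                    kd,
                    factor=frev,
                )

    return ReactionNetwork(reactions, compartments)


def receptor_totals(state: np.ndarray, include_degraded: bool = True) -> np.ndarray:
    """Stoichiometry-weighted receptor counts (R1, R2, N1) summed over
    compartments; used by conservation checks."""
    n_comp = 4 if include_degraded else 3
    per_complex = state[: n_comp * N_COMPLEXES].reshape(n_comp, N_COMPLEXES).sum(axis=0)
    return STOICHIOMETRY @ per_complex
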