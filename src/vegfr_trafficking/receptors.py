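"""Molecular state space: receptors, complexes, compartments.

The model tracks three receptor kinds (VEGFR1, VEGFR2, NRP1) that form eight
ligand-independent molecular species: the three monomers, the VEGFR1 and
VEGFR2 homodimers, and three VEGFR1-NRP1 complexes (R1-N1, R1-R1-N1,
R1-R1-N1-N1).  VEGFR2 does not couple to NRP1 or VEGFR1 in the absence of
ligand.  Each species lives in three compartments (cell surface, Rab4a/5a
early endosomes, Rab11a recycling endosomes) and has one cumulative degraded
pool, giving a 32-entry state vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np


class ReceptorKind(str, Enum):
    R1 = "R1"  # VEGFR1 (membrane-integral mFlt1)
    R2 = "R2"  # VEGFR2
    N1 = "N1"  # Neuropilin-1


#: Canonical complex order; all state vectors and I/O use this order.
COMPLEX_LABELS: tuple[str, ...] = (
    "R1", "R2", "N1", "R1R1", "R2R2", "R1N1", "R1R1N1", "R1R1N1N1",
)

#: Copies of each receptor kind in each complex (rows: R1, R2, N1).
STOICHIOMETRY: np.ndarray = np.array(
    [
        # R1  R2  N1 R1R1 R2R2 R1N1 R1R1N1 R1R1N1N1
        [1, 0, 0, 2, 0, 1, 2, 2],   # R1 copies
        [0, 1, 0, 0, 2, 0, 0, 0],   # R2 copies
        [0, 0, 1, 0, 0, 1, 1, 2],   # N1 copies
    ],
    dtype=float,
)

#: Receptor kind whose trafficking rate constants govern each complex.
#: Any complex containing VEGFR1 traffics with VEGFR1 parameters; the VEGFR2
#: homodimer with VEGFR2 parameters; the NRP1 monomer with NRP1 parameters.
TRAFFICKING_GOVERNOR: tuple[str, ...] = (
    "R1", "R2", "N1", "R1", "R2", "R1", "R1", "R1",
)

MONOMER_LABELS: tuple[str, ...] = ("R1", "R2", "N1")


class Compartment(str, Enum):
    SURFACE = "surface"
    RAB4 = "rab4"      # Rab4a/5a early endosome
    RAB11 = "rab11"    # Rab11a recycling endosome
    DEGRADED = "degraded"  # cumulative sink, never a reaction source


LIVE_COMPARTMENTS: tuple[Compartment, ...] = (
    Compartment.SURFACE, Compartment.RAB4, Compartment.RAB11,
)

N_COMPLEXES = len(COMPLEX_LABELS)
N_STATE = N_COMPLEXES * 4  # 3 live compartments + degraded pools = 32
N_LIVE = N_COMPLEXES * 3   # 24 live entries


@dataclass(frozen=True)
class SpeciesEntry:
    """One state-vector entry: a complex in a compartment."""

    index: int
    complex_label: str
    compartment: Compartment

    @property
    def label(self) -> str:
        return f"{self.complex_label}@{self.compartment.value}"


def enumerate_species(monomers_only: bool = False) -> list[SpeciesEntry]:
    """Canonical ordered state entries, compartment-major.

    With the coupling rules disabled (``monomers_only=True``) only the three
    monomer species exist, giving 12 entries; the full model has 32.
    The returned ``index`` always refers to the full 32-entry layout.
    """
    labels = MONOMER_LABELS if monomers_only else COMPLEX_LABELS
    entries = []
    for ci, comp in enumerate((*LIVE_COMPARTMENTS, Compartment.DEGRADED)):
        for label in labels:
            j = COMPLEX_LABELS.index(label)
            entries.append(SpeciesEntry(ci * N_COMPLEXES + j, label, comp))
    return entries


def species_index(complex_label: str, compartment: Compartment | str) -> int:
    """Index of a complex-in-compartment in the 32-entry state vector."""
    comp = Compartment(compartment)
    order = (*LIVE_COMPARTMENTS, Compartment.DEGRADED)
    return order.index(comp) * N_COMPLEXES + COMPLEX_LABELS.index(complex_label)


def state_labels() -> list[str]:
    return [e.label for e in enumerate_species()]
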