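"""Bead species of the coarse-grained model.

Eight DPD bead species: the charged polyelectrolyte monomers A+ and A-,
the neutral water-soluble block monomer B, the hydrophobic porphyrin ring
bead P and its charged peripheral group Pq+, monovalent counterions CI+
and CI-, and solvent S.  Every bead carries unit mass and a valence in
units of the elementary charge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Integer species codes, used throughout the arrays of the engine.
A_PLUS = 0
A_MINUS = 1
B = 2
P = 3
PQ = 4
CI_PLUS = 5
CI_MINUS = 6
S = 7

N_SPECIES = 8

LABELS = ("A+", "A-", "B", "P", "Pq+", "CI+", "CI-", "S")

#: valence of each species, in units of e
VALENCES = np.array([+1, -1, 0, 0, +1, +1, -1, 0], dtype=np.int8)

#: all beads have unit (reduced) mass
MASSES = np.ones(N_SPECIES)

LABEL_TO_CODE = {lab: i for i, lab in enumerate(LABELS)}

#: species whose beads form the dense associate core (used by the
#: cluster criterion and by radial-profile centering)
CORE_SPECIES = (A_PLUS, A_MINUS, P, PQ)

#: species belonging to the porphyrin unit
PORPHYRIN_SPECIES = (P, PQ)


@dataclass(frozen=True)
class SpeciesTable:
    """The fixed table of the eight bead species with their valences.

    The default instance is the model's species set; it is exposed as a
    type mainly so configurations can echo it and tests can assert the
    charge assignment.
    """

    labels: tuple = LABELS
    valences: tuple = tuple(int(v) for v in VALENCES)
    masses: tuple = tuple(float(m) for m in MASSES)

    def __post_init__(self):
        if len(self.labels) != 8:
            raise ValueError("species table must contain exactly eight species")
        if any(m != 1.0 for m in self.masses):
            raise ValueError("all bead masses are 1 in reduced units")
        if any(v not in (-1, 0, 1) for v in self.valences):
            raise ValueError("valences are monovalent: -1, 0 or +1")

    def valence(self, label: str) -> int:
        return self.valences[LABEL_TO_CODE[label]]


def valence_of(species_codes: np.ndarray) -> np.ndarray:
    """Per-bead valence array for an array of species codes."""
    return VALENCES[np.asarray(species_codes, dtype=np.int64)]
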