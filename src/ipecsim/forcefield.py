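"""Soft-repulsion force field: the chi -> a_ij map and the interaction table.

The conservative DPD repulsion amplitude between like beads at reference
density rho = 3 is a_ii = 25 (Groot--Warren compressibility matching), and
unlike-pair amplitudes follow the linear map from the Flory interaction
parameter,

    a_ij = 25 + 3.27 chi,

so chi = 0 (athermal), 0.5 (theta solvent) and 4.5 (non-solvent) give
a_ij = 25, 26.6 and 39.7.  The default table encodes the calibrated model:
hydrophobic polyelectrolyte backbones (a_AS = 35), a marginally soluble
neutral block (a_BS = 26), mutually attractive porphyrin rings
(a_PP = 18 < 25), poorly soluble porphyrin beads (a_PS = a_PqS = 39) and a
short-range ion--backbone attraction (a_ACI = 27).  Signed variants of A
and CI share the unsigned entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .species import (
    A_MINUS,
    A_PLUS,
    B,
    CI_MINUS,
    CI_PLUS,
    LABEL_TO_CODE,
    N_SPECIES,
    P,
    PQ,
    S,
)

#: slope of the Flory-chi to repulsion map at reference density rho = 3
CHI_SLOPE = 3.27
#: like-pair repulsion at reference density rho = 3
A_LIKE = 25.0


def chi_to_repulsion(chi: float) -> float:
    """Map a Flory chi parameter to a DPD repulsion amplitude a_ij.

    ``a_ij = 25 + 3.27 chi`` at the reference bead density rho = 3.
    Total on any finite ``chi``.
    """
    chi = float(chi)
    if not np.isfinite(chi):
        raise ValueError("chi must be finite")
    return A_LIKE + CHI_SLOPE * chi


def repulsion_to_chi(a_ij: float) -> float:
    """Inverse of :func:`chi_to_repulsion`."""
    return (float(a_ij) - A_LIKE) / CHI_SLOPE


# The six interaction classes of the published table; signed species share
# their unsigned class.
_CLASS_OF = {
    A_PLUS: "A",
    A_MINUS: "A",
    B: "B",
    P: "P",
    PQ: "Pq",
    CI_PLUS: "CI",
    CI_MINUS: "CI",
    S: "S",
}

_DEFAULT_CLASS_TABLE = {
    ("A", "A"): 25.0,
    ("B", "A"): 35.0,
    ("B", "B"): 25.0,
    ("P", "A"): 25.0,
    ("P", "B"): 35.0,
    ("P", "P"): 18.0,
    ("Pq", "A"): 25.0,
    ("Pq", "B"): 35.0,
    ("Pq", "P"): 25.0,
    ("Pq", "Pq"): 25.0,
    ("CI", "A"): 27.0,
    ("CI", "B"): 26.0,
    ("CI", "P"): 39.0,
    ("CI", "Pq"): 39.0,
    ("CI", "CI"): 25.0,
    ("S", "A"): 35.0,
    ("S", "B"): 26.0,
    ("S", "P"): 39.0,
    ("S", "Pq"): 39.0,
    ("S", "CI"): 25.0,
    ("S", "S"): 25.0,
}


@dataclass
class InteractionTable:
    """Symmetric matrix of soft-repulsion amplitudes a_ij (reduced units).

    ``matrix`` is indexed by the integer species codes of
    :mod:`ipecsim.species`; it is always kept symmetric and positive.
    """

    matrix: np.ndarray = field(
        default_factory=lambda: np.full((N_SPECIES, N_SPECIES), A_LIKE)
    )

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (N_SPECIES, N_SPECIES):
            raise ValueError("interaction matrix must be 8x8")
        if not np.allclose(m, m.T):
            raise ValueError("interaction matrix must be symmetric")
        if np.any(m <= 0):
            raise ValueError("repulsion amplitudes must be positive")
        self.matrix = m

    def lookup(self, i, j) -> float:
        """Repulsion amplitude for a species pair (labels or codes)."""
        ci = LABEL_TO_CODE[i] if isinstance(i, str) else int(i)
        cj = LABEL_TO_CODE[j] if isinstance(j, str) else int(j)
        return float(self.matrix[ci, cj])

    def set_pair(self, i, j, value: float) -> None:
        ci = LABEL_TO_CODE[i] if isinstance(i, str) else int(i)
        cj = LABEL_TO_CODE[j] if isinstance(j, str) else int(j)
        if value <= 0:
            raise ValueError("repulsion amplitudes must be positive")
        self.matrix[ci, cj] = self.matrix[cj, ci] = float(value)


def default_interaction_table() -> InteractionTable:
    """The calibrated interaction table of the model (see module docstring)."""
    m = np.empty((N_SPECIES, N_SPECIES))
    for i in range(N_SPECIES):
        for j in range(N_SPECIES):
            key = (_CLASS_OF[i], _CLASS_OF[j])
            if key not in _DEFAULT_CLASS_TABLE:
                key = (key[1], key[0])
            m[i, j] = _DEFAULT_CLASS_TABLE[key]
    return InteractionTable(matrix=m)
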