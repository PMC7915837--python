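"""Molecular templates: diblock polyelectrolytes and the rigid porphyrin unit.

The co-assembling copolymer is a linear A_nA B_nB diblock whose A block
carries one unit charge per bead (positive or negative).  The porphyrin
model is a rigid, planar unit: four hydrophobic ring beads (P) at the
corners of a square, each associated with one positively charged
peripheral bead (Pq+) displaced outward along the square's diagonal, for
a net charge of +4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .species import A_MINUS, A_PLUS, B, P, PQ, VALENCES

#: default porphyrin square edge and Pq arm length, in r_c (bond-length scale)
PORPHYRIN_EDGE = 0.7
PORPHYRIN_ARM = 0.7


@dataclass(frozen=True)
class MoleculeTemplate:
    """Species sequence, bonds and (for rigid units) reference geometry."""

    name: str
    species: np.ndarray                       # (n,) int8 species codes
    bonds: np.ndarray                         # (m,2) intra-molecule bead indices
    rigid: bool = False
    reference_coords: np.ndarray | None = None  # (n,3), COM at origin, rigid only

    @property
    def n_beads(self) -> int:
        return len(self.species)

    @property
    def net_charge(self) -> int:
        return int(VALENCES[self.species].sum())

    def __post_init__(self):
        if self.rigid:
            x = self.reference_coords
            if x is None or x.shape != (self.n_beads, 3):
                raise ValueError("rigid template requires reference coordinates")


def make_diblock(n_a: int, n_b: int, sign: int) -> MoleculeTemplate:
    """Linear diblock with ``n_a`` charged A beads followed by ``n_b`` B beads.

    ``sign = +1`` gives an A+ block (net charge ``+n_a``), ``sign = -1``
    an A- block.  Consecutive beads are joined by harmonic bonds.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("block lengths must be positive")
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 or -1")
    a_species = A_PLUS if sign > 0 else A_MINUS
    species = np.array([a_species] * n_a + [B] * n_b, dtype=np.int8)
    n = n_a + n_b
    bonds = np.column_stack([np.arange(n - 1), np.arange(1, n)]).astype(np.int64)
    name = f"A{n_a}{'+' if sign > 0 else '-'}B{n_b}"
    return MoleculeTemplate(name=name, species=species, bonds=bonds)


def make_porphyrin(
    edge: float = PORPHYRIN_EDGE, arm: float = PORPHYRIN_ARM
) -> MoleculeTemplate:
    """Rigid planar porphyrin: 4 P corner beads + 4 peripheral Pq+ beads.

    The P beads sit at the corners of a square of side ``edge``; each Pq+
    bead is displaced outward along the diagonal by ``arm`` in the same
    plane.  The center of mass of the reference coordinates is the origin
    and the unit is integrated as a rigid body.
    """
    if edge <= 0:
        raise ValueError("edge must be positive")
    if arm < 0:
        raise ValueError("arm must be non-negative")
    h = edge / 2.0
    corners = np.array(
        [[h, h, 0.0], [-h, h, 0.0], [-h, -h, 0.0], [h, -h, 0.0]]
    )
    diag = corners / np.linalg.norm(corners, axis=1, keepdims=True)
    pq = corners + arm * diag
    coords = np.vstack([corners, pq])
    coords -= coords.mean(axis=0)
    species = np.array([P] * 4 + [PQ] * 4, dtype=np.int8)
    bonds = np.empty((0, 2), dtype=np.int64)  # rigid: geometry fixes the unit
    return MoleculeTemplate(
        name="P+", species=species, bonds=bonds, rigid=True, reference_coords=coords
    )
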