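"""System topology and state containers.

``Topology`` stores per-bead species, bonds, molecule assignment and the
rigid-body layout; ``SystemState`` adds positions/velocities in a periodic
cubic box.  Molecules are the chains and porphyrin units; counterions and
solvent beads carry molecule id -1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .species import valence_of

# molecule kinds
CHAIN_PLUS = 0
CHAIN_MINUS = 1
PORPHYRIN = 2

MOL_KIND_NAMES = {CHAIN_PLUS: "chain+", CHAIN_MINUS: "chain-", PORPHYRIN: "P+"}


@dataclass
class Topology:
    species: np.ndarray                 # (N,) int8
    bonds: np.ndarray                   # (M,2) int64 global bead indices
    mol_id: np.ndarray                  # (N,) int64, -1 for solvent/ions
    mol_kind: np.ndarray                # (n_mol,) int8
    rigid_start: np.ndarray             # (n_rigid,) int64 first bead of each body
    rigid_size: np.ndarray              # (n_rigid,) int64 bead count of each body
    rigid_reference: np.ndarray | None = None  # (body_size,3) shared body frame

    @property
    def n_beads(self) -> int:
        return len(self.species)

    @property
    def n_molecules(self) -> int:
        return len(self.mol_kind)

    @property
    def n_rigid(self) -> int:
        return len(self.rigid_start)

    def valences(self) -> np.ndarray:
        return valence_of(self.species)

    def free_mask(self) -> np.ndarray:
        """Boolean mask of beads not belonging to a rigid body."""
        mask = np.ones(self.n_beads, dtype=bool)
        for s, n in zip(self.rigid_start, self.rigid_size):
            mask[s : s + n] = False
        return mask

    def molecule_charges(self) -> np.ndarray:
        """Net charge of each molecule."""
        q = np.zeros(self.n_molecules, dtype=np.int64)
        v = self.valences()
        sel = self.mol_id >= 0
        np.add.at(q, self.mol_id[sel], v[sel])
        return q


@dataclass
class SystemState:
    """Positions, velocities and topology in a periodic cubic box of edge L."""

    pos: np.ndarray                     # (N,3) float64
    vel: np.ndarray                     # (N,3) float64
    box: float
    topology: Topology

    @property
    def n_beads(self) -> int:
        return len(self.pos)

    def wrapped_positions(self) -> np.ndarray:
        return np.mod(self.pos, self.box)

    def wrap(self) -> None:
        np.mod(self.pos, self.box, out=self.pos)

    def total_charge(self) -> int:
        return int(self.topology.valences().sum())

    def check_invariants(self, rho: float | None = None) -> None:
        """Assert electroneutrality and, if given, the density fill rule."""
        if self.total_charge() != 0:
            raise ValueError(f"system not electroneutral: q={self.total_charge()}")
        if rho is not None:
            expect = int(round(rho * self.box**3))
            if self.n_beads != expect:
                raise ValueError(
                    f"bead count {self.n_beads} != round(rho L^3) = {expect}"
                )

    def copy(self) -> "SystemState":
        return SystemState(
            pos=self.pos.copy(),
            vel=self.vel.copy(),
            box=self.box,
            topology=self.topology,
        )


def minimum_image(dr: np.ndarray, box: float) -> np.ndarray:
    """Minimum-image displacement(s) for a cubic box."""
    return dr - box * np.round(dr / box)
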