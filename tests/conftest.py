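"""Shared fixtures and independent reference (oracle) implementations."""

from __future__ import annotations

import numpy as np
import pytest

import ipecsim as ip
from ipecsim.forces import _pair_noise


@pytest.fixture(scope="session")
def table():
    return ip.default_interaction_table()


@pytest.fixture(scope="session")
def charge_model():
    return ip.ChargeModel()


@pytest.fixture(scope="session")
def solvent_state_small():
    """648-bead pure solvent box."""
    return ip.build_initial_state(ip.ScenarioRecipe(L=6, seed=100))


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def minimum_image(d, box):
    return d - box * np.round(d / box)


def brute_force_dpd(pos, vel, species, amat, box, gamma, sigma, dt, seed,
                    step):
    """O(N^2) python reference for the full DPD triple force, sharing the
    counter-based pair noise with the production kernel."""
    n = len(pos)
    forces = np.zeros((n, 3))
    for i in range(n):
        for j in range(i + 1, n):
            d = minimum_image(pos[i] - pos[j], box)
            r2 = d @ d
            if r2 >= 1.0 or r2 == 0.0:
                continue
            r = np.sqrt(r2)
            u = d / r
            w = 1.0 - r
            f = amat[species[i], species[j]] * w
            f -= gamma * w * w * (u @ (vel[i] - vel[j]))
            if sigma > 0:
                f += sigma * w * _pair_noise(seed, step, i, j) / np.sqrt(dt)
            forces[i] += f * u
            forces[j] -= f * u
    return forces


def union_find_clusters(state, d_cut, member_species):
    """Brute-force single-linkage over the all-pairs molecule contact graph."""
    topo = state.topology
    n_mol = topo.n_molecules
    parent = list(range(n_mol))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    sel = np.isin(topo.species, list(member_species)) & (topo.mol_id >= 0)
    idx = np.flatnonzero(sel)
    pos = state.wrapped_positions()[idx]
    mols = topo.mol_id[idx]
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            if mols[a] == mols[b]:
                continue
            d = minimum_image(pos[a] - pos[b], state.box)
            if d @ d <= d_cut * d_cut:
                union(mols[a], mols[b])
    return np.array([find(m) for m in range(n_mol)])


def same_partition(labels_a, labels_b):
    """True when two labelings induce the same partition."""
    seen = {}
    for a, b in zip(labels_a, labels_b):
        key = a
        if key in seen:
            if seen[key] != b:
                return False
        else:
            seen[key] = b
    return len(set(seen.values())) == len(seen)
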