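"""Initial-configuration builders.

Builds every starting state the study needs: randomly dispersed mixtures,
the pre-aggregated single associate used to probe equilibration from the
opposite direction, porphyrin insertion into the bulk solvent of an
equilibrated polymer system, and synthetic cluster fixtures with known
ground-truth labels for testing the aggregate analysis.

All builders obey two hard rules: the box is filled with solvent to
exactly ``round(rho L^3)`` beads, and counterions are added by the
neutrality rule (one CI- per A+ bead, one CI+ per A- bead, one CI- per
Pq+ bead, salt in CI+/CI- pairs), so the total charge is always zero.
"""

from __future__ import annotations

import numpy as np

from .recipes import ScenarioRecipe
from .species import A_MINUS, A_PLUS, B, CI_MINUS, CI_PLUS, P, PQ, S
from .templates import MoleculeTemplate, make_diblock, make_porphyrin
from .topology import (
    CHAIN_MINUS,
    CHAIN_PLUS,
    PORPHYRIN,
    SystemState,
    Topology,
)

#: bond-length scale used for initial chain conformations (r_c units)
BOND_STEP = 0.7
#: minimum clearance between inserted porphyrins and polymer beads (r_c)
INSERT_CLEARANCE = 1.0


def _random_unit(rng, n=1):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _chain_walk(rng, start, n, step=BOND_STEP):
    """Freely jointed random walk of n beads from `start` (unwrapped)."""
    pos = np.empty((n, 3))
    pos[0] = start
    for i in range(1, n):
        pos[i] = pos[i - 1] + step * _random_unit(rng)[0]
    return pos


class _Assembler:
    """Accumulates beads/molecules and finalizes a SystemState."""

    def __init__(self, recipe: ScenarioRecipe):
        recipe.validate()
        self.recipe = recipe
        self.pos_blocks: list[np.ndarray] = []
        self.species_blocks: list[np.ndarray] = []
        self.bonds: list[np.ndarray] = []
        self.mol_id_blocks: list[np.ndarray] = []
        self.mol_kind: list[int] = []
        self.rigid_start: list[int] = []
        self.rigid_size: list[int] = []
        self.rigid_reference = None
        self.n_beads = 0

    def add_molecule(self, template: MoleculeTemplate, coords, kind: int):
        mol = len(self.mol_kind)
        self.mol_kind.append(kind)
        if template.rigid:
            self.rigid_start.append(self.n_beads)
            self.rigid_size.append(template.n_beads)
            self.rigid_reference = template.reference_coords
        if len(template.bonds):
            self.bonds.append(template.bonds + self.n_beads)
        self.pos_blocks.append(np.asarray(coords, dtype=float))
        self.species_blocks.append(template.species.astype(np.int8))
        self.mol_id_blocks.append(np.full(template.n_beads, mol, dtype=np.int64))
        self.n_beads += template.n_beads

    def add_loose(self, species_code: int, coords):
        coords = np.asarray(coords, dtype=float)
        n = len(coords)
        if n == 0:
            return
        self.pos_blocks.append(coords)
        self.species_blocks.append(np.full(n, species_code, dtype=np.int8))
        self.mol_id_blocks.append(np.full(n, -1, dtype=np.int64))
        self.n_beads += n

    def finalize(self, rng) -> SystemState:
        r = self.recipe
        pos = (
            np.vstack(self.pos_blocks) if self.pos_blocks else np.empty((0, 3))
        )
        species = (
            np.concatenate(self.species_blocks)
            if self.species_blocks
            else np.empty(0, dtype=np.int8)
        )
        bonds = (
            np.vstack(self.bonds) if self.bonds else np.empty((0, 2), np.int64)
        )
        mol_id = (
            np.concatenate(self.mol_id_blocks)
            if self.mol_id_blocks
            else np.empty(0, dtype=np.int64)
        )
        topo = Topology(
            species=species,
            bonds=bonds,
            mol_id=mol_id,
            mol_kind=np.array(self.mol_kind, dtype=np.int8),
            rigid_start=np.array(self.rigid_start, dtype=np.int64),
            rigid_size=np.array(self.rigid_size, dtype=np.int64),
            rigid_reference=self.rigid_reference,
        )
        state = SystemState(
            pos=np.mod(pos, r.L), vel=np.zeros_like(pos), box=r.L, topology=topo
        )
        assign_maxwell_velocities(state, rng, kT=1.0)
        state.check_invariants(rho=r.rho)
        return state


def assign_maxwell_velocities(state: SystemState, rng, kT: float = 1.0) -> None:
    """Draw bead velocities at temperature kT, remove net momentum, and
    project rigid-body beads onto exact rigid motion (COM velocity plus
    angular velocity about the COM)."""
    n = state.n_beads
    if n == 0:
        return
    v = rng.normal(scale=np.sqrt(kT), size=(n, 3))
    v -= v.mean(axis=0)
    topo = state.topology
    for s, m in zip(topo.rigid_start, topo.rigid_size):
        sl = slice(s, s + m)
        x = state.pos[sl]
        com = x.mean(axis=0)
        d = x - com
        vcom = v[sl].mean(axis=0)
        ang_mom = np.cross(d, v[sl] - vcom).sum(axis=0)
        inertia = np.einsum("ni,nj->ij", d, d)
        inertia = np.trace(inertia) * np.eye(3) - inertia
        omega = np.linalg.solve(inertia, ang_mom)
        v[sl] = vcom + np.cross(omega, d)
    v -= v.mean(axis=0)
    state.vel[:] = v


def _add_counterions_and_solvent(asm: _Assembler, rng) -> None:
    r = asm.recipe
    L = r.L
    asm.add_loose(CI_PLUS, rng.uniform(0, L, size=(r.n_ci_plus, 3)))
    asm.add_loose(CI_MINUS, rng.uniform(0, L, size=(r.n_ci_minus, 3)))
    asm.add_loose(S, rng.uniform(0, L, size=(r.n_solvent, 3)))


def assemble_box(recipe: ScenarioRecipe) -> SystemState:
    """Random initial state: chains as freely jointed walks, porphyrins at
    random positions/orientations, counterions by the neutrality rule,
    solvent filling to round(rho L^3).  Deterministic given the seed."""
    rng = np.random.default_rng(recipe.seed)
    asm = _Assembler(recipe)
    L = recipe.L
    t_plus = make_diblock(recipe.n_a, recipe.n_b, +1)
    t_minus = make_diblock(recipe.n_a, recipe.n_b, -1)
    t_porph = make_porphyrin(recipe.porphyrin_edge, recipe.porphyrin_arm)
    for _ in range(recipe.n_plus):
        start = rng.uniform(0, L, size=3)
        asm.add_molecule(t_plus, _chain_walk(rng, start, t_plus.n_beads), CHAIN_PLUS)
    for _ in range(recipe.n_minus):
        start = rng.uniform(0, L, size=3)
        asm.add_molecule(t_minus, _chain_walk(rng, start, t_minus.n_beads), CHAIN_MINUS)
    for _ in range(recipe.n_porphyrin):
        com = rng.uniform(0, L, size=3)
        rot = _random_rotation(rng)
        coords = com + t_porph.reference_coords @ rot.T
        asm.add_molecule(t_porph, coords, PORPHYRIN)
    _add_counterions_and_solvent(asm, rng)
    return asm.finalize(rng)


def assemble_preaggregated(recipe: ScenarioRecipe) -> SystemState:
    """One large core-shell associate containing all chains.

    All A beads are packed inside a central sphere whose radius makes the
    mean A density equal rho; each chain's A block runs radially outward
    (radii spaced uniformly in volume so the sphere is filled evenly) and
    its B block continues radially beyond the core sphere, so at step 0 the
    core sphere holds every A bead and no B bead and the associate is a
    single cluster under the contact criterion.
    """
    if recipe.n_plus + recipe.n_minus == 0:
        raise ValueError("preaggregated state requires at least one chain")
    rng = np.random.default_rng(recipe.seed)
    L = recipe.L
    center = np.full(3, L / 2.0)
    n_chains = recipe.n_plus + recipe.n_minus
    n_a, n_b = recipe.n_a, recipe.n_b
    r_core = (3.0 * n_chains * n_a / (4.0 * np.pi * recipe.rho)) ** (1.0 / 3.0)
    # B spacing compressed if the box cannot hold a fully extended brush
    b_step = min(BOND_STEP, max(0.1, (L / 2.0 - r_core - 0.5) / n_b))
    step = 0.5
    for attempt in range(50):
        chains = _pack_core_chains(rng, center, r_core, n_chains, n_a, step)
        if _chains_connected(chains, d_cut=0.7):
            break
    else:
        raise RuntimeError("could not pack a singly connected core")
    asm = _Assembler(recipe)
    t_plus = make_diblock(n_a, n_b, +1)
    t_minus = make_diblock(n_a, n_b, -1)
    kinds = [CHAIN_PLUS] * recipe.n_plus + [CHAIN_MINUS] * recipe.n_minus
    templates = [t_plus] * recipe.n_plus + [t_minus] * recipe.n_minus
    for a_coords, tmpl, kind in zip(chains, templates, kinds):
        coords = np.empty((n_a + n_b, 3))
        coords[:n_a] = a_coords
        # B block extends radially outward from the core sphere
        u_out = a_coords[-1] - center
        nrm = np.linalg.norm(u_out)
        u_out = u_out / nrm if nrm > 1e-9 else _random_unit(rng)[0]
        perp = np.eye(3) - np.outer(u_out, u_out)
        radii_b = r_core + b_step * (np.arange(n_b) + 1)
        jitter = rng.normal(scale=0.15, size=(n_b, 3)) @ perp
        coords[n_a:] = center + radii_b[:, None] * u_out + jitter
        asm.add_molecule(tmpl, coords, kind)
    t_porph = make_porphyrin(recipe.porphyrin_edge, recipe.porphyrin_arm)
    for _ in range(recipe.n_porphyrin):
        com = rng.uniform(0, L, size=3)
        rot = _random_rotation(rng)
        asm.add_molecule(t_porph, com + t_porph.reference_coords @ rot.T, PORPHYRIN)
    _add_counterions_and_solvent(asm, rng)
    return asm.finalize(rng)


def _pack_core_chains(rng, center, r_core, n_chains, n_a, step):
    """A-block conformations confined to the core sphere: each chain is a
    random walk (outward-biased toward its end so the last A bead sits near
    the surface), started next to an already placed bead so the packed core
    is a single contact cluster."""
    placed: list[np.ndarray] = []
    chains = []
    for _ in range(n_chains):
        coords = np.empty((n_a, 3))
        if placed:
            anchor = placed[rng.integers(len(placed))]
            coords[0] = anchor + 0.5 * _random_unit(rng)[0]
            if np.linalg.norm(coords[0] - center) > r_core:
                coords[0] = anchor
        else:
            coords[0] = center + 0.2 * r_core * _random_unit(rng)[0]
        for j in range(1, n_a):
            radial = coords[j - 1] - center
            nrm = np.linalg.norm(radial)
            radial = radial / nrm if nrm > 1e-9 else _random_unit(rng)[0]
            bias = 2.0 * (j / n_a) ** 2
            for _ in range(60):
                d = rng.normal(size=3) + bias * radial
                d *= step / np.linalg.norm(d)
                cand = coords[j - 1] + d
                if np.linalg.norm(cand - center) <= r_core:
                    break
            else:
                cand = coords[j - 1] - step * radial
            coords[j] = cand
        placed.extend(coords)
        chains.append(coords)
    return chains


def _chains_connected(chains, d_cut: float) -> bool:
    """True when the chains' A beads form one single-linkage cluster."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial import cKDTree

    pts = np.vstack(chains)
    owner = np.concatenate(
        [np.full(len(c), k) for k, c in enumerate(chains)]
    )
    pairs = cKDTree(pts).query_pairs(d_cut, output_type="ndarray")
    if len(chains) == 1:
        return True
    mi = owner[pairs[:, 0]]
    mj = owner[pairs[:, 1]]
    sel = mi != mj
    adj = coo_matrix(
        (np.ones(sel.sum()), (mi[sel], mj[sel])),
        shape=(len(chains), len(chains)),
    )
    n_comp, _ = connected_components(adj, directed=False)
    return n_comp == 1


def build_initial_state(recipe: ScenarioRecipe) -> SystemState:
    """Dispatch on ``recipe.mode``."""
    if recipe.mode == "preaggregated":
        return assemble_preaggregated(recipe)
    return assemble_box(recipe)


def insert_porphyrins_bulk(
    state: SystemState,
    n: int,
    seed: int,
    clearance: float = INSERT_CLEARANCE,
    edge: float | None = None,
    arm: float | None = None,
    max_tries: int = 2000,
) -> SystemState:
    """Insert ``n`` porphyrins (plus their 4 CI- each) into the bulk solvent.

    Each unit is placed at a random position/orientation with every bead at
    least ``clearance`` from any polymer bead (A, B, P, Pq); each insertion
    swaps out 12 solvent beads so the total bead count is unchanged and the
    system stays neutral.  Returns a new state; the input is not modified.
    """
    from scipy.spatial import cKDTree

    if n == 0:
        return state.copy()
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    topo = state.topology
    kwargs = {}
    if edge is not None:
        kwargs["edge"] = edge
    if arm is not None:
        kwargs["arm"] = arm
    t_porph = make_porphyrin(**kwargs)

    solvent_idx = np.flatnonzero(topo.species == S)
    if len(solvent_idx) < 12 * n:
        raise ValueError(
            f"need {12 * n} solvent beads to swap, have {len(solvent_idx)}"
        )
    polymer_mask = np.isin(topo.species, [A_PLUS, A_MINUS, B, P, PQ])
    L = state.box
    wrapped = state.wrapped_positions()
    tree = cKDTree(wrapped[polymer_mask], boxsize=L) if polymer_mask.any() else None

    new_coords = []
    for _ in range(n):
        for attempt in range(max_tries):
            com = rng.uniform(0, L, size=3)
            rot = _random_rotation(rng)
            coords = np.mod(com + t_porph.reference_coords @ rot.T, L)
            if tree is None:
                break
            d, _ = tree.query(coords, k=1)
            if d.min() >= clearance:
                break
        else:
            raise RuntimeError(
                f"could not place porphyrin with clearance {clearance} "
                f"after {max_tries} tries"
            )
        new_coords.append(coords)

    # swap out 12 solvent beads per insertion; 4 of their positions host the
    # new counterions so the local density stays unchanged
    removed = rng.choice(solvent_idx, size=12 * n, replace=False)
    keep = np.ones(state.n_beads, dtype=bool)
    keep[removed] = False
    ci_pos = wrapped[removed[: 4 * n]]

    pos_parts = [state.pos[keep]]
    vel_parts = [state.vel[keep]]
    species_parts = [topo.species[keep]]
    mol_id_parts = [topo.mol_id[keep]]
    # old indices -> new indices for bonds / rigid starts
    remap = np.cumsum(keep) - 1
    bonds = remap[topo.bonds] if len(topo.bonds) else topo.bonds
    rigid_start = [int(remap[s]) for s in topo.rigid_start]
    rigid_size = list(topo.rigid_size)
    mol_kind = list(topo.mol_kind)

    n_kept = int(keep.sum())
    offset = n_kept
    vel_rng = np.random.default_rng(seed + 1)
    for coords in new_coords:
        mol = len(mol_kind)
        mol_kind.append(PORPHYRIN)
        rigid_start.append(offset)
        rigid_size.append(8)
        pos_parts.append(coords)
        species_parts.append(t_porph.species.astype(np.int8))
        mol_id_parts.append(np.full(8, mol, dtype=np.int64))
        vel_parts.append(vel_rng.normal(size=(8, 3)))
        offset += 8
    pos_parts.append(ci_pos)
    species_parts.append(np.full(4 * n, CI_MINUS, dtype=np.int8))
    mol_id_parts.append(np.full(4 * n, -1, dtype=np.int64))
    vel_parts.append(vel_rng.normal(size=(4 * n, 3)))

    new_topo = Topology(
        species=np.concatenate(species_parts),
        bonds=bonds,
        mol_id=np.concatenate(mol_id_parts),
        mol_kind=np.array(mol_kind, dtype=np.int8),
        rigid_start=np.array(rigid_start, dtype=np.int64),
        rigid_size=np.array(rigid_size, dtype=np.int64),
        rigid_reference=(
            topo.rigid_reference
            if topo.rigid_reference is not None
            else t_porph.reference_coords
        ),
    )
    new_state = SystemState(
        pos=np.vstack(pos_parts),
        vel=np.vstack(vel_parts),
        box=L,
        topology=new_topo,
    )
    # project the new rigid beads onto rigid motion and keep momentum zero
    for s in rigid_start[len(topo.rigid_start):]:
        sl = slice(s, s + 8)
        x = new_state.pos[sl]
        com = x.mean(axis=0)
        d = x - com
        v = new_state.vel[sl]
        vcom = v.mean(axis=0)
        ang_mom = np.cross(d, v - vcom).sum(axis=0)
        inertia = np.einsum("ni,nj->ij", d, d)
        inertia = np.trace(inertia) * np.eye(3) - inertia
        omega = np.linalg.solve(inertia, ang_mom)
        new_state.vel[sl] = vcom + np.cross(omega, d)
    new_state.vel -= new_state.vel.mean(axis=0)
    if new_state.total_charge() != 0:
        raise AssertionError("insertion broke electroneutrality")
    return new_state


def make_cluster_fixture(
    sizes: list[int],
    L: float,
    d_cut: float = 0.7,
    seed: int = 0,
    n_a: int = 10,
    n_b: int = 25,
    rho: float = 3.0,
):
    """Synthetic state with known cluster structure, for analysis tests.

    Builds one compact group of chains per entry of ``sizes`` (alternating
    chain signs within a group), placed on a grid so that intra-group
    contacts are below ``d_cut`` while inter-group gaps exceed ``2 d_cut``.
    Returns ``(state, labels)`` where ``labels[mol] = group index``.
    """
    if not sizes or any(s < 1 for s in sizes):
        raise ValueError("sizes must be a non-empty list of positive counts")
    rng = np.random.default_rng(seed)
    n_clusters = len(sizes)
    # confinement radius per group and required grid spacing
    r_conf = [0.8 + 0.45 * np.sqrt(n_a * s) * 0.35 for s in sizes]
    spacing = 2 * max(r_conf) + 3.0 * d_cut + 0.5
    per_axis = int(np.floor(L / spacing))
    if per_axis**3 < n_clusters:
        raise ValueError(
            f"cannot pack {n_clusters} clusters with spacing {spacing:.2f} "
            f"in box L={L}"
        )
    centers = []
    for idx in range(n_clusters):
        i, j, k = np.unravel_index(idx, (per_axis,) * 3)
        centers.append((np.array([i, j, k]) + 0.5) * spacing)

    n_plus = sum((s + 1) // 2 for s in sizes)
    n_minus = sum(s // 2 for s in sizes)
    recipe = ScenarioRecipe(
        n_plus=n_plus, n_minus=n_minus, L=L, rho=rho, seed=seed,
        n_a=n_a, n_b=n_b,
    )
    asm = _Assembler(recipe)
    t = {+1: make_diblock(n_a, n_b, +1), -1: make_diblock(n_a, n_b, -1)}
    labels = []
    step = min(0.6 * d_cut, 0.5)
    for c_idx, (size, center, rc) in enumerate(zip(sizes, centers, r_conf)):
        placed_a: list[np.ndarray] = []
        for chain in range(size):
            sign = +1 if chain % 2 == 0 else -1
            if placed_a:
                anchor = placed_a[rng.integers(len(placed_a))]
                start = anchor + 0.8 * d_cut * _random_unit(rng)[0]
            else:
                start = center.copy()
            coords = np.empty((n_a + n_b, 3))
            coords[0] = start
            for b in range(1, n_a + n_b):
                for _ in range(200):
                    cand = coords[b - 1] + step * _random_unit(rng)[0]
                    if np.linalg.norm(cand - center) <= rc:
                        break
                else:
                    cand = center + 0.5 * rc * _random_unit(rng)[0]
                coords[b] = cand
            placed_a.extend(coords[:n_a])
            asm.add_molecule(
                t[sign], coords, CHAIN_PLUS if sign > 0 else CHAIN_MINUS
            )
            labels.append(c_idx)
    _add_counterions_and_solvent(asm, rng)
    state = asm.finalize(rng)
    return state, np.array(labels, dtype=np.int64)
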