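"""DPD forces, neighbor search, integrator, rigid bodies, thermostat."""

import numpy as np
import pytest

import ipecsim as ip
from ipecsim.forces import (
    bond_force,
    collect_pairs,
    dpd_pair_forces,
    pair_conservative_force,
    pair_dissipative_random_force,
)
from conftest import brute_force_dpd


class TestPairForces:
    def test_conservative_zero_at_cutoff_and_beyond(self):
        for r in (1.0, 1.5):
            f = pair_conservative_force(np.array([r, 0, 0]), 25.0)
            assert np.allclose(f, 0)

    @pytest.mark.parametrize("a, mag", [(25.0, 12.5), (18.0, 9.0)])
    def test_conservative_closed_form_at_half_cutoff(self, a, mag):
        f = pair_conservative_force(np.array([0.5, 0, 0]), a)
        assert np.linalg.norm(f) == pytest.approx(mag)
        assert f[0] > 0  # repulsive, along separation

    def test_conservative_zero_at_origin(self):
        assert np.allclose(pair_conservative_force(np.zeros(3), 25.0), 0)

    def test_dissipative_zero_beyond_cutoff(self):
        f = pair_dissipative_random_force(
            np.array([1.2, 0, 0]), np.array([1.0, 0, 0]), 4.5, 3.0, 0.04, 0.7
        )
        assert np.allclose(f, 0)

    def test_dissipative_vanishes_for_perpendicular_motion(self):
        f = pair_dissipative_random_force(
            np.array([0.5, 0, 0]), np.array([0, 2.0, 0]), 4.5, 0.0, 0.04, 0.0
        )
        assert np.allclose(f, 0)

    def test_bond_force_harmonic(self):
        assert np.allclose(bond_force(np.array([0.5, 0, 0]), 4.0, 0.5), 0)
        f = bond_force(np.array([1.0, 0, 0]), 4.0, 0.0)
        assert f[0] == pytest.approx(-4.0)  # pulls toward the partner
        f2 = bond_force(np.array([1.0, 0, 0]), 8.0, 0.0)
        assert np.allclose(f2, 2 * f)


class TestNeighborSearch:
    def test_close_pair_found(self):
        pos = np.array([[1.0, 1.0, 1.0], [1.5, 1.0, 1.0]])
        i, j = collect_pairs(pos, 10.0, 1.0)
        assert len(i) == 1

    def test_periodic_image_pair_found(self):
        pos = np.array([[0.1, 5.0, 5.0], [9.8, 5.0, 5.0]])
        i, j = collect_pairs(pos, 10.0, 1.0)
        assert len(i) == 1  # distance 0.3 through the boundary

    def test_matches_kdtree_on_random_config(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 7.0, size=(500, 3))
        i, j = collect_pairs(pos, 7.0, 1.0)
        from scipy.spatial import cKDTree

        ref = cKDTree(pos, boxsize=7.0).query_pairs(1.0)
        got = set(zip(np.minimum(i, j).tolist(), np.maximum(i, j).tolist()))
        assert got == set(ref)

    def test_small_box_falls_back_to_all_pairs(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 2.5, size=(40, 3))
        i, j = collect_pairs(pos, 2.5, 1.0)
        from scipy.spatial import cKDTree

        ref = cKDTree(pos, boxsize=2.5).query_pairs(1.0)
        got = set(zip(np.minimum(i, j).tolist(), np.maximum(i, j).tolist()))
        assert got == set(ref)


def test_kernel_forces_match_brute_force_oracle(table):
    """Cell-list kernel == O(N^2) python loop (full triple force, shared
    counter-based noise), to 1e-10."""
    rng = np.random.default_rng(2)
    n = 500
    box = 6.0
    pos = rng.uniform(0, box, size=(n, 3))
    vel = rng.normal(size=(n, 3))
    species = rng.integers(0, 8, size=n)
    amat = table.matrix
    ref = brute_force_dpd(pos, vel, species, amat, box, 4.5, 3.0, 0.04, 9, 17)
    forces = np.zeros((n, 3))
    i, j = collect_pairs(pos, box, 1.0)
    dpd_pair_forces(pos, vel, species, amat, box, 4.5, 3.0, 0.04, 9, 17,
                    i, j, forces)
    assert np.abs(forces - ref).max() < 1e-10


def test_pair_noise_is_symmetric_and_order_independent(table):
    """Random force obeys Newton's third law exactly: swapping the pair
    list order changes nothing (shared per-pair noise)."""
    rng = np.random.default_rng(3)
    n = 100
    box = 5.0
    pos = rng.uniform(0, box, size=(n, 3))
    vel = rng.normal(size=(n, 3))
    species = np.zeros(n, dtype=np.int64)
    i, j = collect_pairs(pos, box, 1.0)
    f1 = np.zeros((n, 3))
    dpd_pair_forces(pos, vel, species, table.matrix, box, 4.5, 3.0, 0.04,
                    5, 7, i, j, f1)
    f2 = np.zeros((n, 3))
    perm = np.random.default_rng(4).permutation(len(i))
    dpd_pair_forces(pos, vel, species, table.matrix, box, 4.5, 3.0, 0.04,
                    5, 7, j[perm], i[perm], f2)
    assert np.abs(f1 - f2).max() < 1e-12
    assert np.abs(f1.sum(axis=0)).max() < 1e-10


class _ConstantForceEngine(ip.Engine):
    """Engine with a uniform external force, for integrator checks."""

    def __init__(self, state, params, fext):
        self._fext = np.asarray(fext)
        super().__init__(state, params)

    def _compute_forces(self, pos, vel, step):
        self.last_energies = {"bond": 0.0, "dpd": 0.0,
                              "elec_real": 0.0, "elec_recip": 0.0}
        return np.broadcast_to(self._fext, pos.shape).copy()


def _single_bead_state(L=50.0):
    topo = ip.Topology(
        species=np.array([7], dtype=np.int8),
        bonds=np.empty((0, 2), dtype=np.int64),
        mol_id=np.array([-1]),
        mol_kind=np.empty(0, dtype=np.int8),
        rigid_start=np.empty(0, dtype=np.int64),
        rigid_size=np.empty(0, dtype=np.int64),
    )
    return ip.SystemState(
        pos=np.array([[25.0, 25.0, 25.0]]),
        vel=np.zeros((1, 3)),
        box=L,
        topology=topo,
    )


class TestIntegrator:
    def test_zero_forces_zero_velocity_is_identity(self):
        st = _single_bead_state()
        eng = _ConstantForceEngine(st, ip.SimParams(seed=1), np.zeros(3))
        p0 = st.pos.copy()
        eng.run(10, thermo_stride=0, keep_frames=False)
        assert np.array_equal(st.pos, p0)

    def test_constant_force_matches_hand_iterated_update(self):
        f = np.array([0.3, -0.1, 0.2])
        dt = 0.04
        st = _single_bead_state()
        eng = _ConstantForceEngine(st, ip.SimParams(dt=dt, seed=1), f)
        n = 25
        eng.run(n, thermo_stride=0, keep_frames=False)
        # oracle: iterate the update rule (constant force)
        pos = np.array([25.0, 25.0, 25.0])
        vel = np.zeros(3)
        for _ in range(n):
            pos = pos + dt * vel + 0.5 * dt * dt * f
            vel = vel + dt * f
        assert np.allclose(st.pos[0], pos, atol=1e-12)
        assert np.allclose(st.vel[0], vel, atol=1e-12)

    def test_zero_steps_is_identity_with_empty_log(self):
        st = ip.build_initial_state(ip.ScenarioRecipe(L=5, seed=20))
        p0 = st.pos.copy()
        eng = ip.Engine(st, ip.SimParams(seed=2))
        frames, thermo = eng.run(0)
        assert frames == [] and thermo == []
        assert np.array_equal(st.pos, p0)

    def test_run_deterministic_under_seed(self):
        r = ip.ScenarioRecipe(n_plus=1, n_minus=1, L=6, seed=21)
        a = ip.build_initial_state(r)
        b = ip.build_initial_state(r)
        for s in (a, b):
            ip.Engine(s, ip.SimParams(seed=5)).run(100, thermo_stride=0,
                                                   keep_frames=False)
        assert np.array_equal(a.pos, b.pos)
        assert np.array_equal(a.vel, b.vel)

    def test_instability_detected(self):
        st = _single_bead_state()
        eng = _ConstantForceEngine(st, ip.SimParams(dt=1.0, seed=1),
                                   np.array([5.0, 0, 0]))
        with pytest.raises(ip.EngineInstability):
            eng.run(5, thermo_stride=0, keep_frames=False)


class TestRigidBodies:
    def test_intra_body_distances_preserved(self):
        r = ip.ScenarioRecipe(n_porphyrin=2, L=5, seed=22)
        st = ip.build_initial_state(r)
        eng = ip.Engine(st, ip.SimParams(seed=6))
        from scipy.spatial.distance import pdist

        ref = np.sort(pdist(st.topology.rigid_reference))
        eng.run(1000, thermo_stride=0, keep_frames=False)
        for s, n in zip(st.topology.rigid_start, st.topology.rigid_size):
            x = st.pos[s:s + n]
            d = x - x[0]
            d -= st.box * np.round(d / st.box)
            assert np.abs(np.sort(pdist(x[0] + d)) - ref).max() < 1e-8

    def test_dof_counting(self):
        # one rigid body + 10 free beads, momentum removed: 6 + 30 - 3
        assert ip.count_dof(10, 1) == 33

    def test_momentum_conserved_with_rigid_bodies(self):
        r = ip.ScenarioRecipe(n_porphyrin=2, L=5, seed=23)
        st = ip.build_initial_state(r)
        eng = ip.Engine(st, ip.SimParams(seed=7))
        eng.run(500, thermo_stride=0, keep_frames=False)
        assert np.abs(st.vel.sum(axis=0)).max() < 1e-8


class TestTemperature:
    def test_zero_velocities(self, solvent_state_small):
        st = solvent_state_small.copy()
        st.vel[:] = 0
        assert ip.measure_temperature(st) == 0.0

    def test_sampled_maxwell(self):
        st = ip.build_initial_state(ip.ScenarioRecipe(L=10, seed=24))
        assert ip.measure_temperature(st) == pytest.approx(1.0, abs=0.03)

    def test_thermostat_short_run(self):
        """Reduced-size thermostat check (the full-size one runs in the
        acceptance suite)."""
        st = ip.build_initial_state(ip.ScenarioRecipe(L=6, seed=25))
        eng = ip.Engine(st, ip.SimParams(seed=8))
        _, thermo = eng.run(2000, thermo_stride=100, keep_frames=False)
        temps = [row["temperature"] for row in thermo[5:]]
        assert np.mean(temps) == pytest.approx(1.0, abs=0.05)

    def test_athermal_solvent_density_flat(self):
        """With a_ij = 25 everywhere and no charges the solvent shows no
        structure beyond noise (athermal reference)."""
        st = ip.build_initial_state(ip.ScenarioRecipe(L=6, seed=26))
        eng = ip.Engine(st, ip.SimParams(seed=9))
        eng.run(1500, thermo_stride=0, keep_frames=False)
        h, _ = np.histogramdd(st.wrapped_positions(),
                              bins=(3, 3, 3), range=[(0, 6)] * 3)
        counts = h.ravel()
        expect = st.n_beads / 27
        assert np.abs(counts - expect).max() < 5 * np.sqrt(expect)
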