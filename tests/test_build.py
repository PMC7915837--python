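"""System builders: counts, neutrality, determinism, special layouts."""

import numpy as np
import pytest

import ipecsim as ip
from ipecsim.species import A_MINUS, A_PLUS, B, CI_MINUS, CI_PLUS, P, PQ, S
from ipecsim.topology import minimum_image


def species_counts(state):
    return np.bincount(state.topology.species, minlength=8)


class TestAssembleBox:
    def test_paper_recipe_counterion_counts(self):
        # 137+137 chains x 10 charged beads each force 1370 CI of each sign
        r = ip.ScenarioRecipe(n_plus=137, n_minus=137, L=30, seed=1)
        st = ip.assemble_box(r)
        c = species_counts(st)
        assert c[CI_MINUS] == 1370
        assert c[CI_PLUS] == 1370
        assert c[A_PLUS] == c[A_MINUS] == 1370
        assert c[B] == 274 * 25
        assert st.total_charge() == 0
        assert st.n_beads == round(3 * 30**3)

    def test_single_porphyrin_fill_arithmetic(self):
        r = ip.ScenarioRecipe(n_porphyrin=1, L=10, seed=2)
        st = ip.assemble_box(r)
        c = species_counts(st)
        assert st.n_beads == 3000
        assert c[P] == 4 and c[PQ] == 4
        assert c[CI_MINUS] == 4
        assert c[S] == 2988

    def test_empty_recipe_is_pure_solvent(self):
        r = ip.ScenarioRecipe(L=6, seed=3)
        st = ip.assemble_box(r)
        assert st.total_charge() == 0
        assert (st.topology.species == S).all()
        assert st.n_beads == round(3 * 6**3)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_plus=3, n_minus=2, L=8),
            dict(n_porphyrin=4, n_salt_pairs=50, L=8),
            dict(n_plus=1, n_minus=1, n_porphyrin=2, n_salt_pairs=7, L=8),
        ],
    )
    def test_neutrality_and_fill_invariants(self, kwargs):
        st = ip.assemble_box(ip.ScenarioRecipe(seed=4, **kwargs))
        st.check_invariants(rho=3.0)
        assert (st.pos >= 0).all() and (st.pos < st.box).all()

    def test_determinism(self):
        r = ip.ScenarioRecipe(n_plus=2, n_minus=2, n_porphyrin=1, L=8, seed=5)
        a = ip.assemble_box(r)
        b = ip.assemble_box(r)
        assert np.array_equal(a.pos, b.pos)
        assert np.array_equal(a.vel, b.vel)

    def test_box_too_small_rejected(self):
        with pytest.raises(ValueError, match="box too small|exceed"):
            ip.assemble_box(ip.ScenarioRecipe(n_plus=50, n_minus=50, L=5))

    def test_template_round_trip(self):
        r = ip.ScenarioRecipe(n_plus=3, n_minus=1, L=8, seed=6)
        st = ip.assemble_box(r)
        topo = st.topology
        t = ip.make_diblock(10, 25, +1)
        for mol in range(3):
            beads = np.flatnonzero(topo.mol_id == mol)
            assert len(beads) == 35
            assert np.array_equal(topo.species[beads], t.species)
        # bonds partition per molecule, 34 each
        for mol in range(4):
            beads = np.flatnonzero(topo.mol_id == mol)
            nb = np.isin(topo.bonds, beads).all(axis=1).sum()
            assert nb == 34

    def test_velocities_thermal_and_momentum_free(self):
        st = ip.assemble_box(ip.ScenarioRecipe(L=10, seed=7))
        assert np.abs(st.vel.mean(axis=0)).max() < 1e-12
        assert ip.measure_temperature(st) == pytest.approx(1.0, abs=0.03)


def test_porphyrin_count_for_volume_fraction_round_trip():
    from ipecsim import porphyrin_count_for_volume_fraction

    n = porphyrin_count_for_volume_fraction(0.5, L=15)
    r = ip.ScenarioRecipe(n_porphyrin=n, L=15)
    assert r.porphyrin_volume_fraction == pytest.approx(0.5, rel=0.1)


class TestPreaggregated:
    def test_single_associate_at_step_zero(self):
        r = ip.ScenarioRecipe(n_plus=10, n_minus=10, L=10, seed=8,
                              mode="preaggregated")
        st = ip.assemble_preaggregated(r)
        rep = ip.identify_clusters(st)
        assert rep.n_clusters == 1
        assert rep.association_numbers.tolist() == [20]

    def test_trivial_two_chain_associate(self):
        r = ip.ScenarioRecipe(n_plus=1, n_minus=1, L=8, seed=9,
                              mode="preaggregated")
        st = ip.assemble_preaggregated(r)
        rep = ip.identify_clusters(st)
        assert rep.association_numbers.tolist() == [2]

    def test_core_sphere_holds_all_a_and_no_b(self):
        r = ip.ScenarioRecipe(n_plus=8, n_minus=8, L=10, seed=10,
                              mode="preaggregated")
        st = ip.assemble_preaggregated(r)
        topo = st.topology
        center = np.full(3, st.box / 2)
        r_core = (3 * 160 / (4 * np.pi * 3)) ** (1 / 3)
        a_sel = np.isin(topo.species, [A_PLUS, A_MINUS])
        b_sel = topo.species == B
        ra = np.linalg.norm(
            minimum_image(st.pos[a_sel] - center, st.box), axis=1
        )
        rb = np.linalg.norm(
            minimum_image(st.pos[b_sel] - center, st.box), axis=1
        )
        assert ra.max() <= r_core + 1e-9
        assert (rb > r_core).all()

    def test_requires_chains(self):
        with pytest.raises(ValueError):
            ip.assemble_preaggregated(
                ip.ScenarioRecipe(L=8, mode="preaggregated")
            )


@pytest.fixture(scope="module")
def host():
    r = ip.ScenarioRecipe(n_plus=4, n_minus=4, L=9, seed=11)
    return ip.assemble_box(r)


class TestInsertPorphyrins:
    def test_zero_is_identity(self, host):
        out = ip.insert_porphyrins_bulk(host, 0, seed=1)
        assert np.array_equal(out.pos, host.pos)

    def test_counts_charge_and_clearance(self, host):
        out = ip.insert_porphyrins_bulk(host, 3, seed=2)
        assert out.n_beads == host.n_beads  # swap rule preserves total
        assert out.total_charge() == 0
        c = species_counts(out)
        assert c[P] == 12 and c[PQ] == 12
        # every porphyrin bead at least the clearance from polymer beads
        topo = out.topology
        poly = np.isin(topo.species, [A_PLUS, A_MINUS, B])
        porph = np.isin(topo.species, [P, PQ])
        pp = out.wrapped_positions()
        dmin = np.inf
        for x in pp[porph]:
            d = minimum_image(pp[poly] - x, out.box)
            dmin = min(dmin, np.linalg.norm(d, axis=1).min())
        assert dmin >= 1.0

    def test_insufficient_solvent_rejected(self):
        r = ip.ScenarioRecipe(L=4, seed=12)
        small = ip.assemble_box(r)
        with pytest.raises(ValueError):
            ip.insert_porphyrins_bulk(small, 20, seed=3)


class TestClusterFixture:
    def test_ground_truth_labels_and_stats(self):
        st, labels = ip.make_cluster_fixture([1, 2, 3], L=14, seed=13)
        rep = ip.identify_clusters(st)
        from conftest import same_partition

        assert same_partition(labels, rep.labels)
        dist = ip.association_statistics([rep])
        assert dist.mean_number == pytest.approx(2.0)
        assert sorted(rep.association_numbers.tolist()) == [1, 2, 3]

    def test_single_cluster_weight_one(self):
        st, _ = ip.make_cluster_fixture([5], L=14, seed=14)
        dist = ip.association_statistics([ip.identify_clusters(st)])
        assert dist.weight_fraction_of(5) == pytest.approx(1.0)

    def test_all_unimers(self):
        st, _ = ip.make_cluster_fixture([1, 1, 1, 1], L=14, seed=15)
        dist = ip.association_statistics([ip.identify_clusters(st)])
        assert dist.weight_fraction_of(1) == pytest.approx(1.0)

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError):
            ip.make_cluster_fixture([3] * 30, L=8, seed=16)
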