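"""Cluster identification and association statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_

import ipecsim as ip
from ipecsim.clusters import distribution_from_sizes
from ipecsim.species import CORE_SPECIES
from conftest import same_partition, union_find_clusters


@pytest.fixture(scope="module")
def fixture_123():
    return ip.make_cluster_fixture([1, 2, 3], L=14, seed=40)


@pytest.fixture(scope="module")
def mixed_state():
    """Chains + porphyrins after a short relaxation: irregular contacts."""
    r = ip.ScenarioRecipe(n_plus=5, n_minus=5, n_porphyrin=4, L=8, seed=41)
    state = ip.build_initial_state(r)
    eng = ip.Engine(state, ip.SimParams(seed=42))
    eng.run(300, thermo_stride=0, keep_frames=False)
    return state


class TestIdentifyClusters:
    def test_recovers_fixture_labels(self, fixture_123):
        state, labels = fixture_123
        rep = ip.identify_clusters(state)
        assert same_partition(labels, rep.labels)

    def test_stacked_porphyrins_form_dimer(self):
        r = ip.ScenarioRecipe(n_porphyrin=2, L=8, seed=43)
        state = ip.build_initial_state(r)
        # stack the second unit 0.5 above the first, same orientation
        topo = state.topology
        s0, s1 = topo.rigid_start
        state.pos[s1:s1 + 8] = state.pos[s0:s0 + 8] + np.array([0, 0, 0.5])
        rep = ip.identify_clusters(state)
        assert rep.porphyrin_cluster_sizes.tolist() == [2]

    def test_matches_union_find_oracle(self, mixed_state):
        rep = ip.identify_clusters(mixed_state, d_cut=0.7)
        oracle = union_find_clusters(mixed_state, 0.7, CORE_SPECIES)
        assert same_partition(oracle, rep.labels)

    @pytest.mark.parametrize("d_cut", [0.6, 0.8, 1.0])
    def test_oracle_equivalence_across_cutoffs(self, mixed_state, d_cut):
        rep = ip.identify_clusters(mixed_state, d_cut=d_cut)
        oracle = union_find_clusters(mixed_state, d_cut, CORE_SPECIES)
        assert same_partition(oracle, rep.labels)

    def test_invariant_under_translation_and_wrapping(self, mixed_state):
        rep = ip.identify_clusters(mixed_state)
        shifted = mixed_state.copy()
        shifted.pos += np.array([2.7, -1.3, 5.9])
        shifted.wrap()
        rep2 = ip.identify_clusters(shifted)
        assert same_partition(rep.labels, rep2.labels)

    def test_empty_member_set_rejected(self, mixed_state):
        with pytest.raises(ValueError):
            ip.identify_clusters(mixed_state, member_species=[])

    def test_invalid_cutoff_rejected(self, mixed_state):
        with pytest.raises(ValueError):
            ip.identify_clusters(mixed_state, d_cut=0.0)


class TestAssociationStatistics:
    def test_basic_arithmetic(self):
        d = distribution_from_sizes([1, 2, 3])
        assert d.mean_number == pytest.approx(2.0)
        assert np.allclose(d.weight_fraction, [1 / 6, 2 / 6, 3 / 6])
        assert np.allclose(d.number_fraction, [1 / 3, 1 / 3, 1 / 3])

    def test_preaggregated_full_system_average(self):
        # one cluster holding every chain: <AS>n equals the chain count
        d = distribution_from_sizes([274])
        assert d.mean_number == 274

    def test_porphyrin_only_frame_gives_empty_chain_distribution(self):
        r = ip.ScenarioRecipe(n_porphyrin=3, L=8, seed=44)
        state = ip.build_initial_state(r)
        rep = ip.identify_clusters(state)
        d = ip.association_statistics([rep])
        assert len(d.support) == 0

    def test_equilibration_discard(self):
        reports = []
        for sizes in ([10], [1, 1], [1, 1]):
            labels = np.arange(len(sizes))
            reports.append(
                ip.ClusterReport(
                    step=0, labels=labels,
                    n_plus=np.array(sizes), n_minus=np.zeros(len(sizes),
                                                             dtype=int),
                    n_porph=np.zeros(len(sizes), dtype=int),
                )
            )
        d = ip.association_statistics(reports, discard_fraction=0.34)
        assert d.mean_number == pytest.approx(1.0)  # first frame dropped

    @given(
        sizes=st_.lists(st_.integers(min_value=1, max_value=50),
                        min_size=1, max_size=60)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_normalization_properties(self, sizes):
        d = distribution_from_sizes(sizes)
        assert abs(d.number_fraction.sum() - 1.0) < 1e-12
        assert abs(d.weight_fraction.sum() - 1.0) < 1e-12
        # F_w proportional to AS * N(AS)
        w = d.support * d.counts
        assert np.allclose(d.weight_fraction, w / w.sum())
        assert d.mean_number == pytest.approx(np.mean(sizes))


class TestPorphyrinDistribution:
    def test_all_separated_monomers(self):
        r = ip.ScenarioRecipe(n_porphyrin=4, L=12, seed=45)
        state = ip.build_initial_state(r)
        # spread the units far apart on a grid
        topo = state.topology
        for k, s in enumerate(topo.rigid_start):
            shift = np.array([3.0 * (k % 4) + 1.5, 3.0 * (k // 4) + 1.5, 6.0])
            body = state.pos[s:s + 8]
            state.pos[s:s + 8] = body - body.mean(axis=0) + shift
        d = ip.porphyrin_aggregate_distribution([state])
        assert d.weight_fraction_of(1) == pytest.approx(1.0)
        assert d.dimer_plus_weight == pytest.approx(0.0)

    def test_one_dimer_among_monomers_weight_arithmetic(self):
        d = distribution_from_sizes([2] + [1] * 8)
        assert d.weight_fraction_of(1) == pytest.approx(0.8)
        assert d.weight_fraction_of(2) == pytest.approx(0.2)


class TestSolubilization:
    def _report(self, n_plus, n_minus, n_porph):
        n = len(n_plus)
        return ip.ClusterReport(
            step=0, labels=np.arange(n),
            n_plus=np.array(n_plus), n_minus=np.array(n_minus),
            n_porph=np.array(n_porph),
        )

    def test_all_isolated_gives_zero(self):
        rep = self._report([3, 0, 0], [3, 0, 0], [0, 1, 1])
        s = ip.solubilized_fraction([rep])
        assert s.final_fraction == 0.0

    def test_all_in_associates_gives_one(self):
        rep = self._report([3, 2], [3, 2], [2, 1])
        s = ip.solubilized_fraction([rep])
        assert s.final_fraction == 1.0

    def test_half_solubilized(self):
        rep = self._report([3, 0], [3, 0], [5, 5])
        s = ip.solubilized_fraction([rep])
        assert s.final_fraction == 0.5
        assert s.n_solubilized[-1] == 5

    def test_no_porphyrins_rejected(self):
        rep = self._report([3], [3], [0])
        with pytest.raises(ValueError):
            ip.solubilized_fraction([rep])


class TestComposition:
    def test_stoichiometric_is_neutral(self):
        assert ip.net_core_charge(15, 15, 0) == 0.0

    def test_time_averaged_compositions(self):
        # fractional counts from ensemble averaging are allowed
        assert ip.net_core_charge(12.1, 15, 15.2) == pytest.approx(31.8)
        assert ip.net_core_charge(14.6, 15, 9.0) == pytest.approx(32.0)

    def test_per_cluster_report(self):
        rep = ip.ClusterReport(
            step=0, labels=np.arange(2),
            n_plus=np.array([15, 1]), n_minus=np.array([15, 0]),
            n_porph=np.array([0, 2]),
        )
        comp = ip.core_composition(rep)
        assert comp[0] == (15.0, 15.0, 0.0, 0.0)
        assert comp[1] == (1.0, 0.0, 2.0, 18.0)
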