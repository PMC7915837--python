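"""Associate/aggregate identification and association statistics.

Two molecules belong to the same associate when any bead of one is within
the contact cutoff ``d_cut`` of a bead of the other (minimum image), with
the search restricted to core-forming species (A+, A-, P, Pq+) so that
brushing contacts between B shells do not merge distinct associates; the
transitive closure of this relation defines the clusters (single linkage).
The same criterion, restricted to porphyrin beads, identifies porphyrin
aggregates.

From per-frame cluster reports the module computes the association-number
statistics of the study: the number-averaged association number <AS>_n
(chains per associate, unimers included, porphyrins counted separately),
the weight distribution F_w(AS) proportional to AS * N(AS), porphyrin
aggregate-size distributions, solubilized porphyrin fractions f_P+, and
per-associate compositions with net core charges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .species import CORE_SPECIES, PORPHYRIN_SPECIES
from .templates import MoleculeTemplate
from .topology import CHAIN_MINUS, CHAIN_PLUS, PORPHYRIN, SystemState

#: default contact cutoff: the bond-length scale of the polymer chains
D_CUT_DEFAULT = 0.7


@dataclass
class ClusterReport:
    """Per-frame cluster labels and compositions.

    ``labels[mol]`` is the cluster index of molecule ``mol`` (-1 when the
    molecule was excluded from the clustering).  Per-cluster composition
    arrays are aligned with cluster index 0..n_clusters-1.
    """

    step: int
    labels: np.ndarray
    n_plus: np.ndarray
    n_minus: np.ndarray
    n_porph: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.n_plus)

    @property
    def association_numbers(self) -> np.ndarray:
        """AS (chain count) of every cluster containing at least one chain."""
        as_all = self.n_plus + self.n_minus
        return as_all[as_all > 0]

    @property
    def porphyrin_cluster_sizes(self) -> np.ndarray:
        """Porphyrin count of every cluster containing porphyrins."""
        return self.n_porph[self.n_porph > 0]


@dataclass
class ASDistribution:
    """Number and weight distributions of association numbers."""

    support: np.ndarray          # AS values with nonzero count
    counts: np.ndarray           # N(AS), frame-accumulated
    number_fraction: np.ndarray  # N(AS) / sum N
    weight_fraction: np.ndarray  # AS N(AS) / sum AS N
    mean_number: float           # <AS>_n

    def weight_fraction_of(self, as_value: int) -> float:
        idx = np.flatnonzero(self.support == as_value)
        return float(self.weight_fraction[idx[0]]) if len(idx) else 0.0

    @property
    def dimer_plus_weight(self) -> float:
        """Weight fraction of dimers and larger aggregates, 1 - F_w(1)."""
        return 1.0 - self.weight_fraction_of(1)


def _empty_distribution() -> ASDistribution:
    z = np.empty(0, dtype=np.int64)
    zf = np.empty(0)
    return ASDistribution(z, z.copy(), zf, zf.copy(), float("nan"))


def distribution_from_sizes(sizes) -> ASDistribution:
    """Build an :class:`ASDistribution` from a flat list of cluster sizes."""
    sizes = np.asarray(list(sizes), dtype=np.int64)
    if sizes.size == 0:
        return _empty_distribution()
    support, counts = np.unique(sizes, return_counts=True)
    total = counts.sum()
    weight = support * counts
    return ASDistribution(
        support=support,
        counts=counts,
        number_fraction=counts / total,
        weight_fraction=weight / weight.sum(),
        mean_number=float(weight.sum() / total),
    )


def identify_clusters(
    state: SystemState,
    d_cut: float = D_CUT_DEFAULT,
    member_species=CORE_SPECIES,
    molecule_kinds=None,
    step: int = 0,
) -> ClusterReport:
    """Single-linkage clustering of molecules by bead contacts.

    Two molecules are linked when any of their beads restricted to
    ``member_species`` lie within ``d_cut`` under minimum image;
    ``molecule_kinds`` optionally restricts which molecules participate
    (others get label -1).
    """
    if d_cut <= 0:
        raise ValueError("d_cut must be positive")
    member_species = list(member_species)
    if not member_species:
        raise ValueError("member species set must not be empty")
    topo = state.topology
    n_mol = topo.n_molecules
    mol_ok = np.ones(n_mol, dtype=bool)
    if molecule_kinds is not None:
        mol_ok = np.isin(topo.mol_kind, list(molecule_kinds))
    bead_sel = (
        np.isin(topo.species, member_species)
        & (topo.mol_id >= 0)
    )
    bead_sel &= mol_ok[np.clip(topo.mol_id, 0, None)]
    idx = np.flatnonzero(bead_sel)
    labels = np.full(n_mol, -1, dtype=np.int64)
    active = np.flatnonzero(mol_ok)
    if len(idx) == 0:
        return _report_from_labels(labels, topo, step)
    pos = np.mod(state.pos[idx], state.box)
    # cKDTree with boxsize needs coordinates strictly inside [0, L)
    pos[pos >= state.box] = 0.0
    tree = cKDTree(pos, boxsize=state.box)
    pairs = tree.query_pairs(d_cut, output_type="ndarray")
    mols = topo.mol_id[idx]
    mi = mols[pairs[:, 0]] if len(pairs) else np.empty(0, np.int64)
    mj = mols[pairs[:, 1]] if len(pairs) else np.empty(0, np.int64)
    keep = mi != mj
    mi, mj = mi[keep], mj[keep]
    # compress to active molecules
    remap = -np.ones(n_mol, dtype=np.int64)
    remap[active] = np.arange(len(active))
    adj = coo_matrix(
        (np.ones(len(mi)), (remap[mi], remap[mj])),
        shape=(len(active), len(active)),
    )
    n_comp, comp = connected_components(adj, directed=False)
    labels[active] = comp
    return _report_from_labels(labels, topo, step)


def _report_from_labels(labels: np.ndarray, topo, step: int) -> ClusterReport:
    n_clusters = int(labels.max()) + 1 if (labels >= 0).any() else 0
    n_plus = np.zeros(n_clusters, dtype=np.int64)
    n_minus = np.zeros(n_clusters, dtype=np.int64)
    n_porph = np.zeros(n_clusters, dtype=np.int64)
    for mol in np.flatnonzero(labels >= 0):
        lab = labels[mol]
        kind = topo.mol_kind[mol]
        if kind == CHAIN_PLUS:
            n_plus[lab] += 1
        elif kind == CHAIN_MINUS:
            n_minus[lab] += 1
        elif kind == PORPHYRIN:
            n_porph[lab] += 1
    return ClusterReport(
        step=step, labels=labels, n_plus=n_plus, n_minus=n_minus,
        n_porph=n_porph,
    )


def association_statistics(
    reports, discard_fraction: float = 0.1
) -> ASDistribution:
    """Ensemble- and time-averaged chain association distribution.

    Counts every cluster containing at least one copolymer chain (unimers
    with AS = 1 included; porphyrins never contribute to AS).  The first
    ``discard_fraction`` of the reports is dropped as equilibration when
    more than one report is given.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("at least one cluster report is required")
    if len(reports) > 1 and discard_fraction > 0:
        reports = reports[int(np.floor(discard_fraction * len(reports))):]
    sizes: list[int] = []
    for rep in reports:
        sizes.extend(rep.association_numbers.tolist())
    return distribution_from_sizes(sizes)


def porphyrin_aggregate_distribution(
    states, d_cut: float = D_CUT_DEFAULT, discard_fraction: float = 0.1,
) -> ASDistribution:
    """Weight distribution of porphyrin aggregate sizes (monomer = 1).

    Clustering is restricted to porphyrin beads and porphyrin molecules.
    """
    states = list(states)
    if not states:
        raise ValueError("at least one state is required")
    if len(states) > 1 and discard_fraction > 0:
        states = states[int(np.floor(discard_fraction * len(states))):]
    sizes: list[int] = []
    for st in states:
        rep = identify_clusters(
            st, d_cut=d_cut, member_species=PORPHYRIN_SPECIES,
            molecule_kinds=(PORPHYRIN,),
        )
        sizes.extend(rep.porphyrin_cluster_sizes.tolist())
    return distribution_from_sizes(sizes)


@dataclass
class SolubilizationSeries:
    """Time series of solubilized porphyrin counts and fractions."""

    steps: np.ndarray
    n_solubilized: np.ndarray
    fraction: np.ndarray

    @property
    def final_fraction(self) -> float:
        return float(self.fraction[-1])


def solubilized_fraction(reports) -> SolubilizationSeries:
    """f_P+ over time: a porphyrin is solubilized when its cluster also
    contains at least one copolymer chain."""
    reports = list(reports)
    if not reports:
        raise ValueError("at least one cluster report is required")
    steps, counts, fracs = [], [], []
    for rep in reports:
        total = int(rep.n_porph.sum())
        if total == 0:
            raise ValueError("no porphyrins present in report")
        chains = rep.n_plus + rep.n_minus
        n_sol = int(rep.n_porph[chains > 0].sum())
        steps.append(rep.step)
        counts.append(n_sol)
        fracs.append(n_sol / total)
    return SolubilizationSeries(
        steps=np.array(steps), n_solubilized=np.array(counts),
        fraction=np.array(fracs),
    )


def core_composition(
    report: ClusterReport, chain_charge: float = 10.0,
    porphyrin_charge: float = 4.0,
):
    """Per-cluster (n_PE+, n_PE-, n_P+, net core charge).

    Net charge = chain_charge (n_PE+ - n_PE-) + porphyrin_charge n_P+;
    accepts fractional (time-averaged) counts via :func:`net_core_charge`.
    """
    out = []
    for k in range(report.n_clusters):
        npl, nmi, npo = (
            float(report.n_plus[k]), float(report.n_minus[k]),
            float(report.n_porph[k]),
        )
        out.append(
            (npl, nmi, npo,
             net_core_charge(npl, nmi, npo, chain_charge, porphyrin_charge))
        )
    return out


def net_core_charge(
    n_plus: float, n_minus: float, n_porph: float,
    chain_charge: float = 10.0, porphyrin_charge: float = 4.0,
) -> float:
    """Net associate charge from (possibly time-averaged) compositions."""
    return chain_charge * (n_plus - n_minus) + porphyrin_charge * n_porph


def charge_equivalence(
    chain: MoleculeTemplate, porphyrin: MoleculeTemplate
) -> float:
    """Porphyrins electrostatically equivalent to one chain:
    |chain net charge| / |porphyrin net charge|."""
    qp = abs(porphyrin.net_charge)
    if qp == 0:
        raise ValueError("porphyrin template carries no net charge")
    return abs(chain.net_charge) / qp
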