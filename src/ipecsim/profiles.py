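"""Radial density profiles around associate cores.

For every associate selected by an association-number filter, the core
center is the center of mass of its core beads (A+, A-, P, Pq+) after
minimum-image unwrapping, and species densities are accumulated in
spherical shells around it, averaged over associates and frames.
Distances are in r_c units; densities in beads per reduced volume.
Associates whose unwrapped core spans more than half the box are skipped
(periodic ambiguity) and counted in ``n_skipped``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .species import LABELS, LABEL_TO_CODE, CORE_SPECIES, valence_of
from .clusters import ClusterReport
from .topology import SystemState, minimum_image

BIN_WIDTH_DEFAULT = 0.25


@dataclass
class RadialProfile:
    """Angularly averaged density vs. distance from the core center."""

    bin_edges: np.ndarray               # (n_bins+1,)
    density: dict                       # column name -> (n_bins,) array
    n_samples: int                      # associates x frames averaged
    n_skipped: int = 0                  # cores spanning > L/2, not averaged
    selection: str = ""

    @property
    def r_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def shell_volumes(self) -> np.ndarray:
        return 4.0 / 3.0 * np.pi * np.diff(self.bin_edges**3)

    def integral(self, key: str) -> float:
        """Volume integral of a density column = mean bead count per sample."""
        return float((self.density[key] * self.shell_volumes).sum())


def _matching_clusters(report: ClusterReport, as_filter) -> np.ndarray:
    as_all = report.n_plus + report.n_minus
    if as_filter is None:
        return np.flatnonzero(as_all > 0)
    if callable(as_filter):
        return np.array(
            [k for k in range(report.n_clusters) if as_filter(report, k)],
            dtype=np.int64,
        )
    if np.isscalar(as_filter):
        return np.flatnonzero(as_all == int(as_filter))
    lo, hi = as_filter
    return np.flatnonzero((as_all >= lo) & (as_all <= hi))


def _core_center(state: SystemState, mol_in_cluster: np.ndarray):
    """COM of core beads with minimum-image unwrapping; None if the core
    spans more than half the box."""
    topo = state.topology
    sel = np.isin(topo.mol_id, mol_in_cluster) & np.isin(
        topo.species, CORE_SPECIES
    )
    core = state.pos[sel]
    if len(core) == 0:
        return None
    d = minimum_image(core - core[0], state.box)
    if np.abs(d).max() > state.box / 2.0 - 1.0e-9:
        return None
    return core[0] + d.mean(axis=0)


def radial_density_profile(
    states,
    reports,
    as_filter=None,
    species=None,
    bin_width: float = BIN_WIDTH_DEFAULT,
    r_max: float | None = None,
    weights: str = "count",
) -> RadialProfile:
    """Species-resolved RDP around matching associates.

    ``states`` and ``reports`` are parallel sequences (one report per
    frame).  ``as_filter`` selects associates: ``None`` (all chain-bearing
    clusters), an int (exact AS), a (lo, hi) tuple, or a callable
    ``(report, cluster_index) -> bool``.  ``weights="charge"`` accumulates
    valence-weighted densities instead of counts.
    """
    states = list(states)
    reports = list(reports)
    if len(states) != len(reports):
        raise ValueError("states and reports must be parallel sequences")
    if species is None:
        species = list(LABELS)
    codes = [LABEL_TO_CODE[s] if isinstance(s, str) else int(s) for s in species]
    names = [LABELS[c] for c in codes]
    box = states[0].box
    if r_max is None:
        r_max = box / 2.0
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    nb = len(edges) - 1
    counts = {n: np.zeros(nb) for n in names}
    n_samples = 0
    n_skipped = 0
    for state, report in zip(states, reports):
        clusters = _matching_clusters(report, as_filter)
        for k in clusters:
            mols = np.flatnonzero(report.labels == k)
            center = _core_center(state, mols)
            if center is None:
                n_skipped += 1
                continue
            n_samples += 1
            d = minimum_image(state.pos - center, state.box)
            r = np.linalg.norm(d, axis=1)
            for code, name in zip(codes, names):
                sel = state.topology.species == code
                if weights == "charge":
                    w = valence_of(state.topology.species[sel]).astype(float)
                    h, _ = np.histogram(r[sel], bins=edges, weights=w)
                else:
                    h, _ = np.histogram(r[sel], bins=edges)
                counts[name] += h
    if n_samples == 0:
        raise ValueError(
            f"no associate matched the filter {as_filter!r} "
            f"({n_skipped} skipped for periodic ambiguity)"
        )
    vol = 4.0 / 3.0 * np.pi * np.diff(edges**3)
    density = {n: counts[n] / (n_samples * vol) for n in names}
    return RadialProfile(
        bin_edges=edges,
        density=density,
        n_samples=n_samples,
        n_skipped=n_skipped,
        selection=f"as_filter={as_filter!r} weights={weights}",
    )


def core_charge_profile(
    states,
    reports,
    as_filter=None,
    bin_width: float = BIN_WIDTH_DEFAULT,
    r_max: float | None = None,
) -> RadialProfile:
    """Net valence density plus small-ion densities around associate cores.

    Returns a profile with columns ``net_charge`` (all beads weighted by
    valence), ``CI+`` and ``CI-``.
    """
    states = list(states)
    reports = list(reports)
    if len(states) != len(reports):
        raise ValueError("states and reports must be parallel sequences")
    box = states[0].box
    if r_max is None:
        r_max = box / 2.0
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    nb = len(edges) - 1
    acc = {"net_charge": np.zeros(nb), "CI+": np.zeros(nb), "CI-": np.zeros(nb)}
    n_samples = 0
    n_skipped = 0
    for state, report in zip(states, reports):
        v = valence_of(state.topology.species).astype(float)
        for k in _matching_clusters(report, as_filter):
            mols = np.flatnonzero(report.labels == k)
            center = _core_center(state, mols)
            if center is None:
                n_skipped += 1
                continue
            n_samples += 1
            d = minimum_image(state.pos - center, state.box)
            r = np.linalg.norm(d, axis=1)
            h, _ = np.histogram(r, bins=edges, weights=v)
            acc["net_charge"] += h
            for name in ("CI+", "CI-"):
                sel = state.topology.species == LABEL_TO_CODE[name]
                h, _ = np.histogram(r[sel], bins=edges)
                acc[name] += h
    if n_samples == 0:
        raise ValueError(f"no associate matched the filter {as_filter!r}")
    vol = 4.0 / 3.0 * np.pi * np.diff(edges**3)
    density = {n: acc[n] / (n_samples * vol) for n in acc}
    return RadialProfile(
        bin_edges=edges,
        density=density,
        n_samples=n_samples,
        n_skipped=n_skipped,
        selection=f"as_filter={as_filter!r} charge profile",
    )
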