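"""Numba kernels: neighbor search and the DPD pair/bond forces.

The conservative force is the soft linear repulsion a_ij (1 - r/r_c) r_hat
below the cutoff r_c = 1; the dissipative and random forces use the
standard weight w(r) = 1 - r/r_c with sigma^2 = 2 gamma kT so the pair acts
as a momentum-conserving thermostat.  The random force uses a counter-based
(hash) generator keyed on (seed, step, i, j), so each pair draws one shared
noise value per step and trajectories are independent of iteration order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

SQRT3 = np.sqrt(3.0)


@njit(cache=True, inline="always", fastmath=True)
def _mi(d, box):
    """Minimum image for wrapped coordinates (|d| < box)."""
    if d > 0.5 * box:
        return d - box
    if d < -0.5 * box:
        return d + box
    return d


@njit(cache=True, inline="always")
def _pair_noise(seed, step, i, j):
    """Uniform variate with zero mean, unit variance, from a splitmix64-style
    hash of (seed, step, i, j) with i < j."""
    z = (
        np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15)
        ^ np.uint64(step) * np.uint64(0xBF58476D1CE4E5B9)
        ^ np.uint64(i) * np.uint64(0x94D049BB133111EB)
        ^ np.uint64(j) * np.uint64(0x2545F4914F6CDD1D)
    )
    z = z + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    u = (z >> np.uint64(11)) * (1.0 / 9007199254740992.0)
    return SQRT3 * (2.0 * u - 1.0)


@njit(cache=True, fastmath=True)
def collect_pairs(pos, box, cutoff):
    """All bead pairs (i < j) within ``cutoff`` under minimum image.

    Cell-sorted (counting sort) linked-cell search when the box holds at
    least 3 cells per edge, otherwise an all-pairs scan.  Returns two
    index arrays (original bead indices).
    """
    n = pos.shape[0]
    ncell = int(box / cutoff)
    if ncell < 3:
        return _collect_pairs_allpairs(pos, box, cutoff)
    cell_size = box / ncell
    ncell3 = ncell * ncell * ncell
    cell_of = np.empty(n, dtype=np.int64)
    ncount = np.zeros(ncell3 + 1, dtype=np.int64)
    for i in range(n):
        a = int(pos[i, 0] / cell_size)
        b = int(pos[i, 1] / cell_size)
        c = int(pos[i, 2] / cell_size)
        if a >= ncell:
            a = ncell - 1
        if b >= ncell:
            b = ncell - 1
        if c >= ncell:
            c = ncell - 1
        idx = (a * ncell + b) * ncell + c
        cell_of[i] = idx
        ncount[idx + 1] += 1
    start = np.empty(ncell3 + 1, dtype=np.int64)
    start[0] = 0
    for cidx in range(ncell3):
        start[cidx + 1] = start[cidx] + ncount[cidx + 1]
    fill = start[:ncell3].copy()
    order = np.empty(n, dtype=np.int64)
    for i in range(n):
        cidx = cell_of[i]
        order[fill[cidx]] = i
        fill[cidx] += 1
    # gather positions into cell-sorted order for contiguous scans
    sx = np.empty(n)
    sy = np.empty(n)
    sz = np.empty(n)
    for s in range(n):
        i = order[s]
        sx[s] = pos[i, 0]
        sy[s] = pos[i, 1]
        sz[s] = pos[i, 2]

    offs = np.array(
        [
            [0, 0, 0],
            [1, 0, 0], [0, 1, 0], [1, 1, 0], [-1, 1, 0],
            [0, 0, 1], [1, 0, 1], [-1, 0, 1], [0, 1, 1],
            [1, 1, 1], [-1, 1, 1], [0, -1, 1], [1, -1, 1], [-1, -1, 1],
        ],
        dtype=np.int64,
    )
    # exact upper bound on emitted pairs = candidate count over the stencil
    cap = 32
    for a in range(ncell):
        for b in range(ncell):
            for c in range(ncell):
                cidx = (a * ncell + b) * ncell + c
                nc0 = start[cidx + 1] - start[cidx]
                cap += nc0 * (nc0 - 1) // 2
                for k in range(1, 14):
                    na = (a + offs[k, 0]) % ncell
                    nb = (b + offs[k, 1]) % ncell
                    nc_ = (c + offs[k, 2]) % ncell
                    jdx = (na * ncell + nb) * ncell + nc_
                    cap += nc0 * (start[jdx + 1] - start[jdx])

    cut2 = cutoff * cutoff
    half = 0.5 * box
    out_i = np.empty(cap, dtype=np.int64)
    out_j = np.empty(cap, dtype=np.int64)
    count = 0
    for a in range(ncell):
        for b in range(ncell):
            for c in range(ncell):
                cidx = (a * ncell + b) * ncell + c
                s0 = start[cidx]
                s1 = start[cidx + 1]
                if s0 == s1:
                    continue
                for k in range(14):
                    na = (a + offs[k, 0]) % ncell
                    nb = (b + offs[k, 1]) % ncell
                    nc_ = (c + offs[k, 2]) % ncell
                    jdx = (na * ncell + nb) * ncell + nc_
                    t0 = start[jdx]
                    t1 = start[jdx + 1]
                    for s in range(s0, s1):
                        x0 = sx[s]
                        y0 = sy[s]
                        z0 = sz[s]
                        tb = s + 1 if k == 0 else t0
                        for t in range(tb, t1):
                            dx = x0 - sx[t]
                            if dx > half:
                                dx -= box
                            elif dx < -half:
                                dx += box
                            dy = y0 - sy[t]
                            if dy > half:
                                dy -= box
                            elif dy < -half:
                                dy += box
                            dz = z0 - sz[t]
                            if dz > half:
                                dz -= box
                            elif dz < -half:
                                dz += box
                            if dx * dx + dy * dy + dz * dz <= cut2:
                                out_i[count] = order[s]
                                out_j[count] = order[t]
                                count += 1
    return out_i[:count].copy(), out_j[:count].copy()


@njit(cache=True, fastmath=True)
def _collect_pairs_allpairs(pos, box, cutoff):
    n = pos.shape[0]
    cut2 = cutoff * cutoff
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = _mi(pos[i, 0] - pos[j, 0], box)
            dy = _mi(pos[i, 1] - pos[j, 1], box)
            dz = _mi(pos[i, 2] - pos[j, 2], box)
            if dx * dx + dy * dy + dz * dz <= cut2:
                count += 1
    out_i = np.empty(count, dtype=np.int64)
    out_j = np.empty(count, dtype=np.int64)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = _mi(pos[i, 0] - pos[j, 0], box)
            dy = _mi(pos[i, 1] - pos[j, 1], box)
            dz = _mi(pos[i, 2] - pos[j, 2], box)
            if dx * dx + dy * dy + dz * dz <= cut2:
                out_i[k] = i
                out_j[k] = j
                k += 1
    return out_i, out_j


@njit(cache=True, fastmath=True)
def dpd_pair_forces(
    pos, vel, species, amat, box, gamma, sigma, dt, seed, step, pairs_i, pairs_j,
    forces,
):
    """Accumulate conservative + dissipative + random DPD forces for the
    given candidate pairs; returns the conservative pair energy."""
    inv_sqrt_dt = 1.0 / np.sqrt(dt)
    e_cons = 0.0
    for k in range(pairs_i.shape[0]):
        i = pairs_i[k]
        j = pairs_j[k]
        dx = _mi(pos[i, 0] - pos[j, 0], box)
        dy = _mi(pos[i, 1] - pos[j, 1], box)
        dz = _mi(pos[i, 2] - pos[j, 2], box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= 1.0 or r2 == 0.0:
            continue
        r = np.sqrt(r2)
        ux = dx / r
        uy = dy / r
        uz = dz / r
        w = 1.0 - r
        a = amat[species[i], species[j]]
        e_cons += 0.5 * a * w * w
        fmag = a * w
        vx = vel[i, 0] - vel[j, 0]
        vy = vel[i, 1] - vel[j, 1]
        vz = vel[i, 2] - vel[j, 2]
        vdotu = vx * ux + vy * uy + vz * uz
        fmag -= gamma * w * w * vdotu
        if sigma > 0.0:
            lo = i if i < j else j
            hi = j if i < j else i
            xi = _pair_noise(seed, step, lo, hi)
            fmag += sigma * w * xi * inv_sqrt_dt
        forces[i, 0] += fmag * ux
        forces[i, 1] += fmag * uy
        forces[i, 2] += fmag * uz
        forces[j, 0] -= fmag * ux
        forces[j, 1] -= fmag * uy
        forces[j, 2] -= fmag * uz
    return e_cons


@njit(cache=True, fastmath=True)
def bond_forces(pos, bonds, box, k_bond, r0, forces):
    """Harmonic bond forces -k (r - r0) r_hat; returns the bond energy."""
    e = 0.0
    for m in range(bonds.shape[0]):
        i = bonds[m, 0]
        j = bonds[m, 1]
        dx = _mi(pos[i, 0] - pos[j, 0], box)
        dy = _mi(pos[i, 1] - pos[j, 1], box)
        dz = _mi(pos[i, 2] - pos[j, 2], box)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        e += 0.5 * k_bond * (r - r0) * (r - r0)
        if r > 0.0:
            fmag = -k_bond * (r - r0) / r
            forces[i, 0] += fmag * dx
            forces[i, 1] += fmag * dy
            forces[i, 2] += fmag * dz
            forces[j, 0] -= fmag * dx
            forces[j, 1] -= fmag * dy
            forces[j, 2] -= fmag * dz
    return e


def pair_conservative_force(r_vec: np.ndarray, a_ij: float,
                            r_c: float = 1.0) -> np.ndarray:
    """Conservative soft repulsion on bead i for separation ``r_vec`` =
    r_i - r_j: magnitude a_ij (1 - r/r_c) along r_hat for r < r_c, zero
    beyond; zero vector at r = 0 (soft potential, direction undefined)."""
    r_vec = np.asarray(r_vec, dtype=float)
    r = float(np.linalg.norm(r_vec))
    if r == 0.0 or r >= r_c:
        return np.zeros(3)
    return a_ij * (1.0 - r / r_c) * r_vec / r


def pair_dissipative_random_force(
    r_vec, v_rel, gamma, sigma, dt, xi, r_c: float = 1.0
) -> np.ndarray:
    """Dissipative plus random DPD force on bead i for a single pair.

    ``v_rel = v_i - v_j``; ``xi`` is the pair's shared noise draw (zero
    mean, unit variance), so the equal-and-opposite force on j follows by
    negation with the same ``xi``.
    """
    r_vec = np.asarray(r_vec, dtype=float)
    v_rel = np.asarray(v_rel, dtype=float)
    r = float(np.linalg.norm(r_vec))
    if r == 0.0 or r >= r_c:
        return np.zeros(3)
    u = r_vec / r
    w = 1.0 - r / r_c
    f = -gamma * w * w * float(np.dot(u, v_rel))
    f += sigma * w * float(xi) / np.sqrt(dt)
    return f * u


def bond_force(r_vec, k_bond: float, r0: float = 0.0) -> np.ndarray:
    """Harmonic bond force on bead i: -k (r - r0) r_hat."""
    r_vec = np.asarray(r_vec, dtype=float)
    r = float(np.linalg.norm(r_vec))
    if r == 0.0:
        return np.zeros(3)
    return -k_bond * (r - r0) * r_vec / r
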