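"""Text file I/O: extended XYZ, columnar dumps, topology JSON, CSV tables.

All formats are plain text and self-describing.  Floats in the XYZ writer
use ``repr`` so configurations round-trip exactly through the decimal
representation.
"""

from __future__ import annotations

import csv
import json

import numpy as np

from .species import LABELS, LABEL_TO_CODE, valence_of
from .topology import SystemState, Topology

UNITS_COMMENT = "reduced DPD units (r_c = kT = m = 1)"


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

def write_xyz(fh_or_path, state: SystemState, step: int = 0,
              append: bool = False) -> None:
    """One extended-XYZ frame: label x y z charge, exact float round-trip."""
    own = isinstance(fh_or_path, (str, bytes)) or hasattr(fh_or_path, "__fspath__")
    fh = open(fh_or_path, "a" if append else "w") if own else fh_or_path
    try:
        L = state.box
        topo = state.topology
        q = valence_of(topo.species)
        fh.write(f"{state.n_beads}\n")
        fh.write(
            f'Lattice="{L!r} 0 0 0 {L!r} 0 0 0 {L!r}" '
            f"Properties=species:S:1:pos:R:3:charge:R:1 step={step} "
            f"units={UNITS_COMMENT.split()[0]}\n"
        )
        pos = state.wrapped_positions()
        for i in range(state.n_beads):
            x, y, z = (float(v) for v in pos[i])
            fh.write(
                f"{LABELS[topo.species[i]]} {x!r} {y!r} {z!r} {int(q[i])}\n"
            )
    finally:
        if own:
            fh.close()


def read_xyz(path):
    """Read the first frame of an extended XYZ file.

    Returns ``(species_codes, pos, box, step)``.
    """
    with open(path) as fh:
        n = int(fh.readline())
        header = fh.readline()
        box = None
        step = 0
        for tok in header.replace('"', " ").split():
            if tok.startswith("step="):
                step = int(tok[5:])
        if "Lattice=" in header:
            lat = header.split('Lattice="')[1].split('"')[0].split()
            box = float(lat[0])
        species = np.empty(n, dtype=np.int8)
        pos = np.empty((n, 3))
        for i in range(n):
            parts = fh.readline().split()
            species[i] = LABEL_TO_CODE[parts[0]]
            pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
    return species, pos, box, step


# ---------------------------------------------------------------------------
# columnar dump (positions + velocities, resumable)
# ---------------------------------------------------------------------------

def write_dump_frame(fh, state: SystemState, step: int) -> None:
    """Append one columnar frame: step id species x y z vx vy vz."""
    fh.write(f"# frame step={step} n={state.n_beads}\n")
    topo = state.topology
    pos = state.wrapped_positions()
    for i in range(state.n_beads):
        x, y, z = (float(v) for v in pos[i])
        vx, vy, vz = (float(v) for v in state.vel[i])
        fh.write(
            f"{step} {i} {LABELS[topo.species[i]]} "
            f"{x!r} {y!r} {z!r} {vx!r} {vy!r} {vz!r}\n"
        )


def read_last_dump_frame(path):
    """Last frame of a columnar dump: ``(step, pos, vel)``."""
    last_header = None
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            if line.startswith("# frame"):
                last_header = (lineno, line)
    if last_header is None:
        raise ValueError(f"no frames in dump {path}")
    lineno, header = last_header
    step = int(header.split("step=")[1].split()[0])
    n = int(header.split("n=")[1].split()[0])
    pos = np.empty((n, 3))
    vel = np.empty((n, 3))
    with open(path) as fh:
        for _ in range(lineno + 1):
            next(fh)
        for i in range(n):
            parts = fh.readline().split()
            pos[i] = [float(p) for p in parts[3:6]]
            vel[i] = [float(p) for p in parts[6:9]]
    return step, pos, vel


# ---------------------------------------------------------------------------
# topology JSON
# ---------------------------------------------------------------------------

def topology_to_json(topo: Topology, box: float | None = None) -> str:
    data = {
        "units": UNITS_COMMENT,
        "species": topo.species.tolist(),
        "bonds": topo.bonds.tolist(),
        "mol_id": topo.mol_id.tolist(),
        "mol_kind": topo.mol_kind.tolist(),
        "rigid_start": topo.rigid_start.tolist(),
        "rigid_size": topo.rigid_size.tolist(),
        "rigid_reference": (
            topo.rigid_reference.tolist()
            if topo.rigid_reference is not None
            else None
        ),
    }
    if box is not None:
        data["box"] = box
    return json.dumps(data)


def topology_from_json(text: str) -> Topology:
    data = json.loads(text)
    ref = data.get("rigid_reference")
    return Topology(
        species=np.array(data["species"], dtype=np.int8),
        bonds=np.array(data["bonds"], dtype=np.int64).reshape(-1, 2),
        mol_id=np.array(data["mol_id"], dtype=np.int64),
        mol_kind=np.array(data["mol_kind"], dtype=np.int8),
        rigid_start=np.array(data["rigid_start"], dtype=np.int64),
        rigid_size=np.array(data["rigid_size"], dtype=np.int64),
        rigid_reference=np.array(ref) if ref is not None else None,
    )


def save_topology(topo: Topology, path, box: float | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(topology_to_json(topo, box))


def load_topology(path) -> Topology:
    with open(path) as fh:
        return topology_from_json(fh.read())


def load_state(xyz_path, topology_path) -> SystemState:
    """Rebuild a SystemState from an XYZ frame plus its topology JSON."""
    species, pos, box, _ = read_xyz(xyz_path)
    with open(topology_path) as fh:
        data = json.loads(fh.read())
    topo = topology_from_json(json.dumps(data))
    if not np.array_equal(species, topo.species):
        raise ValueError("XYZ species do not match topology")
    if box is None:
        box = data.get("box")
    return SystemState(pos=pos, vel=np.zeros_like(pos), box=float(box),
                       topology=topo)


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def write_thermo_csv(path, rows, config_hash: str = "") -> None:
    """Observable log: step, temperature, E_bond, E_elec_real, E_elec_recip."""
    fields = ["step", "temperature", "E_bond", "E_elec_real", "E_elec_recip"]
    with open(path, "w", newline="") as fh:
        fh.write(f"# {UNITS_COMMENT}; config={config_hash}\n")
        w = csv.DictWriter(fh, fieldnames=fields)
        w.writeheader()
        for row in rows:
            w.writerow({k: row[k] for k in fields})


def write_distribution_csv(path, dist, config_hash: str = "") -> None:
    """AS distribution table: AS, N_frac, Fw."""
    with open(path, "w", newline="") as fh:
        fh.write(
            f"# {UNITS_COMMENT}; <AS>n={dist.mean_number}; "
            f"config={config_hash}\n"
        )
        w = csv.writer(fh)
        w.writerow(["AS", "N_frac", "Fw"])
        for s, nf, wf in zip(dist.support, dist.number_fraction,
                             dist.weight_fraction):
            w.writerow([int(s), repr(float(nf)), repr(float(wf))])


def write_series_csv(path, series, config_hash: str = "") -> None:
    """Solubilization series: step, N_P, f_P."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# {UNITS_COMMENT}; config={config_hash}\n")
        w = csv.writer(fh)
        w.writerow(["step", "N_P", "f_P"])
        for s, n, f in zip(series.steps, series.n_solubilized,
                           series.fraction):
            w.writerow([int(s), int(n), repr(float(f))])


def write_profile_csv(path, profile, config_hash: str = "") -> None:
    """RDP table: r_mid then one density column per species."""
    names = list(profile.density)
    with open(path, "w", newline="") as fh:
        fh.write(
            f"# {UNITS_COMMENT}; {profile.selection}; "
            f"n_samples={profile.n_samples}; skipped={profile.n_skipped}; "
            f"config={config_hash}\n"
        )
        w = csv.writer(fh)
        w.writerow(["r_mid"] + names)
        for b in range(len(profile.r_mid)):
            w.writerow(
                [repr(float(profile.r_mid[b]))]
                + [repr(float(profile.density[n][b])) for n in names]
            )


def write_cluster_report_json(path, report, config_hash: str = "") -> None:
    data = {
        "units": UNITS_COMMENT,
        "config": config_hash,
        "step": int(report.step),
        "labels": report.labels.tolist(),
        "n_plus": report.n_plus.tolist(),
        "n_minus": report.n_minus.tolist(),
        "n_porph": report.n_porph.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(data, fh)
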