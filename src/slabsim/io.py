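"""File I/O: trajectories (XYZ/PDB/DCD/XTC), tables, profiles, and fits.

Standard trajectory formats go through MDAnalysis; XYZ and PDB writers are
plain-text and self-contained so fixtures stay human-readable. Internal
length unit is nm; PDB/DCD/XTC use Angstrom on disk.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .contacts import ContactMap
from .engine import Frame, Topology, Trajectory
from .phase import CoexistenceCurve, CriticalFit, DensityProfile

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_pdb",
    "write_trajectory",
    "load_trajectory",
    "profile_to_tsv",
    "profile_from_tsv",
    "curve_to_tsv",
    "curve_from_tsv",
    "fit_to_json",
    "contact_map_to_tsv",
    "contact_map_from_tsv",
    "save_checkpoint",
    "load_checkpoint",
]


def write_xyz(traj: Trajectory, path, symbols=None) -> None:
    """Plain XYZ with the box on the comment line (nm)."""
    n = traj.positions.shape[1]
    symbols = symbols if symbols is not None else ["C"] * n
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{n}\n")
            bx = traj.box
            fh.write(
                f"box {bx[0]:.6f} {bx[1]:.6f} {bx[2]:.6f} "
                f"time {traj.times[f]:.6f}\n"
            )
            for s, (x, y, z) in zip(symbols, traj.positions[f]):
                fh.write(f"{s} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path) -> Trajectory:
    frames, times = [], []
    box = None
    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line.strip():
                break
            n = int(line)
            meta = fh.readline().split()
            box = np.array([float(meta[1]), float(meta[2]), float(meta[3])])
            t = float(meta[5]) if len(meta) > 5 else float(len(times))
            pos = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            frames.append(pos)
            times.append(t)
    if not frames:
        raise ValueError(f"no frames in {path}")
    return Trajectory(np.stack(frames), box, np.array(times))


def write_pdb(topology: Topology, frame: Frame, path) -> None:
    """One CA-like pseudo-atom per bead, chains lettered A, B, C, ..."""
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
    pos = frame.positions * 10.0  # nm -> Angstrom
    bx = frame.box * 10.0
    with open(path, "w") as fh:
        fh.write(
            f"CRYST1{bx[0]:9.3f}{bx[1]:9.3f}{bx[2]:9.3f}"
            f"  90.00  90.00  90.00 P 1           1\n"
        )
        serial = 0
        for ci, (sl, ch) in enumerate(zip(topology.chain_slices(), topology.chains)):
            cid = letters[ci % len(letters)]
            for k, i in enumerate(range(sl.start, sl.stop)):
                serial += 1
                code = ch.residues[k]
                fh.write(
                    f"ATOM  {serial % 100000:5d}  CA  {code:>3s} {cid}"
                    f"{(k + 1) % 10000:4d}    "
                    f"{pos[i, 0]:8.3f}{pos[i, 1]:8.3f}{pos[i, 2]:8.3f}"
                    f"  1.00  0.00\n"
                )
            fh.write("TER\n")
        fh.write("END\n")


def write_trajectory(traj: Trajectory, path) -> None:
    """Write coordinates as DCD or XTC (by extension) via MDAnalysis."""
    import MDAnalysis as mda

    n = traj.positions.shape[1]
    u = mda.Universe.empty(n, trajectory=True)
    with mda.Writer(str(path), n) as w:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.positions[f] * 10.0
            u.dimensions = [*(traj.box * 10.0), 90.0, 90.0, 90.0]
            u.trajectory.ts.time = traj.times[f]
            w.write(u.atoms)


def load_trajectory(topology_path, coords_path=None) -> Trajectory:
    """Read PDB/GRO (+ XTC/DCD) into a Trajectory (Angstrom -> nm)."""
    import MDAnalysis as mda

    if coords_path is None:
        u = mda.Universe(str(topology_path))
    else:
        u = mda.Universe(str(topology_path), str(coords_path))
    frames, times = [], []
    box = None
    for ts in u.trajectory:
        frames.append(u.atoms.positions / 10.0)
        times.append(float(ts.time))
        if ts.dimensions is not None:
            box = np.asarray(ts.dimensions[:3], float) / 10.0
    if box is None or not np.all(box > 0):
        raise ValueError("trajectory has no box information")
    return Trajectory(np.stack(frames), box, np.array(times))


# ---------------------------------------------------------------------------
# tabular outputs


def _write_tsv(path, header_meta: dict, columns: dict) -> None:
    with open(path, "w") as fh:
        for k, v in header_meta.items():
            fh.write(f"# {k} = {v}\n")
        keys = list(columns)
        fh.write("\t".join(keys) + "\n")
        arrs = [np.asarray(columns[k]) for k in keys]
        for row in zip(*arrs):
            fh.write("\t".join(f"{x:.10g}" for x in row) + "\n")


def _read_tsv(path):
    meta, rows, header = {}, [], None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                k, _, v = line[1:].partition("=")
                meta[k.strip()] = v.strip()
            elif header is None:
                header = line.split()
            else:
                rows.append([float(x) for x in line.split()])
    data = np.array(rows)
    return meta, header, data


def profile_to_tsv(profile: DensityProfile, path) -> None:
    _write_tsv(
        path,
        {
            "axis": profile.axis,
            "bin_width_nm": profile.bin_width,
            **profile.metadata,
        },
        {
            "bin_center_nm": profile.bin_centers,
            "density_mg_per_mL": profile.values,
            "sem": profile.sem,
        },
    )


def profile_from_tsv(path) -> DensityProfile:
    meta, _, data = _read_tsv(path)
    return DensityProfile(
        bin_centers=data[:, 0],
        values=data[:, 1],
        axis=meta.get("axis", "z"),
        bin_width=float(meta.get("bin_width_nm", data[1, 0] - data[0, 0])),
        sem=data[:, 2],
        metadata={k: v for k, v in meta.items() if k not in ("axis", "bin_width_nm")},
    )


def curve_to_tsv(curve: CoexistenceCurve, path) -> None:
    n = curve.temperatures.size
    _write_tsv(
        path,
        {"kind": "coexistence_curve"},
        {
            "temperature_K": curve.temperatures,
            "rho_dilute": curve.rho_l,
            "rho_dense": curve.rho_h,
            "sem_dilute": curve.sem_l if curve.sem_l is not None else np.zeros(n),
            "sem_dense": curve.sem_h if curve.sem_h is not None else np.zeros(n),
        },
    )


def curve_from_tsv(path) -> CoexistenceCurve:
    _, _, data = _read_tsv(path)
    return CoexistenceCurve(
        temperatures=data[:, 0],
        rho_l=data[:, 1],
        rho_h=data[:, 2],
        sem_l=data[:, 3],
        sem_h=data[:, 4],
    )


def fit_to_json(fit: CriticalFit, path) -> None:
    payload = {
        "Tc_K": fit.Tc,
        "B": fit.B,
        "beta": fit.beta,
        "rho_c": fit.rho_c,
        "C_per_K": fit.C,
        "residual_norm": fit.residual_norm,
        "covariance": None if fit.covariance is None else fit.covariance.tolist(),
        "warning": fit.warning,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def contact_map_to_tsv(cmap: ContactMap, path) -> None:
    """Matrix as TSV plus a JSON sidecar with provenance."""
    path = Path(path)
    np.savetxt(path, cmap.matrix, delimiter="\t", fmt="%.8g")
    sidecar = {
        "cutoff_rule": cmap.cutoff_rule,
        "cutoff_value_nm": cmap.cutoff_value,
        "resolution": cmap.resolution,
        "n_frames": cmap.n_frames,
        "n_chain_pairs": cmap.n_chain_pairs,
        "homotypic": cmap.homotypic,
        **cmap.metadata,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def contact_map_from_tsv(path) -> ContactMap:
    path = Path(path)
    matrix = np.loadtxt(path, delimiter="\t", ndmin=2)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ContactMap(
        matrix=matrix,
        cutoff_rule=meta["cutoff_rule"],
        cutoff_value=meta["cutoff_value_nm"],
        resolution=meta["resolution"],
        n_frames=meta["n_frames"],
        n_chain_pairs=meta["n_chain_pairs"],
        homotypic=meta["homotypic"],
    )


def save_checkpoint(path, positions, velocities, step: int, seed: int, box) -> None:
    np.savez(
        path,
        positions=positions,
        velocities=velocities,
        step=np.array([step]),
        seed=np.array([seed]),
        box=np.asarray(box),
    )


def load_checkpoint(path) -> dict:
    with np.load(path) as d:
        return {
            "positions": d["positions"],
            "velocities": d["velocities"],
            "step": int(d["step"][0]),
            "seed": int(d["seed"][0]),
            "box": d["box"],
        }
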