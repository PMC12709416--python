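"""Residue-level implicit-solvent model and Langevin dynamics in slab geometry.

Energy model
------------
Beads (one per residue) interact through three terms:

* bonded: harmonic springs between consecutive beads,
  ``U(r) = k/2 (r - l)^2`` with ``k = 8368 kJ/mol/nm^2``, ``l = 0.38 nm``;
* Ashbaugh-Hatch: a Lennard-Jones potential whose attractive part is scaled
  by the pair stickiness ``lambda_ij`` while the repulsive core is
  lambda-independent, truncated at ``rc_lj = 2.0 nm``;
* Debye-Hueckel: screened Coulomb with screening length 1 nm and relative
  dielectric 80, truncated at 4.0 nm.

Pair parameters are arithmetic means of per-residue sigma and lambda.
Units: nm, ps, K, kJ/mol, g/mol, elementary charges.

Dynamics use a BAOAB Langevin splitting; the default per-bead friction
(0.01 ps^-1) is deliberately small for fast diffusive sampling and is a
tunable of the thermostat, not of the physical model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .params import ParameterTable, SequenceRecord

KB = 0.00831446261815324  # kJ/mol/K
COULOMB = 138.935458  # kJ mol^-1 nm e^-2

# model constants of the bonded / Ashbaugh-Hatch terms
BOND_K = 8368.0  # kJ/mol/nm^2
BOND_L = 0.38  # nm
AH_EPS = 0.8368  # kJ/mol

_R_FLOOR = 1e-3  # nm; below this a nonbonded pair is treated as singular

__all__ = [
    "KB",
    "COULOMB",
    "BOND_K",
    "BOND_L",
    "AH_EPS",
    "Topology",
    "Frame",
    "Trajectory",
    "SimulationConfig",
    "EnergyReport",
    "SingularityError",
    "DivergenceError",
    "PackingError",
    "bonded_energy",
    "ah_potential",
    "dh_potential",
    "total_energy_forces",
    "minimize_energy",
    "langevin_run",
    "build_slab_system",
    "kinetic_temperature",
]


class SingularityError(FloatingPointError):
    """A nonbonded pair distance fell below the positivity floor."""


class DivergenceError(FloatingPointError):
    """Non-finite coordinates appeared during integration."""

    def __init__(self, step: int):
        super().__init__(f"non-finite coordinates at step {step}")
        self.step = step


class PackingError(RuntimeError):
    """Random chain placement failed within the retry budget."""


# ---------------------------------------------------------------------------
# topology / frames


@dataclass(frozen=True)
class Topology:
    """Bead-chain topology with per-bead parameters resolved.

    Beads are ordered chain by chain; bonds connect consecutive beads within
    a chain only.
    """

    chains: tuple[SequenceRecord, ...]
    sigma: np.ndarray  # (n,) nm
    lam: np.ndarray  # (n,)
    charge: np.ndarray  # (n,) e
    mass: np.ndarray  # (n,) g/mol
    chain_index: np.ndarray  # (n,) int

    @classmethod
    def from_chains(
        cls,
        chains: Sequence[SequenceRecord],
        table: ParameterTable,
        termini_charged: bool = True,
        his_charge: float = 0.0,
    ) -> "Topology":
        from .params import assign_charges

        sig, lamv, q, m, cid = [], [], [], [], []
        for k, ch in enumerate(chains):
            s, l, _, mm = table.arrays(ch.residues)
            sig.append(s)
            lamv.append(l)
            m.append(mm)
            q.append(assign_charges(ch, table, termini_charged, his_charge))
            cid.append(np.full(len(ch), k, dtype=np.int64))
        return cls(
            chains=tuple(chains),
            sigma=np.concatenate(sig),
            lam=np.concatenate(lamv),
            charge=np.concatenate(q),
            mass=np.concatenate(m),
            chain_index=np.concatenate(cid),
        )

    @property
    def n_beads(self) -> int:
        return self.sigma.size

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def bonds(self) -> np.ndarray:
        """(n_bonds, 2) indices of consecutive same-chain bead pairs."""
        i = np.arange(self.n_beads - 1)
        same = self.chain_index[i] == self.chain_index[i + 1]
        return np.stack([i[same], i[same] + 1], axis=1)

    def chain_slices(self) -> list[slice]:
        out, start = [], 0
        for ch in self.chains:
            out.append(slice(start, start + len(ch)))
            start += len(ch)
        return out


@dataclass
class Frame:
    """One configuration: positions (nm), orthorhombic box (nm), time (ps)."""

    positions: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ValueError("box must be three positive edge lengths")


@dataclass
class Trajectory:
    """Stacked frames with a constant orthorhombic box."""

    positions: np.ndarray  # (F, n, 3) nm
    box: np.ndarray  # (3,) nm
    times: np.ndarray  # (F,) ps

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.times = np.asarray(self.times, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> Frame:
        return Frame(self.positions[i], self.box, float(self.times[i]))

    def slice_frames(self, sl: slice) -> "Trajectory":
        return Trajectory(self.positions[sl], self.box, self.times[sl])

    @classmethod
    def from_frames(cls, frames: Sequence[Frame]) -> "Trajectory":
        return cls(
            np.stack([f.positions for f in frames]),
            np.asarray(frames[0].box, float),
            np.array([f.time for f in frames]),
        )


@dataclass
class SimulationConfig:
    """Integration and interaction settings."""

    temperature: float = 300.0  # K
    timestep: float = 10.0  # fs
    n_steps: int = 10_000
    friction: float = 0.01  # ps^-1
    seed: int = 0
    rc_lj: float = 2.0  # nm
    rc_elec: float = 4.0  # nm
    debye_length: float = 1.0  # nm
    dielectric: float = 80.0
    shift_at_cutoff: bool = False
    save_every: int = 1000  # steps between saved frames

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction < 0 or self.temperature < 0:
            raise ValueError("friction and temperature must be non-negative")

    def validate_box(self, box: np.ndarray) -> None:
        half = float(np.min(box)) / 2.0
        if max(self.rc_lj, self.rc_elec) > half + 1e-12:
            raise ValueError(
                f"cutoffs ({self.rc_lj}, {self.rc_elec}) exceed half the "
                f"smallest box edge ({half})"
            )


@dataclass(frozen=True)
class EnergyReport:
    bonded: float
    ashbaugh_hatch: float
    electrostatic: float

    @property
    def total(self) -> float:
        return self.bonded + self.ashbaugh_hatch + self.electrostatic


# ---------------------------------------------------------------------------
# scalar potentials (reference semantics; the MD kernels replicate these)


def bonded_energy(r: float, k: float = BOND_K, l: float = BOND_L) -> float:
    """Harmonic bond energy (kJ/mol) at separation r (nm)."""
    if r < 0:
        raise ValueError("negative separation")
    return 0.5 * k * (r - l) ** 2


def _ulj(r: float, sigma: float, eps: float = AH_EPS) -> float:
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def ah_potential(
    r: float,
    sigma_ij: float,
    lam_ij: float,
    eps: float = AH_EPS,
    rc_lj: float = 2.0,
    shift_at_cutoff: bool = False,
) -> float:
    """Ashbaugh-Hatch pair energy (kJ/mol).

    For ``r <= 2^(1/6) sigma``: ``U_LJ + eps (1 - lambda)``; for larger r up
    to the cutoff: ``lambda U_LJ``; zero beyond. With ``shift_at_cutoff``,
    ``lambda U_LJ(rc)`` is subtracted inside the cutoff so the energy is
    continuous at rc.
    """
    if r <= 0:
        raise ValueError("separation must be positive")
    if r > rc_lj:
        return 0.0
    shift = lam_ij * _ulj(rc_lj, sigma_ij, eps) if shift_at_cutoff else 0.0
    if r <= 2.0 ** (1.0 / 6.0) * sigma_ij:
        return _ulj(r, sigma_ij, eps) + eps * (1.0 - lam_ij) - shift
    return lam_ij * _ulj(r, sigma_ij, eps) - shift


def dh_potential(
    r: float,
    qi: float,
    qj: float,
    debye_length: float = 1.0,
    dielectric: float = 80.0,
    rc_elec: float = 4.0,
    shift_at_cutoff: bool = False,
) -> float:
    """Debye-Hueckel screened-Coulomb pair energy (kJ/mol)."""
    if r <= 0:
        raise ValueError("separation must be positive")
    if r > rc_elec:
        return 0.0
    u = COULOMB * qi * qj / (dielectric * r) * math.exp(-r / debye_length)
    if shift_at_cutoff:
        u -= COULOMB * qi * qj / (dielectric * rc_elec) * math.exp(
            -rc_elec / debye_length
        )
    return u


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _pair_energy_force(
    r, sigma, lam, qq, rc_lj, rc_elec, ldebye, dielectric, shift
):
    """Return (u_ah, u_dh, f_over_r) for one nonbonded pair at distance r."""
    u_ah = 0.0
    u_dh = 0.0
    f = 0.0  # magnitude of -dU/dr
    if r <= rc_lj:
        sr6 = (sigma / r) ** 6
        ulj = 4.0 * AH_EPS * (sr6 * sr6 - sr6)
        dulj = 4.0 * AH_EPS * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
        if r <= 1.122462048309373 * sigma:
            u_ah = ulj + AH_EPS * (1.0 - lam)
            f -= dulj
        else:
            u_ah = lam * ulj
            f -= lam * dulj
        if shift:
            src6 = (sigma / rc_lj) ** 6
            u_ah -= lam * 4.0 * AH_EPS * (src6 * src6 - src6)
    if qq != 0.0 and r <= rc_elec:
        u = COULOMB * qq / (dielectric * r) * math.exp(-r / ldebye)
        u_dh = u
        f += u * (1.0 / r + 1.0 / ldebye)
        if shift:
            u_dh -= COULOMB * qq / (dielectric * rc_elec) * math.exp(
                -rc_elec / ldebye
            )
    return u_ah, u_dh, f / r


@njit(cache=True)
def _energy_forces(
    pos, box, sigma, lam, charge, chain_id,
    rc_lj, rc_elec, ldebye, dielectric, shift,
):
    """All-pairs energies and forces with minimum-image convention.

    Returns (e_bond, e_ah, e_dh, forces, status); status 1 flags a
    nonbonded pair below the positivity floor.
    """
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    e_bond = 0.0
    e_ah = 0.0
    e_dh = 0.0
    status = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box[0] * np.rint(dx / box[0])
            dy -= box[1] * np.rint(dy / box[1])
            dz -= box[2] * np.rint(dz / box[2])
            r2 = dx * dx + dy * dy + dz * dz
            bonded = (j == i + 1) and (chain_id[i] == chain_id[j])
            if bonded:
                r = math.sqrt(r2)
                if r < 1e-9:
                    status = 1
                    continue
                e_bond += 0.5 * BOND_K * (r - BOND_L) ** 2
                fr = -BOND_K * (r - BOND_L) / r  # (-dU/dr)/r
                forces[i, 0] += fr * dx
                forces[i, 1] += fr * dy
                forces[i, 2] += fr * dz
                forces[j, 0] -= fr * dx
                forces[j, 1] -= fr * dy
                forces[j, 2] -= fr * dz
                continue
            rc_max = rc_elec if rc_elec > rc_lj else rc_lj
            if r2 > rc_max * rc_max:
                continue
            r = math.sqrt(r2)
            if r < 1e-3:
                status = 1
                continue
            sij = 0.5 * (sigma[i] + sigma[j])
            lij = 0.5 * (lam[i] + lam[j])
            qq = charge[i] * charge[j]
            u_ah, u_dh, f_over_r = _pair_energy_force(
                r, sij, lij, qq, rc_lj, rc_elec, ldebye, dielectric, shift
            )
            e_ah += u_ah
            e_dh += u_dh
            forces[i, 0] += f_over_r * dx
            forces[i, 1] += f_over_r * dy
            forces[i, 2] += f_over_r * dz
            forces[j, 0] -= f_over_r * dx
            forces[j, 1] -= f_over_r * dy
            forces[j, 2] -= f_over_r * dz
    return e_bond, e_ah, e_dh, forces, status


@njit(cache=True)
def _run_baoab(
    pos, vel, box, sigma, lam, charge, chain_id, mass,
    dt, gamma, kT, n_steps, save_every, seed,
    rc_lj, rc_elec, ldebye, dielectric, shift,
):
    """BAOAB Langevin integration; saves every ``save_every`` steps.

    Returns (saved_pos, saved_vel, diag, fail_step). diag holds per-step
    averages of kinetic temperature and bond energy; fail_step >= 0 marks
    divergence.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    n_saved = n_steps // save_every
    saved_pos = np.zeros((n_saved, n, 3))
    saved_vel = np.zeros((n_saved, n, 3))
    c1 = math.exp(-gamma * dt)
    c2v = np.empty(n)
    for i in range(n):
        c2v[i] = math.sqrt(kT / mass[i] * (1.0 - c1 * c1))
    eb, ea, ed, forces, status = _energy_forces(
        pos, box, sigma, lam, charge, chain_id,
        rc_lj, rc_elec, ldebye, dielectric, shift,
    )
    if status != 0:
        diag = np.zeros(2)
        return saved_pos[:0], saved_vel[:0], diag, 0
    acc_T = 0.0
    acc_bond = 0.0
    ndof = 3.0 * n
    isave = 0
    fail_step = -1
    for step in range(n_steps):
        # B
        for i in range(n):
            inv_m = dt * 0.5 / mass[i]
            vel[i, 0] += forces[i, 0] * inv_m
            vel[i, 1] += forces[i, 1] * inv_m
            vel[i, 2] += forces[i, 2] * inv_m
        # A
        for i in range(n):
            pos[i, 0] += vel[i, 0] * dt * 0.5
            pos[i, 1] += vel[i, 1] * dt * 0.5
            pos[i, 2] += vel[i, 2] * dt * 0.5
        # O
        for i in range(n):
            vel[i, 0] = c1 * vel[i, 0] + c2v[i] * np.random.normal()
            vel[i, 1] = c1 * vel[i, 1] + c2v[i] * np.random.normal()
            vel[i, 2] = c1 * vel[i, 2] + c2v[i] * np.random.normal()
        # A
        for i in range(n):
            pos[i, 0] += vel[i, 0] * dt * 0.5
            pos[i, 1] += vel[i, 1] * dt * 0.5
            pos[i, 2] += vel[i, 2] * dt * 0.5
        eb, ea, ed, forces, status = _energy_forces(
            pos, box, sigma, lam, charge, chain_id,
            rc_lj, rc_elec, ldebye, dielectric, shift,
        )
        # B
        for i in range(n):
            inv_m = dt * 0.5 / mass[i]
            vel[i, 0] += forces[i, 0] * inv_m
            vel[i, 1] += forces[i, 1] * inv_m
            vel[i, 2] += forces[i, 2] * inv_m
        ke = 0.0
        for i in range(n):
            ke += 0.5 * mass[i] * (
                vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            )
        if status != 0 or not math.isfinite(ke + eb + ea + ed):
            fail_step = step + 1
            break
        acc_T += 2.0 * ke / (ndof * KB)
        acc_bond += eb
        if (step + 1) % save_every == 0:
            ok = True
            for i in range(n):
                for d in range(3):
                    if not math.isfinite(pos[i, d]):
                        ok = False
            if not ok:
                fail_step = step + 1
                break
            for i in range(n):
                for d in range(3):
                    saved_pos[isave, i, d] = pos[i, d]
                    saved_vel[isave, i, d] = vel[i, d]
            isave += 1
    diag = np.empty(2)
    n_done = float(step + 1) if fail_step >= 0 else float(n_steps)
    diag[0] = acc_T / n_done
    diag[1] = acc_bond / n_done
    return saved_pos[:isave], saved_vel[:isave], diag, fail_step


# ---------------------------------------------------------------------------
# public operations


def total_energy_forces(
    frame: Frame, topology: Topology, config: SimulationConfig
) -> tuple[EnergyReport, np.ndarray]:
    """Energies (bonded / Ashbaugh-Hatch / electrostatic) and forces.

    Bonded pairs contribute only the harmonic term (they are excluded from
    the nonbonded sums); all other pairs within the cutoffs contribute the
    Ashbaugh-Hatch and Debye-Hueckel terms under minimum image.
    """
    config.validate_box(frame.box)
    eb, ea, ed, forces, status = _energy_forces(
        np.ascontiguousarray(frame.positions, dtype=np.float64),
        np.asarray(frame.box, dtype=np.float64),
        topology.sigma,
        topology.lam,
        topology.charge,
        topology.chain_index,
        config.rc_lj,
        config.rc_elec,
        config.debye_length,
        config.dielectric,
        config.shift_at_cutoff,
    )
    if status:
        raise SingularityError(
            f"nonbonded pair closer than {_R_FLOOR} nm positivity floor"
        )
    return EnergyReport(eb, ea, ed), forces


def minimize_energy(
    frame: Frame,
    topology: Topology,
    config: SimulationConfig,
    n_iter: int = 500,
    max_disp: float = 0.02,
    force_tol: float = 1e3,
) -> Frame:
    """Displacement-capped steepest descent to relax packing overlaps.

    Moves along the force with the largest per-bead displacement capped at
    ``max_disp`` nm per iteration; stops when the maximum force magnitude
    falls below ``force_tol`` kJ/mol/nm. Intended to precede dynamics on
    randomly packed systems.
    """
    pos = np.array(frame.positions, dtype=np.float64)
    for _ in range(n_iter):
        eb, ea, ed, forces, status = _energy_forces(
            pos, np.asarray(frame.box, np.float64),
            topology.sigma, topology.lam, topology.charge,
            topology.chain_index,
            config.rc_lj, config.rc_elec, config.debye_length,
            config.dielectric, config.shift_at_cutoff,
        )
        fmag = np.sqrt((forces**2).sum(axis=1))
        fmax = float(fmag.max())
        if fmax < force_tol:
            break
        pos += forces * (max_disp / fmax)
    return Frame(pos, frame.box, frame.time)


@dataclass
class RunResult:
    """Trajectory plus end state and run diagnostics."""

    trajectory: Trajectory
    final_positions: np.ndarray
    final_velocities: np.ndarray
    mean_kinetic_temperature: float  # K, averaged over every step
    mean_bond_energy: float  # kJ/mol, averaged over every step


def langevin_run(
    frame: Frame,
    topology: Topology,
    config: SimulationConfig,
    velocities: np.ndarray | None = None,
) -> RunResult:
    """Integrate Langevin dynamics; deterministic for a given seed.

    Initial velocities default to a Maxwell-Boltzmann draw at the target
    temperature (zero at T = 0). Frames are saved every
    ``config.save_every`` steps.
    """
    config.validate_box(frame.box)
    pos = np.array(frame.positions, dtype=np.float64)
    rng = np.random.default_rng(config.seed)
    if velocities is None:
        if config.temperature > 0:
            scale = np.sqrt(KB * config.temperature / topology.mass)
            velocities = rng.normal(size=pos.shape) * scale[:, None]
        else:
            velocities = np.zeros_like(pos)
    vel = np.array(velocities, dtype=np.float64)
    dt_ps = config.timestep * 1e-3
    saved_pos, saved_vel, diag, fail_step = _run_baoab(
        pos, vel, np.asarray(frame.box, dtype=np.float64),
        topology.sigma, topology.lam, topology.charge,
        topology.chain_index, topology.mass,
        dt_ps, config.friction, KB * config.temperature,
        config.n_steps, config.save_every,
        int(config.seed) % (2**31 - 1),
        config.rc_lj, config.rc_elec, config.debye_length,
        config.dielectric, config.shift_at_cutoff,
    )
    if fail_step >= 0:
        raise DivergenceError(fail_step)
    times = frame.time + dt_ps * config.save_every * np.arange(
        1, saved_pos.shape[0] + 1
    )
    traj = Trajectory(saved_pos, np.asarray(frame.box, float), times)
    return RunResult(
        trajectory=traj,
        final_positions=pos,
        final_velocities=vel,
        mean_kinetic_temperature=float(diag[0]),
        mean_bond_energy=float(diag[1]),
    )


def kinetic_temperature(velocities: np.ndarray, mass: np.ndarray) -> float:
    """Instantaneous kinetic temperature (K) from velocities (nm/ps)."""
    ke = 0.5 * np.sum(mass[:, None] * velocities**2)
    return 2.0 * ke / (3.0 * velocities.shape[0] * KB)


def build_slab_system(
    topology: Topology,
    box: Sequence[float],
    seed: int = 0,
    min_separation: float = 0.4,
    max_retries: int = 2000,
    slab_width: float | None = None,
) -> Frame:
    """Place chains randomly in the box as equilibrium-bond random walks.

    No two beads of different chains end up closer than ``min_separation``
    under minimum image; non-neighbour beads within a chain keep a
    self-avoidance distance of 0.8 x ``min_separation``. With
    ``slab_width``, chain starting points are confined to a central slab of
    that z-extent — the standard initialization for coexistence runs, which
    lets the dilute phase fill by evaporation.
    """
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []
    occupied = np.zeros((0, 3))

    def _min_image_dist(pts_a: np.ndarray, pts_b: np.ndarray) -> float:
        d = pts_a[:, None, :] - pts_b[None, :, :]
        d -= box * np.round(d / box)
        return float(np.sqrt((d**2).sum(axis=2)).min())

    for sl, ch in zip(topology.chain_slices(), topology.chains):
        n = len(ch)
        for attempt in range(max_retries):
            start = rng.random(3) * box
            if slab_width is not None:
                start[2] = box[2] / 2.0 + (rng.random() - 0.5) * slab_width
            pts = np.empty((n, 3))
            pts[0] = start
            ok = True
            for i in range(1, n):
                for _ in range(50):
                    step = rng.normal(size=3)
                    step *= BOND_L / np.linalg.norm(step)
                    cand = pts[i - 1] + step
                    d = pts[: max(0, i - 1)] - cand
                    if d.size:
                        d -= box * np.round(d / box)
                        if np.sqrt((d**2).sum(axis=1)).min() < 0.8 * min_separation:
                            continue
                    pts[i] = cand
                    break
                else:
                    ok = False
                    break
            if not ok:
                continue
            if occupied.size and _min_image_dist(pts, occupied) < min_separation:
                continue
            placed.append(pts)
            occupied = np.vstack([occupied, pts])
            break
        else:
            raise PackingError(
                f"could not place chain {ch.id!r} after {max_retries} tries"
            )
    return Frame(np.vstack(placed), box, 0.0)
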