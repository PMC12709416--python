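"""Density profiles, coexistence densities, and critical-point fitting.

A phase-separated slab run yields a z-density profile with a dense central
plateau and dilute outer plateaus. The dense/dilute densities over a
temperature scan form a coexistence curve, fitted by

    drho = B (1 - T/Tc)^beta          (order parameter, beta fixed at 0.325)
    (rho_h + rho_l)/2 = rho_c + C (Tc - T)   (rectilinear diameter)

which yields the critical temperature Tc, amplitude B, critical density
rho_c and diameter slope C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .engine import Topology, Trajectory

AVOGADRO = 6.02214076e23
BETA_ISING = 0.325  # 3D Ising critical exponent, held fixed in all fits

__all__ = [
    "BETA_ISING",
    "DensityProfile",
    "CoexistenceCurve",
    "CoexistenceDensities",
    "CriticalFit",
    "z_density_profile",
    "radial_density_profile",
    "coexistence_densities",
    "fit_critical_point",
    "chain_concentration",
    "peak_local_density_ratio",
    "center_slab",
]


@dataclass
class DensityProfile:
    """Binned density along z or radially from the system COM."""

    bin_centers: np.ndarray  # nm
    values: np.ndarray  # mg/mL
    axis: str  # "z" | "radial"
    bin_width: float  # nm
    sem: np.ndarray  # mg/mL
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.sem = np.asarray(self.sem, float)
        if np.any(self.values < -1e-12) or np.any(self.sem < -1e-12):
            raise ValueError("densities and SEMs must be non-negative")


@dataclass
class CoexistenceCurve:
    """Dense/dilute densities over temperature."""

    temperatures: np.ndarray  # K, strictly increasing
    rho_l: np.ndarray
    rho_h: np.ndarray
    sem_l: np.ndarray | None = None
    sem_h: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, float)
        self.rho_l = np.asarray(self.rho_l, float)
        self.rho_h = np.asarray(self.rho_h, float)
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(self.rho_h < self.rho_l):
            raise ValueError("rho_h must be >= rho_l pointwise")


@dataclass
class CoexistenceDensities:
    rho_l: float
    rho_h: float
    sem_l: float
    sem_h: float
    phase_separated: bool
    metadata: dict = field(default_factory=dict)


@dataclass
class CriticalFit:
    Tc: float  # K
    B: float
    beta: float
    rho_c: float
    C: float  # density per K
    residual_norm: float
    covariance: np.ndarray | None
    warning: str | None = None


def _mass_per_bin(z, mass, edges, box_z):
    z = np.mod(z, box_z)
    idx = np.clip((z / (edges[1] - edges[0])).astype(int), 0, len(edges) - 2)
    out = np.zeros(len(edges) - 1)
    np.add.at(out, idx, mass)
    return out


def center_slab(traj: Trajectory, mass: np.ndarray, coarse_bin: float = 1.0) -> Trajectory:
    """Translate each frame so the densest z-region sits at the box center.

    The densest coarse bin sets a provisional center; the mass-weighted
    circular mean of beads within a quarter box of it refines the shift.
    Resolves slab wrap-around across the periodic boundary.
    """
    box = traj.box
    lz = box[2]
    n_bins = max(4, int(round(lz / coarse_bin)))
    edges = np.linspace(0.0, lz, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = np.array(traj.positions, copy=True)
    for f in range(traj.n_frames):
        z = np.mod(out[f, :, 2], lz)
        hist = _mass_per_bin(z, mass, edges, lz)
        z0 = centers[int(np.argmax(hist))]
        dz = z - z0
        dz -= lz * np.rint(dz / lz)
        sel = np.abs(dz) <= lz / 4.0
        if sel.any():
            z0 = z0 + np.average(dz[sel], weights=mass[sel])
        out[f, :, 2] = np.mod(z - z0 + lz / 2.0, lz)
    return Trajectory(out, box, traj.times)


def _block_sem(per_frame: np.ndarray, n_blocks: int = 5) -> np.ndarray:
    """SEM across equal trajectory blocks (axis 0 = frames)."""
    f = per_frame.shape[0]
    n_blocks = min(n_blocks, f)
    if n_blocks < 2:
        return np.zeros(per_frame.shape[1:])
    cut = f - f % n_blocks
    blocks = per_frame[:cut].reshape(n_blocks, cut // n_blocks, *per_frame.shape[1:])
    means = blocks.mean(axis=1)
    return means.std(axis=0, ddof=1) / np.sqrt(n_blocks)


def z_density_profile(
    traj: Trajectory,
    topology: Topology,
    bin_width: float = 1.0,
    center: bool = True,
    n_blocks: int = 5,
) -> DensityProfile:
    """Mass density (mg/mL) vs z, averaged over frames.

    With ``center``, frames are first shifted so the densest region maps to
    the box center (required before plateau averaging). SEM is estimated by
    block averaging over ``n_blocks`` equal trajectory blocks.
    """
    box = traj.box
    lz = float(box[2])
    if bin_width >= lz:
        raise ValueError("bin_width must be smaller than the box length")
    if center:
        traj = center_slab(traj, topology.mass)
    n_bins = max(1, int(round(lz / bin_width)))
    edges = np.linspace(0.0, lz, n_bins + 1)
    bin_vol = box[0] * box[1] * (edges[1] - edges[0])  # nm^3
    # mg/mL == g/L; 1 nm^3 = 1e-24 L
    conv = 1.0 / (AVOGADRO * bin_vol * 1e-24)
    per_frame = np.stack(
        [
            _mass_per_bin(traj.positions[f, :, 2], topology.mass, edges, lz) * conv
            for f in range(traj.n_frames)
        ]
    )
    return DensityProfile(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        values=per_frame.mean(axis=0),
        axis="z",
        bin_width=float(edges[1] - edges[0]),
        sem=_block_sem(per_frame, n_blocks),
        metadata={"centered": center, "n_frames": traj.n_frames},
    )


def radial_density_profile(
    traj: Trajectory,
    topology: Topology,
    bin_width: float = 1.0,
    n_blocks: int = 5,
) -> DensityProfile:
    """Mass density (mg/mL) vs distance from the system COM, per shell."""
    box = traj.box
    r_max = float(np.min(box)) / 2.0
    n_bins = max(1, int(np.ceil(r_max / bin_width)))
    edges = bin_width * np.arange(n_bins + 1)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    conv = 1.0 / (AVOGADRO * shell_vol * 1e-24)
    mass = topology.mass
    per_frame = []
    for f in range(traj.n_frames):
        pos = traj.positions[f]
        com = np.average(pos, axis=0, weights=mass)
        d = pos - com
        d -= box * np.rint(d / box)
        r = np.sqrt((d**2).sum(axis=1))
        idx = np.clip((r / bin_width).astype(int), 0, n_bins - 1)
        hist = np.zeros(n_bins)
        np.add.at(hist, idx, mass)
        per_frame.append(hist * conv)
    per_frame = np.stack(per_frame)
    return DensityProfile(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        values=per_frame.mean(axis=0),
        axis="radial",
        bin_width=bin_width,
        sem=_block_sem(per_frame, n_blocks),
        metadata={"n_frames": traj.n_frames},
    )


def coexistence_densities(
    profile: DensityProfile,
    buffer: float = 2.0,
    flat_ratio: float = 2.0,
) -> CoexistenceDensities:
    """Dilute/dense plateau densities from a centered z-profile.

    The dense region is the contiguous stretch around the global maximum
    where the density exceeds the midpoint between the extreme values;
    ``buffer`` (nm) is excluded on each side of each interface before
    averaging. A profile whose plateau ratio falls below ``flat_ratio`` is
    flagged as not phase separated and both densities are the profile mean.
    """
    v = profile.values
    z = profile.bin_centers
    lo, hi = float(v.min()), float(v.max())
    meta = {"buffer_nm": buffer, "flat_ratio": flat_ratio}
    if hi <= flat_ratio * max(lo, 1e-12):
        m = float(v.mean())
        s = float(np.sqrt(np.mean(profile.sem**2) / max(len(v), 1)))
        return CoexistenceDensities(m, m, s, s, False, meta | {"reason": "flat"})
    mid = 0.5 * (lo + hi)
    imax = int(np.argmax(v))
    above = v >= mid
    il = imax
    while il > 0 and above[il - 1]:
        il -= 1
    ir = imax
    while ir < len(v) - 1 and above[ir + 1]:
        ir += 1
    z_left, z_right = z[il], z[ir]
    meta |= {"interface_left_nm": float(z_left), "interface_right_nm": float(z_right)}
    dense_sel = (z >= z_left + buffer) & (z <= z_right - buffer)
    if not dense_sel.any():  # dense slab thinner than the two buffers
        dense_sel = (z >= z_left) & (z <= z_right)
    dilute_sel = (z < z_left - buffer) | (z > z_right + buffer)
    if not dilute_sel.any():
        dilute_sel = ~((z >= z_left) & (z <= z_right))
    if not dilute_sel.any():
        m = float(v.mean())
        s = float(np.sqrt(np.mean(profile.sem**2) / max(len(v), 1)))
        return CoexistenceDensities(m, m, s, s, False, meta | {"reason": "no dilute region"})

    def _plateau(sel):
        mean = float(v[sel].mean())
        sem = float(np.sqrt(np.mean(profile.sem[sel] ** 2) / sel.sum()))
        return mean, sem

    rho_h, sem_h = _plateau(dense_sel)
    rho_l, sem_l = _plateau(dilute_sel)
    return CoexistenceDensities(rho_l, rho_h, sem_l, sem_h, True, meta)


def fit_critical_point(
    curve: CoexistenceCurve, beta: float = BETA_ISING
) -> CriticalFit:
    """Two-stage critical-point fit with the exponent held fixed.

    Stage 1: nonlinear least squares of ``rho_h - rho_l = B (1 - T/Tc)^beta``
    for (B, Tc). Stage 2: ordinary linear fit of the diameter
    ``(rho_h + rho_l)/2`` against ``Tc - T`` for (rho_c, C), with Tc from
    stage 1.
    """
    T = curve.temperatures
    drho = curve.rho_h - curve.rho_l
    ok = drho > 0
    if ok.sum() < 3:
        raise ValueError(
            f"need >= 3 temperatures with rho_h > rho_l, got {int(ok.sum())}"
        )
    T, drho = T[ok], drho[ok]
    diam = 0.5 * (curve.rho_h + curve.rho_l)[ok]
    t_max = float(T.max())

    def resid(p):
        B, Tc = p
        x = 1.0 - T / Tc
        return B * np.sign(x) * np.abs(x) ** beta - drho

    B0 = float(drho.max())
    Tc0 = t_max / (1.0 - (drho.min() / max(B0, 1e-300)) ** (1.0 / beta) + 1e-9)
    Tc0 = max(Tc0, t_max * 1.001)
    sol = least_squares(
        resid,
        x0=[B0, Tc0],
        bounds=([0.0, t_max * (1.0 + 1e-12)], [np.inf, np.inf]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    if not sol.success:
        raise RuntimeError(f"critical fit did not converge: {sol.message}")
    B, Tc = sol.x
    # covariance from the Jacobian (Gauss-Newton approximation)
    try:
        dof = max(len(T) - 2, 1)
        s2 = 2.0 * sol.cost / dof
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
    except np.linalg.LinAlgError:
        cov = None
    x = Tc - T
    A = np.stack([np.ones_like(x), x], axis=1)
    coef, *_ = np.linalg.lstsq(A, diam, rcond=None)
    rho_c, C = float(coef[0]), float(coef[1])
    warning = None
    if C <= 0:
        warning = "diameter slope C is not positive"
        warnings.warn(warning, stacklevel=2)
    return CriticalFit(
        Tc=float(Tc),
        B=float(B),
        beta=beta,
        rho_c=rho_c,
        C=C,
        residual_norm=float(np.sqrt(2.0 * sol.cost)),
        covariance=cov,
        warning=warning,
    )


def peak_local_density_ratio(
    traj: Trajectory,
    topology: Topology,
    radius: float = 2.0,
    last_frames: int = 5,
) -> float:
    """Condensation diagnostic: peak local density over the box mean.

    Local density at a bead counts beads of *other* chains within
    ``radius`` (nm, minimum image), so a single collapsed coil does not
    register as a dense region; the reference is the box-mean density of
    other-chain beads. The median of the per-frame peak over the last
    ``last_frames`` saved frames is returned. Values well above one signal
    a condensed phase; a dispersed system stays within small-number
    fluctuations of one.
    """
    box = traj.box
    vol_sphere = 4.0 / 3.0 * np.pi * radius**3
    n = topology.n_beads
    cid = topology.chain_index
    per_chain = np.bincount(cid)
    ratios = []
    for f in range(max(0, traj.n_frames - last_frames), traj.n_frames):
        pos = traj.positions[f]
        d = pos[:, None, :] - pos[None, :, :]
        d -= box * np.rint(d / box)
        r2 = (d**2).sum(axis=2)
        other = cid[:, None] != cid[None, :]
        counts = ((r2 < radius**2) & other).sum(axis=1)
        # reference: mean density of other-chain beads for each bead's chain
        mean_other = (n - per_chain[cid]) / float(np.prod(box))
        ratios.append(float(np.max(counts / (vol_sphere * mean_other))))
    return float(np.median(ratios))


def chain_concentration(n_chains: int, box: np.ndarray) -> float:
    """Molar concentration (mM) of ``n_chains`` in an orthorhombic box (nm)."""
    box = np.asarray(box, float)
    vol_l = float(np.prod(box)) * 1e-24
    if vol_l <= 0:
        raise ValueError("box volume must be positive")
    return n_chains / (AVOGADRO * vol_l) * 1e3
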