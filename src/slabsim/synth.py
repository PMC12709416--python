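"""Synthetic inputs with known ground truth for every analysis stage.

Each generator is seed-deterministic and emits the same containers the
pipeline consumes, so every stage can be exercised round-trip against the
generating parameters without any external data: homopolymer sequences and
parameter tables, slab trajectories with planted plateau densities,
coexistence curves drawn from the scaling law, contact trajectories with
planted contact probabilities, and sp2/cation/H-bond geometries with
closed-form labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import Topology, Trajectory
from .geometry import AtomisticSystem
from .params import CANONICAL_CODES, ParameterTable, ResidueParams, SequenceRecord
from .phase import AVOGADRO, BETA_ISING, CoexistenceCurve

__all__ = [
    "make_homopolymer",
    "uniform_table",
    "gen_coexistence_data",
    "gen_slab_fixture",
    "gen_contact_fixture",
    "build_pi_fixture",
    "gen_interaction_system",
    "PiFixture",
]


def uniform_table(
    sigma: float = 0.6,
    lam: float = 0.5,
    mass: float = 110.0,
    provenance: str = "synthetic-uniform",
    overrides: dict | None = None,
) -> ParameterTable:
    """A 20-entry table with identical bead parameters everywhere.

    Standard charges (D/E -1, K/R +1) are kept so charge-dependent code
    paths stay exercised; ``overrides`` maps code -> ResidueParams fields.
    """
    charges = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0}
    entries = {
        c: ResidueParams(c, sigma, lam, charges.get(c, 0.0), mass)
        for c in CANONICAL_CODES
    }
    for code, kw in (overrides or {}).items():
        base = entries[code].__dict__ | kw
        entries[code] = ResidueParams(**base)
    return ParameterTable(entries, provenance)


def make_homopolymer(
    n_res: int,
    lam: float,
    sigma: float = 0.6,
    charge: float = 0.0,
    mass: float = 110.0,
    code: str = "A",
    chain_id: str = "homopolymer",
) -> tuple[SequenceRecord, ParameterTable]:
    """A single-letter chain plus a table realizing the stated parameters."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    seq = SequenceRecord(id=chain_id, residues=code * n_res)
    table = uniform_table(
        sigma=sigma,
        lam=lam,
        mass=mass,
        provenance=f"synthetic-homopolymer-{code}",
        overrides={code: {"sigma": sigma, "lam": lam, "charge": charge, "mass": mass}},
    )
    return seq, table


def gen_coexistence_data(
    Tc: float,
    B: float,
    rho_c: float,
    C: float,
    temps: np.ndarray,
    noise_rel: float = 0.0,
    seed: int = 0,
) -> CoexistenceCurve:
    """Coexistence curve drawn from the scaling + rectilinear-diameter laws.

    ``rho_h/l = rho_c + C (Tc - T) +/- B (1 - T/Tc)^beta / 2`` with
    multiplicative Gaussian noise of relative size ``noise_rel``. All
    temperatures must lie below Tc and the dilute branch must stay
    non-negative.
    """
    temps = np.sort(np.asarray(temps, float))
    if np.any(temps >= Tc):
        raise ValueError("all temperatures must be below Tc")
    drho = B * (1.0 - temps / Tc) ** BETA_ISING
    diam = rho_c + C * (Tc - temps)
    rho_l = diam - drho / 2.0
    rho_h = diam + drho / 2.0
    if np.any(rho_l < 0):
        raise ValueError("parameters give a negative dilute density")
    if noise_rel:
        rng = np.random.default_rng(seed)
        rho_l = rho_l * (1.0 + noise_rel * rng.standard_normal(rho_l.size))
        rho_h = rho_h * (1.0 + noise_rel * rng.standard_normal(rho_h.size))
        rho_l = np.clip(rho_l, 0.0, None)
        rho_h = np.maximum(rho_h, rho_l)
    return CoexistenceCurve(temps, rho_l, rho_h)


def _free_beads_topology(n: int, mass: float) -> Topology:
    """One long unbonded pseudo-chain of identical beads (analysis only).

    Built as a single chain, so density analyses see its mass array; no
    dynamics is ever run on it.
    """
    seq = SequenceRecord(id="slab-fixture", residues="A" * n)
    return Topology(
        chains=(seq,),
        sigma=np.full(n, 0.6),
        lam=np.full(n, 0.5),
        charge=np.zeros(n),
        mass=np.full(n, mass),
        chain_index=np.zeros(n, dtype=np.int64),
    )


def gen_slab_fixture(
    rho_dense: float,
    rho_dilute: float,
    box: tuple[float, float, float] = (10.0, 10.0, 60.0),
    slab_halfwidth: float = 10.0,
    interface_width: float = 0.0,
    n_frames: int = 1,
    bead_mass: float = 100.0,
    seed: int = 0,
    fine_bin: float = 0.25,
) -> tuple[Trajectory, Topology]:
    """Slab trajectory with planted dense/dilute densities (mg/mL).

    The target profile is a two-sided sigmoid (a sharp step when
    ``interface_width`` is 0) centered in z. Bead counts per fine bin are
    deterministic (rounded expectations), so recovered plateaus match the
    targets up to rounding; xy positions are uniform random.
    """
    box = np.asarray(box, float)
    lz = box[2]
    n_bins = int(round(lz / fine_bin))
    edges = np.linspace(0, lz, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    z0 = lz / 2.0
    if interface_width > 0:
        w = interface_width
        prof = rho_dilute + (rho_dense - rho_dilute) * (
            1.0 / (1.0 + np.exp((np.abs(centers - z0) - slab_halfwidth) / w))
        )
    else:
        prof = np.where(
            np.abs(centers - z0) <= slab_halfwidth, rho_dense, rho_dilute
        )
    bin_vol = box[0] * box[1] * (edges[1] - edges[0])
    expected = prof * AVOGADRO * bin_vol * 1e-24 / bead_mass
    # cumulative rounding keeps every plateau average at its target even
    # when the expected count per fine bin is below one
    cum = np.rint(np.cumsum(expected))
    counts = np.diff(np.concatenate([[0.0], cum])).astype(int)
    n = int(counts.sum())
    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, n, 3))
    for f in range(n_frames):
        z = np.repeat(centers, counts)
        z = z + (rng.random(n) - 0.5) * (edges[1] - edges[0])
        xy = rng.random((n, 2)) * box[:2]
        frames[f, :, 0] = xy[:, 0]
        frames[f, :, 1] = xy[:, 1]
        frames[f, :, 2] = z
    traj = Trajectory(frames, box, np.arange(n_frames, dtype=float))
    return traj, _free_beads_topology(n, bead_mass)


def gen_contact_fixture(
    p_matrix: np.ndarray,
    n_frames: int,
    cutoff: float = 0.5,
    seed: int = 0,
    seq_a: str | None = None,
    seq_b: str | None = None,
) -> tuple[Trajectory, Topology]:
    """Two-chain trajectory whose contact map converges to ``p_matrix``.

    Per frame, each residue of chain B independently draws a partner in
    chain A from the categorical distribution given by its column of
    ``p_matrix`` (or no partner), and is placed inside the cutoff of that
    partner and outside everyone else's; the marginal contact probability
    of every pair is then exactly ``p_ij``. This requires every column to
    sum to <= 1. The all-ones matrix is realized exactly by co-locating
    both chains inside one cutoff ball. Bead sigmas are chosen so the
    calvados rule reproduces the same cutoff.
    """
    p = np.asarray(p_matrix, float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    n_a, n_b = p.shape
    seq_a = seq_a or "A" * n_a
    seq_b = seq_b or "A" * n_b
    if (len(seq_a), len(seq_b)) != (n_a, n_b):
        raise ValueError("sequence lengths must match p_matrix shape")
    all_ones = np.all(p == 1.0)
    col_ok = np.all(p.sum(axis=0) <= 1.0 + 1e-12)
    if not (all_ones or col_ok):
        raise ValueError(
            "p_matrix not geometrically realizable: columns must sum to <= 1 "
            "(or the matrix must be all ones)"
        )
    s = 4.0 * cutoff
    n_max = max(n_a, n_b)
    box = np.array([(n_max + 4) * s, 6.0 * s, 6.0 * s])
    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, n_a + n_b, 3))
    if all_ones:
        tiny = 0.1 * cutoff / max(n_a + n_b, 1)
        for f in range(n_frames):
            for i in range(n_a):
                frames[f, i] = (s + i * tiny, s, s)
            for j in range(n_b):
                frames[f, n_a + j] = (s + j * tiny, s, s + 0.3 * cutoff)
    else:
        probs = np.vstack([p, 1.0 - p.sum(axis=0)])  # (n_a + 1, n_b)
        probs = np.clip(probs, 0.0, None)
        for f in range(n_frames):
            for i in range(n_a):
                frames[f, i] = (s + i * s, s, s)
            for j in range(n_b):
                partner = rng.choice(n_a + 1, p=probs[:, j] / probs[:, j].sum())
                if partner < n_a:
                    frames[f, n_a + j] = (s + partner * s, s, s + 0.5 * cutoff)
                else:
                    frames[f, n_a + j] = (s + j * s, 3.5 * s, s)
    traj = Trajectory(frames, box, np.arange(n_frames, dtype=float))
    sigma = cutoff / 2.0 ** (1.0 / 6.0)
    rec_a = SequenceRecord(id="chainA", residues=seq_a)
    rec_b = SequenceRecord(id="chainB", residues=seq_b)
    topo = Topology(
        chains=(rec_a, rec_b),
        sigma=np.full(n_a + n_b, sigma),
        lam=np.full(n_a + n_b, 0.5),
        charge=np.zeros(n_a + n_b),
        mass=np.full(n_a + n_b, 110.0),
        chain_index=np.concatenate(
            [np.zeros(n_a, dtype=np.int64), np.ones(n_b, dtype=np.int64)]
        ),
    )
    return traj, topo


# ---------------------------------------------------------------------------
# pi-geometry fixtures


def _hexagon(radius: float = 0.14) -> np.ndarray:
    ang = np.radians(np.arange(6) * 60.0)
    return np.stack(
        [radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)], axis=1
    )


def _rot_x(deg: float) -> np.ndarray:
    t = math.radians(deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


@dataclass
class PiFixture:
    """Constructed geometry plus its closed-form expected classification."""

    kind: str  # "cation" | "sp2" | "hbond"
    coords: dict  # named coordinate arrays, nm
    expected: bool
    geometry: dict = field(default_factory=dict)


def build_pi_fixture(
    separation: float,
    tilt: float = 0.0,
    lateral_offset: float = 0.0,
    kind: str = "sp2",
) -> PiFixture:
    """Ideal phenol-ring + partner geometry with a closed-form label.

    The label is computed directly from the construction parameters (not by
    running the detectors): distances and cosines follow from the placement
    by elementary geometry.

    * ``cation``: a charged nitrogen at distance ``separation`` from the ring
      center, tilted ``tilt`` degrees off the ring normal, then shifted
      laterally in-plane by ``lateral_offset``.
    * ``sp2``: a guanidinium plane with COM at height ``separation`` over the
      ring center (plus lateral offset), its normal tilted by ``tilt``.
    * ``hbond``: a donor N at distance ``separation`` from the acceptor, with
      the hydrogen placed so the D-H...A angle is ``180 - tilt`` degrees.
    """
    ring = _hexagon()
    if kind == "cation":
        t = math.radians(tilt)
        n_pos = np.array(
            [lateral_offset + separation * math.sin(t), 0.0, separation * math.cos(t)]
        )
        dist = float(np.linalg.norm(n_pos))
        cos = abs(n_pos[2]) / dist if dist > 0 else 1.0
        expected = dist < 0.6 and cos > 0.8
        return PiFixture(
            kind, {"ring": ring, "nitrogen": n_pos}, expected,
            {"distance": dist, "abs_cos": cos},
        )
    if kind == "sp2":
        com = np.array([lateral_offset, 0.0, separation])
        local = np.array(
            [[0.0, 0.0, 0.0], [0.13, 0.0, 0.0], [-0.065, 0.1126, 0.0],
             [-0.065, -0.1126, 0.0]]
        )  # CZ, NE, NH1, NH2 in-plane
        guan = (local @ _rot_x(tilt).T) + com
        normal_g = _rot_x(tilt) @ np.array([0.0, 0.0, 1.0])
        d_com = float(np.linalg.norm(com))
        cos = abs(float(normal_g[2]))
        # elevate each plane toward the other and re-measure the COM distance
        u_ring = np.array([0.0, 0.0, 1.0 if com[2] >= 0 else -1.0])
        u_g = normal_g if float(np.dot(normal_g, -com)) >= 0 else -normal_g
        p_r = 0.15 * u_ring
        p_g = com + 0.15 * u_g
        d_elev = float(np.linalg.norm(p_g - p_r))
        expected = d_com < 0.8 and cos > 0.8 and d_elev < 0.4
        return PiFixture(
            kind, {"ring": ring, "guanidinium": guan}, expected,
            {"com_distance": d_com, "abs_cos": cos, "elevated_distance": d_elev},
        )
    if kind == "hbond":
        acceptor = np.zeros(3)
        donor = np.array([0.0, 0.0, separation])
        t = math.radians(tilt)
        # hydrogen 0.1 nm from the donor, tilted off the D->A axis
        h = donor + 0.1 * np.array([math.sin(t), 0.0, -math.cos(t)])
        v1, v2 = donor - h, acceptor - h
        ang = math.degrees(
            math.acos(
                float(np.clip(
                    np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                    -1.0, 1.0,
                ))
            )
        )
        expected = separation <= 0.35 and ang >= 150.0
        return PiFixture(
            kind, {"donor": donor, "hydrogen": h, "acceptor": acceptor},
            expected, {"da_distance": separation, "angle_deg": ang},
        )
    raise ValueError(f"unknown fixture kind {kind!r}")


def gen_interaction_system(
    n_frames: int = 10,
    cation_pi_frames: tuple[int, ...] = (0, 1, 2, 3),
    hbond_frames: tuple[int, ...] = (0, 1),
    resname: str = "ARG",
) -> AtomisticSystem:
    """One Arg/Lys + one Tyr with scripted per-frame interaction status.

    In frames listed in ``cation_pi_frames`` the cation group stacks over
    the Tyr ring (which for Arg also satisfies the sp2 criterion); in
    ``hbond_frames`` (must be cation-pi frames to be observable in the
    conditional statistic) the Tyr backbone O additionally sits collinear
    with an N-H donor. Everything is deterministic.
    """
    hbond_frames = tuple(hbond_frames)
    cation_pi_frames = tuple(cation_pi_frames)
    ring_c = np.array([3.0, 3.0, 3.0])
    ring = _hexagon() + ring_c
    if resname == "ARG":
        cat_names = ["CZ", "NE", "NH1", "NH2", "HH11"]
        local = np.array(
            [[0.0, 0.0, 0.0], [0.13, 0.0, 0.0], [-0.065, 0.1126, 0.0],
             [-0.065, -0.1126, 0.0], [0.0, 0.0, 0.0]]  # HH11 placed per frame
        )
    elif resname == "LYS":
        cat_names = ["NZ", "HZ1"]
        local = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
    else:
        raise ValueError("resname must be ARG or LYS")
    tyr_names = list(TYR_RING_NAMES) + ["O"]
    names = cat_names + tyr_names
    n_cat = len(cat_names)
    frames = []
    for f in range(n_frames):
        pos = np.zeros((len(names), 3))
        if f in cation_pi_frames:
            cat_com = ring_c + np.array([0.0, 0.0, 0.35])
        else:
            cat_com = ring_c + np.array([3.0, 0.0, 0.0])
        pos[:n_cat] = local + cat_com
        pos[n_cat : n_cat + 6] = ring
        if f in hbond_frames:
            # acceptor O 0.30 nm from NH1 along +y, H collinear in between
            if resname == "ARG":
                nh1 = pos[3]
            else:
                nh1 = pos[0]
            direction = np.array([0.0, 1.0, 0.0])
            pos[-1] = nh1 + 0.30 * direction
            h_idx = 4 if resname == "ARG" else 1
            pos[h_idx] = nh1 + 0.10 * direction
        else:
            pos[-1] = ring_c + np.array([0.0, 2.0, 0.0])
            h_idx = 4 if resname == "ARG" else 1
            pos[h_idx] = pos[0] + np.array([0.0, 0.05, 0.05])
        frames.append(pos)
    traj = Trajectory(
        np.stack(frames), np.array([50.0, 50.0, 50.0]),
        np.arange(n_frames, dtype=float),
    )
    return AtomisticSystem(
        names=np.array(names, dtype=object),
        resnames=np.array([resname] * n_cat + ["TYR"] * len(tyr_names), dtype=object),
        resids=np.array([1] * n_cat + [2] * len(tyr_names)),
        chains=np.array(["A"] * n_cat + ["B"] * len(tyr_names), dtype=object),
        trajectory=traj,
    )


TYR_RING_NAMES = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
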