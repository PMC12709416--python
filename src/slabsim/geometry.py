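"""Geometric detection of cation-pi, sp2-pi and hydrogen-bond interactions,
their (conditional) percentage statistics, and Donnan-style ion partitioning.

Criteria
--------
cation-pi (Arg/Lys nitrogen N vs. aromatic ring):
    |N - ring COM| < 0.6 nm  and  |cos(angle(N - COM, ring normal))| > 0.8.
sp2-pi (guanidinium plane vs. ring plane):
    COM distance < 0.8 nm, |cos(angle between normals)| > 0.8, and after
    displacing each plane's COM 0.15 nm along its normal (oriented toward
    the other plane), displaced-COM distance < 0.4 nm.
hydrogen bond (donor heavy atom D, its hydrogen H, acceptor A):
    |D - A| <= 0.35 nm  and  angle(D-H...A) >= 150 deg; a heavy-atom-only
    fallback (distance gate alone) serves hydrogen-free inputs.

Ion partitioning: within each bin carrying net protein charge concentration
Delta = c_cationic - c_anionic (mM of charges) in bulk salt c0, local
electroneutrality plus a fixed activity product give
    anion = (Delta + sqrt(Delta^2 + 4 c0^2)) / 2,  cation = c0^2 / anion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .engine import Trajectory

__all__ = [
    "PiPlane",
    "InteractionRecord",
    "IonProfile",
    "AtomisticSystem",
    "ring_plane",
    "detect_cation_pi",
    "detect_sp2_pi",
    "detect_hbond",
    "interaction_percentages",
    "predict_ion_profiles",
]

CATION_PI_DIST = 0.6  # nm
CATION_PI_COS = 0.8
SP2_PI_COM_DIST = 0.8  # nm
SP2_PI_COS = 0.8
SP2_PI_ELEVATION = 0.15  # nm
SP2_PI_ELEV_DIST = 0.4  # nm
HBOND_DA_DIST = 0.35  # nm
HBOND_ANGLE = 150.0  # degrees

#: charged-nitrogen atom names evaluated per cation residue; a pair counts
#: as cation-pi if any nitrogen passes (charge delocalization over the
#: guanidinium). Configurable via the ``cation_atoms`` argument.
CATION_NITROGENS = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",)}
TYR_RING_ATOMS = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
GUANIDINIUM_ATOMS = ("CZ", "NE", "NH1", "NH2")
#: donor N -> attached hydrogen names for the hydrogen-bond detector
ARG_DONOR_H = {"NE": ("HE",), "NH1": ("HH11", "HH12"), "NH2": ("HH21", "HH22")}
LYS_DONOR_H = {"NZ": ("HZ1", "HZ2", "HZ3")}


@dataclass(frozen=True)
class PiPlane:
    """A planar sp2 group: member coordinates, centroid, unit normal."""

    member_coords: np.ndarray  # (m, 3) nm
    com: np.ndarray  # (3,)
    normal: np.ndarray  # (3,), |normal| = 1


@dataclass(frozen=True)
class InteractionRecord:
    frame: int
    pair: tuple  # ((chain, resid) cation/sp2 partner, (chain, resid) Tyr)
    kind: str  # "cation_pi" | "sp2_pi" | "hbond"
    geometry: dict


@dataclass
class IonProfile:
    bin_centers: np.ndarray  # nm
    protein_cation_conc: np.ndarray  # mM
    protein_anion_conc: np.ndarray  # mM
    predicted_cation: np.ndarray  # mM
    predicted_anion: np.ndarray  # mM
    bulk_salt: float  # mM


def ring_plane(coords: np.ndarray) -> PiPlane:
    """Best-fit plane of >= 3 non-collinear points (SVD of the centered set).

    The normal sign is arbitrary here; pairwise detectors orient it as
    needed.
    """
    coords = np.asarray(coords, float)
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 points to define a plane")
    com = coords.mean(axis=0)
    centered = coords - com
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-10 * max(s[0], 1e-30):
        raise ValueError("degenerate geometry: points are collinear")
    return PiPlane(member_coords=coords, com=com, normal=vt[2])


def detect_cation_pi(n_coord: np.ndarray, ring: PiPlane) -> tuple[bool, dict]:
    """Distance + ring-normal alignment gate for a single charged nitrogen."""
    v = np.asarray(n_coord, float) - ring.com
    dist = float(np.linalg.norm(v))
    if dist < 1e-12:
        return True, {"distance": dist, "abs_cos": 1.0}
    cos = float(abs(np.dot(v / dist, ring.normal)))
    hit = dist < CATION_PI_DIST and cos > CATION_PI_COS
    return hit, {"distance": dist, "abs_cos": cos}


def detect_sp2_pi(
    guanidinium: PiPlane,
    ring: PiPlane,
    elevation_mode: str = "toward",
) -> tuple[bool, dict]:
    """Stacking gate between two sp2 planes.

    ``elevation_mode="toward"`` (default) displaces each COM along its
    normal oriented toward the other plane's COM — the stacked geometry;
    ``"fixed"`` displaces along the stored normals as-is.
    """
    d_com = float(np.linalg.norm(guanidinium.com - ring.com))
    cos = float(abs(np.dot(guanidinium.normal, ring.normal)))
    if elevation_mode == "toward":
        to_ring = ring.com - guanidinium.com
        n_g = guanidinium.normal * np.sign(np.dot(guanidinium.normal, to_ring) or 1.0)
        n_r = ring.normal * np.sign(np.dot(ring.normal, -to_ring) or 1.0)
    elif elevation_mode == "fixed":
        n_g, n_r = guanidinium.normal, ring.normal
    else:
        raise ValueError(f"unknown elevation_mode {elevation_mode!r}")
    p_g = guanidinium.com + SP2_PI_ELEVATION * n_g
    p_r = ring.com + SP2_PI_ELEVATION * n_r
    d_elev = float(np.linalg.norm(p_g - p_r))
    hit = d_com < SP2_PI_COM_DIST and cos > SP2_PI_COS and d_elev < SP2_PI_ELEV_DIST
    return hit, {"com_distance": d_com, "abs_cos": cos, "elevated_distance": d_elev}


def detect_hbond(
    donor_heavy: np.ndarray,
    donor_h: np.ndarray | None,
    acceptor: np.ndarray,
) -> tuple[bool, dict]:
    """Donor-acceptor distance and D-H...A angle gate.

    With ``donor_h=None`` only the heavy-atom distance gate applies
    (fallback for structures without hydrogens).
    """
    d = np.asarray(donor_heavy, float)
    a = np.asarray(acceptor, float)
    da = float(np.linalg.norm(d - a))
    geom = {"da_distance": da}
    if da > HBOND_DA_DIST:
        return False, geom
    if donor_h is None:
        geom["angle_deg"] = np.nan
        return True, geom
    h = np.asarray(donor_h, float)
    v1 = d - h
    v2 = a - h
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        return False, geom
    ang = float(np.degrees(np.arccos(np.clip(np.dot(v1 / n1, v2 / n2), -1, 1))))
    geom["angle_deg"] = ang
    return ang >= HBOND_ANGLE, geom


# ---------------------------------------------------------------------------
# atomistic containers and selections


@dataclass
class AtomisticSystem:
    """Named atoms plus coordinates: the input of the trajectory detectors."""

    names: np.ndarray  # (n,) atom names
    resnames: np.ndarray  # (n,)
    resids: np.ndarray  # (n,) int
    chains: np.ndarray  # (n,) chain labels
    trajectory: Trajectory  # positions in nm

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype=object)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.chains = np.asarray(self.chains, dtype=object)

    @classmethod
    def from_mdanalysis(cls, universe) -> "AtomisticSystem":
        """Build from an MDAnalysis Universe (Angstrom -> nm)."""
        ag = universe.atoms
        frames = []
        times = []
        for ts in universe.trajectory:
            frames.append(ag.positions / 10.0)
            times.append(float(ts.time))
        box = universe.dimensions[:3] / 10.0 if universe.dimensions is not None else None
        if box is None or not np.all(np.asarray(box) > 0):
            span = np.ptp(frames[0], axis=0)
            box = span + 100.0  # effectively non-periodic
        traj = Trajectory(np.stack(frames), np.asarray(box, float), np.array(times))
        chains = getattr(ag, "chainIDs", None)
        if chains is None:
            chains = ag.segids
        return cls(ag.names, ag.resnames, ag.resids, chains, traj)

    def residues(self) -> list[tuple]:
        """Unique (chain, resid, resname) triples in order of appearance."""
        seen, out = set(), []
        for c, r, n in zip(self.chains, self.resids, self.resnames):
            key = (c, int(r))
            if key not in seen:
                seen.add(key)
                out.append((c, int(r), n))
        return out

    def atom_index(self, chain, resid: int, name: str) -> int | None:
        sel = (
            (self.chains == chain)
            & (self.resids == resid)
            & (self.names == name)
        )
        idx = np.flatnonzero(sel)
        return int(idx[0]) if idx.size else None


def select_residues(system: AtomisticSystem, expr: str) -> list[tuple]:
    """Tiny selection grammar over residues.

    Space-separated clauses joined by ``and``: ``resname NAME[,NAME...]``,
    ``resid N`` or ``resid N-M``, ``chain C[,C...]``. Example:
    ``"resname ARG,LYS and chain A"``.
    """
    clauses = [c.strip() for c in expr.split(" and ")]
    out = []
    for chain, resid, resname in system.residues():
        ok = True
        for cl in clauses:
            parts = cl.split()
            if len(parts) != 2:
                raise ValueError(f"cannot parse selection clause {cl!r}")
            key, val = parts
            if key == "resname":
                ok &= resname in val.split(",")
            elif key == "resid":
                if "-" in val:
                    a, b = val.split("-")
                    ok &= int(a) <= resid <= int(b)
                else:
                    ok &= resid == int(val)
            elif key == "chain":
                ok &= str(chain) in val.split(",")
            else:
                raise ValueError(f"unknown selection keyword {key!r}")
        if ok:
            out.append((chain, resid, resname))
    return out


@dataclass
class InteractionSummary:
    cation_pi_pct: float
    sp2_pi_pct: float
    hbond_given_cation_pi_pct: float  # NaN when no cation-pi events
    n_observations: int
    n_cation_pi: int
    conditional_defined: bool
    records: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


def _pair_frame_eval(
    system: AtomisticSystem,
    pos: np.ndarray,
    cat: tuple,
    tyr: tuple,
    cation_atoms: dict,
    use_hydrogens: bool,
) -> tuple[bool, bool, bool]:
    c_chain, c_resid, c_resname = cat
    t_chain, t_resid, _ = tyr
    ring_idx = [system.atom_index(t_chain, t_resid, a) for a in TYR_RING_ATOMS]
    if any(i is None for i in ring_idx):
        raise ValueError(f"Tyr residue {tyr} lacks ring atoms")
    ring = ring_plane(pos[ring_idx])

    n_names = cation_atoms.get(c_resname, ())
    cpi = False
    for nm in n_names:
        i = system.atom_index(c_chain, c_resid, nm)
        if i is not None and detect_cation_pi(pos[i], ring)[0]:
            cpi = True
            break

    sp2 = False
    guan_idx = [system.atom_index(c_chain, c_resid, a) for a in GUANIDINIUM_ATOMS]
    if all(i is not None for i in guan_idx):
        sp2 = detect_sp2_pi(ring_plane(pos[guan_idx]), ring)[0]

    hbond = False
    acc_i = system.atom_index(t_chain, t_resid, "O")  # Tyr backbone carbonyl
    if acc_i is not None:
        donor_h = ARG_DONOR_H if c_resname == "ARG" else LYS_DONOR_H
        for d_name, h_names in donor_h.items():
            d_i = system.atom_index(c_chain, c_resid, d_name)
            if d_i is None:
                continue
            h_found = False
            for h_name in h_names:
                h_i = system.atom_index(c_chain, c_resid, h_name)
                if h_i is not None:
                    h_found = True
                    if use_hydrogens and detect_hbond(pos[d_i], pos[h_i], pos[acc_i])[0]:
                        hbond = True
            if not h_found or not use_hydrogens:
                if detect_hbond(pos[d_i], None, pos[acc_i])[0]:
                    hbond = True
            if hbond:
                break
    return cpi, sp2, hbond


def interaction_percentages(
    system: AtomisticSystem,
    cation_selection: str = "resname ARG,LYS",
    aromatic_selection: str = "resname TYR",
    cation_atoms: dict | None = None,
    use_hydrogens: bool = True,
    keep_records: bool = False,
) -> InteractionSummary:
    """Per-kind interaction percentages over all (frame, pair) observations.

    The hydrogen-bond percentage is conditional: it is computed only over
    observations that already form the cation-pi interaction. With zero
    cation-pi events the conditional is undefined (NaN, flagged).
    """
    cation_atoms = cation_atoms or CATION_NITROGENS
    cats = select_residues(system, cation_selection)
    tyrs = select_residues(system, aromatic_selection)
    if not cats or not tyrs:
        raise ValueError("empty cation or aromatic selection")
    traj = system.trajectory
    n_obs = 0
    n_cpi = 0
    n_sp2 = 0
    n_hb_given_cpi = 0
    records: list[InteractionRecord] = []
    for f in range(traj.n_frames):
        pos = traj.positions[f]
        for cat in cats:
            for tyr in tyrs:
                cpi, sp2, hbond = _pair_frame_eval(
                    system, pos, cat, tyr, cation_atoms, use_hydrogens
                )
                n_obs += 1
                n_cpi += cpi
                n_sp2 += sp2
                if cpi:
                    n_hb_given_cpi += hbond
                if keep_records:
                    pair = ((cat[0], cat[1]), (tyr[0], tyr[1]))
                    for kind, hit in (
                        ("cation_pi", cpi),
                        ("sp2_pi", sp2),
                        ("hbond", cpi and hbond),
                    ):
                        if hit:
                            records.append(
                                InteractionRecord(f, pair, kind, {})
                            )
    cond_defined = n_cpi > 0
    return InteractionSummary(
        cation_pi_pct=100.0 * n_cpi / n_obs,
        sp2_pi_pct=100.0 * n_sp2 / n_obs,
        hbond_given_cation_pi_pct=(
            100.0 * n_hb_given_cpi / n_cpi if cond_defined else float("nan")
        ),
        n_observations=n_obs,
        n_cation_pi=n_cpi,
        conditional_defined=cond_defined,
        records=records,
        metadata={
            "cation_atoms": {k: list(v) for k, v in cation_atoms.items()},
            "use_hydrogens": use_hydrogens,
        },
    )


def predict_ion_profiles(
    protein_cation_conc: np.ndarray,
    protein_anion_conc: np.ndarray,
    bulk_salt: float,
    bin_centers: np.ndarray | None = None,
) -> IonProfile:
    """Monovalent salt partitioning from local charged-residue content.

    Per bin with net protein charge concentration
    ``Delta = c_cationic - c_anionic`` (mM) and bulk salt ``c0`` (mM):
    electroneutrality ``cation + Delta = anion`` and activity product
    ``cation * anion = c0^2`` give the closed form above. An excess of mobile
    anions therefore tracks the sign of the protein's net positive charge.
    """
    if bulk_salt <= 0:
        raise ValueError("bulk_salt must be positive")
    cp = np.asarray(protein_cation_conc, float)
    cm = np.asarray(protein_anion_conc, float)
    delta = cp - cm
    anion = 0.5 * (delta + np.sqrt(delta**2 + 4.0 * bulk_salt**2))
    cation = bulk_salt**2 / anion
    if bin_centers is None:
        bin_centers = np.arange(cp.size, dtype=float)
    return IonProfile(
        bin_centers=np.asarray(bin_centers, float),
        protein_cation_conc=cp,
        protein_anion_conc=cm,
        predicted_cation=cation,
        predicted_anion=anion,
        bulk_salt=float(bulk_salt),
    )
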