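"""Inter-chain contact maps and their 1D / region / residue-type reductions.

A contact map holds, for every residue pair (i in species A, j in species B),
the probability that the pair is within a cutoff, averaged over all
inter-chain pairs and frames. Two cutoff rules are supported:

* ``"calvados"`` — the pair-specific bead-overlap distance ``2^(1/6) sigma_ij``
  (arithmetic-mean sigma), natural for one-bead-per-residue trajectories;
* ``"fixed"`` — a single distance in nm; for multi-particle residues the
  residue-residue distance is the minimum over constituent particles.

Distances use the minimum-image convention, since slab systems span the box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import pearsonr

from .engine import Topology, Trajectory
from .params import CANONICAL_CODES, ParameterTable, Region, SequenceRecord

__all__ = [
    "ContactMap",
    "ResidueTypeMap",
    "interchain_contact_map",
    "project_1d",
    "region_average",
    "residue_type_map",
    "lambda_contact_correlation",
]


@dataclass
class ContactMap:
    matrix: np.ndarray  # (nA, nB) probabilities
    cutoff_rule: str  # "calvados" | "fixed"
    cutoff_value: float | None  # nm, for the fixed rule
    resolution: str
    n_frames: int
    n_chain_pairs: int
    homotypic: bool
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            raise ValueError("contact probabilities must lie in [0, 1]")
        self.matrix = np.clip(m, 0.0, 1.0)


def _min_image_dists(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    d -= box * np.rint(d / box)
    return np.sqrt((d**2).sum(axis=2))


def interchain_contact_map(
    traj: Trajectory,
    topology: Topology,
    params: ParameterTable | None = None,
    rule: str = "calvados",
    cutoff: float | None = None,
    species_a: Sequence[int] | None = None,
    species_b: Sequence[int] | None = None,
    resolution: str = "residue-bead",
) -> ContactMap:
    """Contact probabilities between residues of two chain species.

    ``species_a`` / ``species_b`` list chain indices; both default to all
    chains (the homotypic case, which requires >= 2 chains and yields a
    symmetrized map). The calvados rule derives per-pair cutoffs from bead
    sigmas; the fixed rule uses ``cutoff`` nm.
    """
    if rule not in ("calvados", "fixed"):
        raise ValueError(f"unknown cutoff rule {rule!r}")
    if rule == "fixed" and (cutoff is None or cutoff <= 0):
        raise ValueError("fixed rule needs a positive cutoff")
    if resolution not in ("residue-bead", "near-atomic", "atomistic"):
        raise ValueError(f"unknown resolution {resolution!r}")
    slices = topology.chain_slices()
    all_chains = list(range(topology.n_chains))
    homotypic = species_a is None and species_b is None
    a_idx = list(species_a) if species_a is not None else all_chains
    b_idx = list(species_b) if species_b is not None else all_chains
    if homotypic and len(all_chains) < 2:
        raise ValueError("homotypic contact map needs at least two chains")
    n_a = len(topology.chains[a_idx[0]])
    n_b = len(topology.chains[b_idx[0]])
    for k in a_idx:
        if len(topology.chains[k]) != n_a:
            raise ValueError("species A chains differ in length")
    for k in b_idx:
        if len(topology.chains[k]) != n_b:
            raise ValueError("species B chains differ in length")

    if rule == "calvados":
        sig_a = topology.sigma[slices[a_idx[0]]]
        sig_b = topology.sigma[slices[b_idx[0]]]
        cut = 2.0 ** (1.0 / 6.0) * 0.5 * (sig_a[:, None] + sig_b[None, :])
    else:
        cut = float(cutoff)

    pairs = [(a, b) for a in a_idx for b in b_idx if a != b]
    if not pairs:
        raise ValueError("no inter-chain pairs between the two species")
    box = traj.box
    acc = np.zeros((n_a, n_b))
    for f in range(traj.n_frames):
        pos = traj.positions[f]
        for a, b in pairs:
            d = _min_image_dists(pos[slices[a]], pos[slices[b]], box)
            acc += d < cut
    mat = acc / (len(pairs) * traj.n_frames)
    if homotypic:
        mat = 0.5 * (mat + mat.T)
    return ContactMap(
        matrix=mat,
        cutoff_rule=rule,
        cutoff_value=cutoff,
        resolution=resolution,
        n_frames=traj.n_frames,
        n_chain_pairs=len(pairs),
        homotypic=homotypic,
    )


def project_1d(cmap: ContactMap, axis: str = "A") -> np.ndarray:
    """Relative contact probability per residue: mean over the other axis."""
    if axis not in ("A", "B"):
        raise ValueError("axis must be 'A' or 'B'")
    return cmap.matrix.mean(axis=1 if axis == "A" else 0)


def region_average(
    cmap: ContactMap,
    regions_a: Sequence[Region],
    regions_b: Sequence[Region],
    offset_a: int = 1,
    offset_b: int = 1,
) -> np.ndarray:
    """Block matrix of mean contact probability per region pair.

    Regions use parent-protein numbering; ``offset_a``/``offset_b`` give the
    number of the first map row/column. Regions on one axis must neither
    overlap nor leave the map bounds.
    """

    def _indices(regions, offset, n):
        idx = []
        seen = np.zeros(n, dtype=bool)
        for r in regions:
            i0, i1 = r.start - offset, r.end - offset + 1
            if i0 < 0 or i1 > n:
                raise IndexError(f"region {r.name!r} outside map bounds")
            if seen[i0:i1].any():
                raise ValueError(f"region {r.name!r} overlaps another region")
            seen[i0:i1] = True
            idx.append(slice(i0, i1))
        return idx

    ia = _indices(regions_a, offset_a, cmap.matrix.shape[0])
    ib = _indices(regions_b, offset_b, cmap.matrix.shape[1])
    out = np.empty((len(ia), len(ib)))
    for i, sa in enumerate(ia):
        for j, sb in enumerate(ib):
            out[i, j] = cmap.matrix[sa, sb].mean()
    return out


@dataclass
class ResidueTypeMap:
    """20x20 contact statistics by amino-acid type (symmetric)."""

    matrix: np.ndarray  # (20, 20); NaN where no position pair exists
    pair_counts: np.ndarray  # (20, 20) number of position pairs
    normalized: bool
    codes: str = CANONICAL_CODES

    def value(self, a: str, b: str) -> float:
        i, j = self.codes.index(a), self.codes.index(b)
        return float(self.matrix[i, j])

    def count(self, a: str, b: str) -> int:
        i, j = self.codes.index(a), self.codes.index(b)
        return int(self.pair_counts[i, j])


def residue_type_map(
    cmap: ContactMap,
    seq_a: SequenceRecord,
    seq_b: SequenceRecord,
    normalized: bool = True,
) -> ResidueTypeMap:
    """Aggregate a positional contact map by amino-acid type.

    The unnormalized entry for a type pair sums matrix entries over all
    position pairs of that type combination (both orientations for distinct
    types); normalization divides by the number of such position pairs.
    Absent type pairs are NaN, never divided by zero.
    """
    if (len(seq_a), len(seq_b)) != cmap.matrix.shape:
        raise ValueError(
            f"sequence lengths {(len(seq_a), len(seq_b))} do not match map "
            f"shape {cmap.matrix.shape}"
        )
    n_types = len(CANONICAL_CODES)
    t_a = np.array([CANONICAL_CODES.index(c) for c in seq_a.residues])
    t_b = np.array([CANONICAL_CODES.index(c) for c in seq_b.residues])
    sums = np.zeros((n_types, n_types))
    counts = np.zeros((n_types, n_types))
    np.add.at(sums, (t_a[:, None], t_b[None, :]), cmap.matrix)
    np.add.at(counts, (t_a[:, None], t_b[None, :]), 1.0)
    # fold both orientations into a symmetric matrix
    sums_sym = sums + sums.T - np.diag(np.diag(sums))
    counts_sym = counts + counts.T - np.diag(np.diag(counts))
    if normalized:
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = np.where(counts_sym > 0, sums_sym / counts_sym, np.nan)
    else:
        mat = np.where(counts_sym > 0, sums_sym, np.nan)
    return ResidueTypeMap(
        matrix=mat, pair_counts=counts_sym.astype(int), normalized=normalized
    )


def lambda_contact_correlation(
    typemap: ResidueTypeMap,
    params: ParameterTable,
    score: str = "mean",
) -> float:
    """Pearson r between type-pair contact probability and pair stickiness.

    The pair stickiness score defaults to the model's own combination rule,
    the arithmetic mean ``(lam_i + lam_j)/2``; ``score="product_half"``
    uses ``lam_i * lam_j / 2`` instead. Only type pairs present in the
    sequences (pair_counts > 0) enter the correlation.
    """
    if not typemap.normalized:
        raise ValueError("correlation requires a normalized type map")
    if score not in ("mean", "product_half"):
        raise ValueError(f"unknown score {score!r}")
    lam = np.array([params[c].lam for c in typemap.codes])
    if score == "mean":
        sc = 0.5 * (lam[:, None] + lam[None, :])
    else:
        sc = 0.5 * lam[:, None] * lam[None, :]
    iu = np.triu_indices(len(typemap.codes))
    x, y = sc[iu], typemap.matrix[iu]
    ok = (typemap.pair_counts[iu] > 0) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 type pairs with observations")
    return float(pearsonr(x[ok], y[ok]).statistic)
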