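"""Desk-scale study protocols combining engine and analysis stages.

These are the canonical small-system experiments the package uses to probe
phase behavior on a single CPU in minutes: a 10-chain, 50-bead homopolymer
in an 8 x 8 x 24 nm slab. The full-scale protocol of the residue-level
model (100 chains, 20 x 20 x 280 nm, 10 us) uses the same code path but is
a cluster-sized computation; the desk scale preserves the physics
(condensation of sticky chains, temperature-dependent dilute phase) at
reduced statistical precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import (
    SimulationConfig,
    Topology,
    build_slab_system,
    langevin_run,
    minimize_energy,
)
from .phase import (
    CoexistenceDensities,
    coexistence_densities,
    peak_local_density_ratio,
    z_density_profile,
)
from .synth import make_homopolymer

__all__ = ["HomopolymerSlabResult", "homopolymer_slab_run", "dilute_density_at"]

#: desk-scale defaults: chains x beads and slab box (nm)
DESK_N_CHAINS = 10
DESK_N_RES = 50
DESK_BOX = (8.0, 8.0, 24.0)


@dataclass
class HomopolymerSlabResult:
    peak_density_ratio: float
    coexistence: CoexistenceDensities
    mean_kinetic_temperature: float
    topology: Topology
    trajectory: "object"


def homopolymer_slab_run(
    lam: float,
    temperature: float,
    seed: int,
    n_steps: int = 40_000,
    n_chains: int = DESK_N_CHAINS,
    n_res: int = DESK_N_RES,
    box: tuple = DESK_BOX,
    slab_start: bool = False,
    friction: float = 0.1,
) -> HomopolymerSlabResult:
    """Build, relax, and run one homopolymer slab; analyze the second half.

    ``slab_start`` confines the initial chains to the box center — the
    coexistence protocol, where the dilute phase fills by evaporation.
    A random start is the condensation protocol. Friction 0.1 ps^-1 keeps
    the thermostat responsive while condensation releases energy.
    """
    seq, table = make_homopolymer(n_res, lam=lam)
    topo = Topology.from_chains([seq] * n_chains, table)
    frame = build_slab_system(
        topo, box, seed=seed, min_separation=0.5,
        slab_width=box[2] / 4.0 if slab_start else None,
    )
    cfg = SimulationConfig(
        temperature=temperature, n_steps=n_steps, friction=friction,
        seed=seed, save_every=max(1, n_steps // 40),
    )
    frame = minimize_energy(frame, topo, cfg)
    res = langevin_run(frame, topo, cfg)
    half = res.trajectory.slice_frames(
        slice(res.trajectory.n_frames // 2, None)
    )
    prof = z_density_profile(half, topo, bin_width=1.0)
    return HomopolymerSlabResult(
        peak_density_ratio=peak_local_density_ratio(half, topo),
        coexistence=coexistence_densities(prof, buffer=2.0),
        mean_kinetic_temperature=res.mean_kinetic_temperature,
        topology=topo,
        trajectory=res.trajectory,
    )


def dilute_density_at(
    lam: float,
    temperature: float,
    seed: int,
    n_steps: int = 60_000,
    n_chains: int = 20,
    n_res: int = 25,
) -> float:
    """Dilute-phase density (mg/mL) from the evaporation protocol.

    Defaults to 20 chains of 25 beads: at fixed bead count, more and
    shorter chains shrink the per-chain density quantum of the dilute
    phase, which keeps the temperature trend resolvable on desk-scale
    runs.
    """
    res = homopolymer_slab_run(
        lam, temperature, seed, n_steps=n_steps, n_chains=n_chains,
        n_res=n_res, slab_start=True,
    )
    return res.coexistence.rho_l
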