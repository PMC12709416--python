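import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from slabsim.engine import SimulationConfig, Topology
from slabsim.params import SequenceRecord
from slabsim.synth import make_homopolymer, uniform_table


@pytest.fixture(scope="session")
def table():
    """Synthetic uniform parameter table (decoupled from the packaged one)."""
    return uniform_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_system():
    """30 random beads in 3 bonded chains, for energy-oracle comparisons."""
    seq, tab = make_homopolymer(10, lam=0.7, sigma=0.55, charge=0.0)
    topo = Topology.from_chains([seq] * 3, tab)
    return topo


def random_frame_positions(rng, n, box, min_dist=0.3):
    """Random positions with all pair distances above min_dist and away
    from the energy-truncation radii (where the potential is discontinuous
    and numerical gradients are meaningless)."""
    from slabsim.engine import Frame

    box = np.asarray(box, float)
    while True:
        pos = rng.random((n, 3)) * box
        d = pos[:, None, :] - pos[None, :, :]
        d -= box * np.rint(d / box)
        r = np.sqrt((d**2).sum(axis=2))
        np.fill_diagonal(r, 10.0)
        if r.min() < min_dist:
            continue
        if np.any(np.abs(r - 2.0) < 1e-3) or np.any(np.abs(r - 4.0) < 1e-3):
            continue
        return Frame(pos, box)
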