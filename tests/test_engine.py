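"""Energy model, forces, integrator, and system building."""

import numpy as np
import pytest

from slabsim.engine import (
    AH_EPS,
    KB,
    DivergenceError,
    Frame,
    PackingError,
    SimulationConfig,
    SingularityError,
    Topology,
    ah_potential,
    bonded_energy,
    build_slab_system,
    dh_potential,
    langevin_run,
    minimize_energy,
    total_energy_forces,
)
from slabsim.synth import make_homopolymer

from conftest import random_frame_positions
from oracle import brute_force_energies


class TestScalarPotentials:
    def test_bond_zero_at_equilibrium(self):
        assert bonded_energy(0.38) == 0.0

    @pytest.mark.parametrize("r", [0.48, 0.28])
    def test_bond_symmetric_displacement(self, r):
        assert bonded_energy(r) == pytest.approx(41.84)

    def test_ah_at_sigma_is_repulsive_offset(self):
        # U_LJ(sigma) = 0, so only the eps(1 - lambda) offset remains
        assert ah_potential(0.6, 0.6, 0.5) == pytest.approx(0.4184)

    def test_ah_minimum_depth_is_minus_eps_lambda(self):
        r_min = 2 ** (1 / 6) * 0.6
        assert ah_potential(r_min, 0.6, 0.5) == pytest.approx(-0.4184)
        # continuous across the branch point
        assert ah_potential(r_min - 1e-12, 0.6, 0.5) == pytest.approx(
            ah_potential(r_min + 1e-12, 0.6, 0.5), abs=1e-9
        )

    def test_ah_lambda_one_is_plain_lj(self):
        for r in (0.5, 0.68, 1.2, 1.9):
            ulj = 4 * AH_EPS * ((0.6 / r) ** 12 - (0.6 / r) ** 6)
            assert ah_potential(r, 0.6, 1.0) == pytest.approx(ulj)

    def test_ah_zero_beyond_cutoff(self):
        assert ah_potential(2.1, 0.6, 1.0) == 0.0

    def test_ah_shifted_continuous_at_cutoff(self):
        u_in = ah_potential(2.0 - 1e-9, 0.6, 0.8, shift_at_cutoff=True)
        assert u_in == pytest.approx(0.0, abs=1e-6)

    def test_dh_like_charges_screened_coulomb(self):
        assert dh_potential(1.0, 1.0, 1.0) == pytest.approx(0.639, abs=5e-4)

    def test_dh_zero_charge_and_beyond_cutoff(self):
        assert dh_potential(1.0, 0.0, 1.0) == 0.0
        assert dh_potential(4.5, 1.0, 1.0) == 0.0


class TestEnergyForces:
    def test_single_bead_all_zero(self, table):
        seq, tab = make_homopolymer(1, lam=0.5)
        topo = Topology.from_chains([seq], tab)
        frame = Frame(np.zeros((1, 3)) + 5.0, np.array([10.0, 10.0, 10.0]))
        rep, forces = total_energy_forces(frame, topo, SimulationConfig())
        assert rep.total == 0.0
        assert np.all(forces == 0.0)

    def test_bonded_dimer_matches_scalar_ops(self):
        # lam=0, q=0, at the bond length (inside the repulsive branch)
        seq, tab = make_homopolymer(2, lam=0.0, sigma=0.6)
        topo = Topology.from_chains([seq], tab)
        frame = Frame(
            np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 5.38]]),
            np.array([10.0, 10.0, 10.0]),
        )
        rep, _ = total_energy_forces(frame, topo, SimulationConfig())
        assert rep.bonded == pytest.approx(0.0, abs=1e-12)
        # bonded pair excluded from nonbonded sums
        assert rep.ashbaugh_hatch == 0.0

    def test_nonbonded_dimer_matches_scalar_ops(self):
        seq, tab = make_homopolymer(1, lam=0.4, sigma=0.6)
        topo = Topology.from_chains([seq, seq], tab)
        r = 0.5
        frame = Frame(
            np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0 + r]]),
            np.array([10.0, 10.0, 10.0]),
        )
        rep, _ = total_energy_forces(frame, topo, SimulationConfig())
        assert rep.ashbaugh_hatch == pytest.approx(ah_potential(r, 0.6, 0.4))

    def test_random_frames_match_brute_force_oracle(self, small_system, rng):
        topo = small_system
        cfg = SimulationConfig()
        box = np.array([8.0, 8.0, 12.0])
        for _ in range(100):
            frame = random_frame_positions(rng, topo.n_beads, box)
            rep, _ = total_energy_forces(frame, topo, cfg)
            eb, ea, ed = brute_force_energies(
                frame.positions, box, topo.sigma, topo.lam, topo.charge,
                topo.chain_index,
            )
            scale = max(abs(eb) + abs(ea) + abs(ed), 1.0)
            assert abs(rep.bonded - eb) / scale < 1e-9
            assert abs(rep.ashbaugh_hatch - ea) / scale < 1e-9
            assert abs(rep.electrostatic - ed) / scale < 1e-9

    def test_forces_match_numerical_gradient(self, small_system, rng):
        topo = small_system
        cfg = SimulationConfig()
        box = np.array([8.0, 8.0, 12.0])
        h = 1e-5
        for _ in range(5):
            frame = random_frame_positions(rng, topo.n_beads, box, min_dist=0.45)
            _, forces = total_energy_forces(frame, topo, cfg)
            num = np.zeros_like(forces)
            for i in range(topo.n_beads):
                for d in range(3):
                    pp = frame.positions.copy()
                    pp[i, d] += h
                    ep = total_energy_forces(Frame(pp, box), topo, cfg)[0].total
                    pp[i, d] -= 2 * h
                    em = total_energy_forces(Frame(pp, box), topo, cfg)[0].total
                    num[i, d] = -(ep - em) / (2 * h)
            fscale = np.abs(forces).max()
            assert np.abs(forces - num).max() / fscale < 1e-6

    def test_newtons_third_law(self, small_system, rng):
        box = np.array([8.0, 8.0, 12.0])
        for _ in range(20):
            frame = random_frame_positions(rng, small_system.n_beads, box)
            _, forces = total_energy_forces(frame, small_system, SimulationConfig())
            assert np.abs(forces.sum(axis=0)).max() < 1e-9 * max(
                np.abs(forces).max(), 1.0
            )

    def test_overlapping_beads_raise_singularity(self):
        seq, tab = make_homopolymer(1, lam=0.5)
        topo = Topology.from_chains([seq, seq], tab)
        frame = Frame(
            np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0 + 1e-6]]),
            np.array([10.0, 10.0, 10.0]),
        )
        with pytest.raises(SingularityError):
            total_energy_forces(frame, topo, SimulationConfig())

    def test_cutoffs_must_fit_in_box(self):
        seq, tab = make_homopolymer(1, lam=0.5)
        topo = Topology.from_chains([seq], tab)
        frame = Frame(np.zeros((1, 3)) + 1, np.array([4.0, 4.0, 4.0]))
        with pytest.raises(ValueError, match="cutoff"):
            total_energy_forces(frame, topo, SimulationConfig())


class TestLangevin:
    def test_free_bead_at_zero_temperature_stays_put(self):
        seq, tab = make_homopolymer(1, lam=0.0)
        topo = Topology.from_chains([seq], tab)
        frame = Frame(np.full((1, 3), 5.0), np.array([10.0, 10.0, 10.0]))
        cfg = SimulationConfig(temperature=0.0, n_steps=500, save_every=100)
        res = langevin_run(frame, topo, cfg)
        assert np.allclose(res.trajectory.positions, 5.0)

    def test_identical_seed_gives_identical_trajectory(self):
        seq, tab = make_homopolymer(5, lam=0.5)
        topo = Topology.from_chains([seq], tab)
        frame = build_slab_system(topo, [8.0, 8.0, 8.0], seed=3)
        cfg = SimulationConfig(temperature=300.0, n_steps=2000, seed=7, save_every=200)
        a = langevin_run(frame, topo, cfg)
        b = langevin_run(frame, topo, cfg)
        assert np.array_equal(a.trajectory.positions, b.trajectory.positions)
        c = langevin_run(frame, topo, SimulationConfig(
            temperature=300.0, n_steps=2000, seed=8, save_every=200))
        assert not np.array_equal(a.trajectory.positions, c.trajectory.positions)

    def test_repulsive_pair_separates_monotonically_at_t0(self):
        # two nonbonded beads inside the repulsive core, zero temperature
        seq, tab = make_homopolymer(1, lam=0.0, sigma=0.6)
        topo = Topology.from_chains([seq, seq], tab)
        r0 = 0.55
        frame = Frame(
            np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0 + r0]]),
            np.array([10.0, 10.0, 10.0]),
        )
        cfg = SimulationConfig(temperature=0.0, n_steps=3000, friction=1.0,
                               save_every=50)
        res = langevin_run(frame, topo, cfg)
        seps = np.linalg.norm(
            res.trajectory.positions[:, 1] - res.trajectory.positions[:, 0], axis=1
        )
        grow = np.diff(np.concatenate([[r0], seps]))
        # monotone until past the potential minimum
        below = seps < 2 ** (1 / 6) * 0.6
        assert np.all(grow[below] > 0)
        assert seps[-1] >= 2 ** (1 / 6) * 0.6 - 1e-9

    def test_divergence_reports_step_index(self):
        seq, tab = make_homopolymer(2, lam=0.0)
        topo = Topology.from_chains([seq], tab)
        # absurd timestep destabilizes the stretched bond; the huge box keeps
        # minimum image from capping the runaway separation
        frame = Frame(
            np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 5.9]]),
            np.array([1e200, 1e200, 1e200]),  # no minimum-image capping
        )
        cfg = SimulationConfig(temperature=300.0, timestep=5e4, n_steps=20000,
                               save_every=100)
        with pytest.raises(DivergenceError) as err:
            langevin_run(frame, topo, cfg)
        assert err.value.step >= 1


class TestBuildSlabSystem:
    def test_single_chain_built_at_bond_length(self, table):
        seq, tab = make_homopolymer(3, lam=0.5)
        topo = Topology.from_chains([seq], tab)
        frame = build_slab_system(topo, [10.0, 10.0, 20.0], seed=1)
        d = np.linalg.norm(np.diff(frame.positions, axis=0), axis=1)
        assert np.allclose(d, 0.38, atol=1e-9)

    def test_same_seed_reproduces_frame(self):
        seq, tab = make_homopolymer(10, lam=0.5)
        topo = Topology.from_chains([seq] * 4, tab)
        f1 = build_slab_system(topo, [10.0, 10.0, 20.0], seed=11)
        f2 = build_slab_system(topo, [10.0, 10.0, 20.0], seed=11)
        assert np.array_equal(f1.positions, f2.positions)

    def test_min_separation_verified_by_brute_force(self):
        seq, tab = make_homopolymer(5, lam=0.5)
        topo = Topology.from_chains([seq] * 20, tab)
        box = np.array([10.0, 10.0, 20.0])
        frame = build_slab_system(topo, box, seed=5, min_separation=0.4)
        pos = frame.positions
        cid = topo.chain_index
        for i in range(topo.n_beads):
            for j in range(i + 1, topo.n_beads):
                d = pos[i] - pos[j]
                d -= box * np.rint(d / box)
                r = np.sqrt((d**2).sum())
                if cid[i] != cid[j]:
                    assert r >= 0.4 - 1e-12
                elif j > i + 1:  # intra-chain self-avoidance distance
                    assert r >= 0.8 * 0.4 - 1e-12

    def test_impossible_packing_raises(self):
        seq, tab = make_homopolymer(50, lam=0.5)
        topo = Topology.from_chains([seq] * 50, tab)
        with pytest.raises(PackingError):
            build_slab_system(topo, [1.5, 1.5, 1.5], seed=1, max_retries=5)


class TestMinimize:
    def test_minimization_reduces_energy(self):
        seq, tab = make_homopolymer(20, lam=0.5)
        topo = Topology.from_chains([seq] * 5, tab)
        cfg = SimulationConfig()
        frame = build_slab_system(topo, [8.0, 8.0, 12.0], seed=2,
                                  min_separation=0.35)
        e0 = total_energy_forces(frame, topo, cfg)[0].total
        relaxed = minimize_energy(frame, topo, cfg)
        e1 = total_energy_forces(relaxed, topo, cfg)[0].total
        assert e1 < e0
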