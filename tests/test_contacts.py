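"""Contact maps, reductions, and the stickiness-correlation check."""

import numpy as np
import pytest

from slabsim.contacts import (
    ContactMap,
    interchain_contact_map,
    lambda_contact_correlation,
    project_1d,
    region_average,
    residue_type_map,
)
from slabsim.engine import Trajectory
from slabsim.params import Region, SequenceRecord
from slabsim.synth import gen_contact_fixture

from oracle import brute_contact_map


def _make_map(matrix, **kw):
    defaults = dict(
        cutoff_rule="fixed", cutoff_value=0.5, resolution="residue-bead",
        n_frames=1, n_chain_pairs=1, homotypic=False,
    )
    defaults.update(kw)
    return ContactMap(matrix=np.asarray(matrix, float), **defaults)


class TestInterchainContactMap:
    def test_distant_chains_give_zero_matrix(self):
        p = np.zeros((3, 4))
        traj, topo = gen_contact_fixture(p, n_frames=5, cutoff=0.5, seed=1)
        cmap = interchain_contact_map(
            traj, topo, rule="fixed", cutoff=0.5, species_a=[0], species_b=[1]
        )
        assert np.all(cmap.matrix == 0.0)

    def test_all_contacts_give_ones(self):
        p = np.ones((3, 3))
        traj, topo = gen_contact_fixture(p, n_frames=4, cutoff=0.5, seed=1)
        cmap = interchain_contact_map(
            traj, topo, rule="fixed", cutoff=0.5, species_a=[0], species_b=[1]
        )
        assert np.all(cmap.matrix == 1.0)

    def test_hand_placed_single_contact_matches_oracle(self):
        # two 2-residue chains; only pair (0, 1) within cutoff
        box = np.array([20.0, 20.0, 20.0])
        pos = np.array([
            [[5.0, 5.0, 8.0], [15.0, 5.0, 5.0],
             [11.0, 5.0, 5.0], [5.0, 5.0, 8.3]],
        ])
        traj = Trajectory(pos, box, np.zeros(1))
        from slabsim.engine import Topology

        rec = SequenceRecord("c", "AA")
        topo = Topology(
            chains=(rec, rec),
            sigma=np.full(4, 0.5), lam=np.full(4, 0.5),
            charge=np.zeros(4), mass=np.full(4, 100.0),
            chain_index=np.array([0, 0, 1, 1]),
        )
        cmap = interchain_contact_map(
            traj, topo, rule="fixed", cutoff=0.5, species_a=[0], species_b=[1]
        )
        expected = brute_contact_map(
            pos, box, [slice(0, 2)], [slice(2, 4)], 0.5
        )
        np.testing.assert_array_equal(cmap.matrix, expected)
        np.testing.assert_array_equal(cmap.matrix, [[0.0, 1.0], [0.0, 0.0]])

    def test_calvados_rule_equals_pairwise_sigma_oracle(self, rng):
        # random two-chain frames; per-pair cutoff 2^(1/6) * sigma_ij
        from slabsim.engine import Topology

        n = 5
        rec = SequenceRecord("c", "A" * n)
        sig_chain = rng.uniform(0.4, 0.7, size=n)
        sigma = np.concatenate([sig_chain, sig_chain])  # same species
        topo = Topology(
            chains=(rec, rec), sigma=sigma, lam=np.full(2 * n, 0.5),
            charge=np.zeros(2 * n), mass=np.full(2 * n, 100.0),
            chain_index=np.repeat([0, 1], n),
        )
        box = np.array([6.0, 6.0, 6.0])
        pos = rng.random((20, 2 * n, 3)) * box
        traj = Trajectory(pos, box, np.arange(20.0))
        cmap = interchain_contact_map(traj, topo, rule="calvados")
        cut = 2 ** (1 / 6) * 0.5 * (sig_chain[:, None] + sig_chain[None, :])
        expected = brute_contact_map(pos, box, [slice(0, n)], [slice(n, 2 * n)], cut)
        # homotypic: oracle over both ordered pairs, then symmetrized
        expected_rev = brute_contact_map(pos, box, [slice(n, 2 * n)], [slice(0, n)], cut.T)
        np.testing.assert_allclose(cmap.matrix, (expected + expected_rev) / 2)

    def test_duplicated_frames_leave_map_unchanged(self):
        p = np.full((2, 2), 0.5)
        traj, topo = gen_contact_fixture(p, n_frames=30, cutoff=0.5, seed=3)
        double = Trajectory(
            np.repeat(traj.positions, 2, axis=0), traj.box,
            np.arange(2 * traj.n_frames, dtype=float),
        )
        m1 = interchain_contact_map(traj, topo, rule="fixed", cutoff=0.5,
                                    species_a=[0], species_b=[1])
        m2 = interchain_contact_map(double, topo, rule="fixed", cutoff=0.5,
                                    species_a=[0], species_b=[1])
        np.testing.assert_allclose(m1.matrix, m2.matrix)

    def test_empirical_map_converges_to_planted_probabilities(self):
        p = np.full((3, 3), 0.3)
        n_frames = 8000
        traj, topo = gen_contact_fixture(p, n_frames=n_frames, cutoff=0.5, seed=9)
        cmap = interchain_contact_map(
            traj, topo, rule="fixed", cutoff=0.5, species_a=[0], species_b=[1]
        )
        se = np.sqrt(0.3 * 0.7 / n_frames)
        assert np.all(np.abs(cmap.matrix - 0.3) < 3 * se)

    def test_single_chain_homotypic_is_error(self):
        from slabsim.engine import Topology

        rec = SequenceRecord("c", "AAA")
        topo = Topology(
            chains=(rec,), sigma=np.full(3, 0.5), lam=np.full(3, 0.5),
            charge=np.zeros(3), mass=np.full(3, 100.0),
            chain_index=np.zeros(3, dtype=np.int64),
        )
        traj = Trajectory(np.zeros((1, 3, 3)) + 2.0,
                          np.array([10.0, 10.0, 10.0]), np.zeros(1))
        with pytest.raises(ValueError, match="two chains"):
            interchain_contact_map(traj, topo)

    def test_unknown_rule_or_resolution_rejected(self):
        p = np.zeros((2, 2))
        traj, topo = gen_contact_fixture(p, n_frames=1, cutoff=0.5, seed=1)
        with pytest.raises(ValueError, match="rule"):
            interchain_contact_map(traj, topo, rule="nearest")
        with pytest.raises(ValueError, match="resolution"):
            interchain_contact_map(traj, topo, rule="fixed", cutoff=0.5,
                                   resolution="quantum")

    def test_chain_relabeling_invariance(self):
        # permuting chain order leaves the homotypic map unchanged
        from slabsim.engine import Topology

        rng = np.random.default_rng(4)
        n, n_chains = 4, 3
        rec = SequenceRecord("c", "A" * n)
        box = np.array([8.0, 8.0, 8.0])
        pos = rng.random((10, n * n_chains, 3)) * box
        topo = Topology(
            chains=(rec,) * n_chains, sigma=np.full(n * n_chains, 0.5),
            lam=np.full(n * n_chains, 0.5), charge=np.zeros(n * n_chains),
            mass=np.full(n * n_chains, 100.0),
            chain_index=np.repeat(np.arange(n_chains), n),
        )
        m1 = interchain_contact_map(
            Trajectory(pos, box, np.arange(10.0)), topo, rule="fixed", cutoff=0.6
        )
        perm = np.concatenate([np.arange(n) + 2 * n, np.arange(n),
                               np.arange(n) + n])
        m2 = interchain_contact_map(
            Trajectory(pos[:, perm], box, np.arange(10.0)), topo,
            rule="fixed", cutoff=0.6,
        )
        np.testing.assert_allclose(m1.matrix, m2.matrix)


class TestProjections:
    def test_constant_matrix_projects_to_constant(self):
        cmap = _make_map(np.full((3, 5), 0.4))
        np.testing.assert_allclose(project_1d(cmap, "A"), 0.4)
        np.testing.assert_allclose(project_1d(cmap, "B"), 0.4)

    def test_row_means(self):
        cmap = _make_map([[0.0, 1.0], [0.0, 0.0]])
        np.testing.assert_allclose(project_1d(cmap, "A"), [0.5, 0.0])

    def test_projection_preserves_mean(self, rng):
        m = rng.random((6, 9))
        cmap = _make_map(m)
        assert project_1d(cmap, "A").mean() == pytest.approx(m.mean())
        assert project_1d(cmap, "B").mean() == pytest.approx(m.mean())


class TestRegionAverage:
    def test_single_region_is_global_mean(self, rng):
        m = rng.random((10, 10))
        cmap = _make_map(m)
        block = region_average(
            cmap, [Region("all", 1, 10)], [Region("all", 1, 10)]
        )
        assert block[0, 0] == pytest.approx(m.mean())

    def test_two_constant_blocks(self):
        m = np.block([
            [np.full((5, 5), 0.2), np.full((5, 5), 0.8)],
            [np.full((5, 5), 0.8), np.full((5, 5), 0.6)],
        ])
        cmap = _make_map(m)
        regions = [Region("first", 1, 5), Region("second", 6, 10)]
        block = region_average(cmap, regions, regions)
        np.testing.assert_allclose(block, [[0.2, 0.8], [0.8, 0.6]])

    def test_planted_enrichment_ordering_recovered(self):
        # synthetic map with FFR:FFR > FFR:M8BR > M8BR:M8BR
        n1, n2 = 140, 172  # M8BR-like and FFR-like lengths
        m = np.empty((n1 + n2, n1 + n2))
        m[:n1, :n1] = 0.05
        m[:n1, n1:] = m[n1:, :n1] = 0.15
        m[n1:, n1:] = 0.40
        cmap = _make_map(m)
        regions = [Region("M8BR", 633, 772), Region("FFR", 773, 944)]
        block = region_average(cmap, regions, regions, offset_a=633, offset_b=633)
        assert block[1, 1] > block[0, 1] > block[0, 0]

    def test_out_of_range_and_overlapping_regions_rejected(self):
        cmap = _make_map(np.zeros((10, 10)))
        with pytest.raises(IndexError):
            region_average(cmap, [Region("r", 1, 11)], [Region("r", 1, 10)])
        with pytest.raises(ValueError, match="overlap"):
            region_average(
                cmap, [Region("a", 1, 6), Region("b", 5, 10)],
                [Region("all", 1, 10)],
            )


class TestResidueTypeMap:
    def test_all_ones_normalized_entry_is_one(self):
        seq = SequenceRecord("s", "AY")
        cmap = _make_map(np.ones((2, 2)))
        tmap = residue_type_map(cmap, seq, seq, normalized=True)
        assert tmap.value("A", "Y") == pytest.approx(1.0)

    def test_planted_single_pair_counting(self):
        # seqs chosen so there are exactly 4 Y-R position pairs
        seq_a = SequenceRecord("a", "YRYA")
        seq_b = SequenceRecord("b", "RYAY")
        m = np.zeros((4, 4))
        m[0, 0] = 0.6  # one Y(a)-R(b) pair carries all the contact weight
        cmap = _make_map(m)
        un = residue_type_map(cmap, seq_a, seq_b, normalized=False)
        no = residue_type_map(cmap, seq_a, seq_b, normalized=True)
        assert un.value("Y", "R") == pytest.approx(0.6)
        assert un.count("Y", "R") == 4
        assert no.value("Y", "R") == pytest.approx(0.15)

    def test_absent_types_flagged_not_divided(self):
        seq = SequenceRecord("s", "AY")
        cmap = _make_map(np.ones((2, 2)))
        tmap = residue_type_map(cmap, seq, seq, normalized=True)
        assert np.isnan(tmap.value("W", "W"))
        assert tmap.count("W", "W") == 0

    def test_normalized_times_counts_equals_unnormalized(self, rng):
        letters = np.array(list("ARNDYFKEQ"))
        sa = SequenceRecord("a", "".join(rng.choice(letters, 30)))
        sb = SequenceRecord("b", "".join(rng.choice(letters, 25)))
        m = rng.random((30, 25))
        cmap = _make_map(m)
        un = residue_type_map(cmap, sa, sb, normalized=False)
        no = residue_type_map(cmap, sa, sb, normalized=True)
        mask = un.pair_counts > 0
        np.testing.assert_allclose(
            no.matrix[mask] * no.pair_counts[mask], un.matrix[mask]
        )
        # symmetry
        np.testing.assert_allclose(no.matrix[mask], no.matrix.T[mask])

    def test_length_mismatch_is_error(self):
        cmap = _make_map(np.ones((2, 2)))
        with pytest.raises(ValueError, match="length"):
            residue_type_map(cmap, SequenceRecord("a", "AYA"),
                             SequenceRecord("b", "AY"))


class TestLambdaContactCorrelation:
    def _typemap_from_score(self, table, transform):
        """Build a normalized type map exactly transform(score) on a few types."""
        from slabsim.contacts import ResidueTypeMap
        from slabsim.params import CANONICAL_CODES

        lam = np.array([table[c].lam for c in CANONICAL_CODES])
        score = 0.5 * (lam[:, None] + lam[None, :])
        counts = np.zeros_like(score, dtype=int)
        present = [CANONICAL_CODES.index(c) for c in "AYRDEKFG"]
        for i in present:
            for j in present:
                counts[i, j] = 1
        mat = np.where(counts > 0, transform(score), np.nan)
        return ResidueTypeMap(matrix=mat, pair_counts=counts, normalized=True)

    def test_exact_linearity_gives_r_one(self):
        from slabsim.params import default_table

        t = default_table()
        tmap = self._typemap_from_score(t, lambda s: 0.1 + 0.5 * s)
        assert lambda_contact_correlation(tmap, t) == pytest.approx(1.0)

    def test_negative_affine_gives_r_minus_one(self):
        from slabsim.params import default_table

        t = default_table()
        tmap = self._typemap_from_score(t, lambda s: 1.0 - 0.4 * s)
        assert lambda_contact_correlation(tmap, t) == pytest.approx(-1.0)

    def test_shuffled_scores_decorrelate(self, rng):
        from slabsim.params import default_table

        t = default_table()
        tmap = self._typemap_from_score(t, lambda s: 0.1 + 0.5 * s)
        iu = np.triu_indices(20)
        base = tmap.matrix.copy()
        rs = []
        for _ in range(200):
            vals = base[iu].copy()
            ok = np.isfinite(vals)
            shuf = vals[ok]
            rng.shuffle(shuf)
            vals[ok] = shuf
            m = np.full_like(base, np.nan)
            m[iu] = vals
            m.T[iu] = vals
            from slabsim.contacts import ResidueTypeMap

            tm = ResidueTypeMap(matrix=m, pair_counts=tmap.pair_counts,
                                normalized=True)
            rs.append(lambda_contact_correlation(tm, t))
        assert abs(np.mean(rs)) < 0.1  # permutation null centred at zero

    def test_product_score_option(self):
        from slabsim.params import default_table

        t = default_table()
        from slabsim.params import CANONICAL_CODES

        lam = np.array([t[c].lam for c in CANONICAL_CODES])
        score = 0.5 * lam[:, None] * lam[None, :]
        counts = np.ones_like(score, dtype=int)
        from slabsim.contacts import ResidueTypeMap

        tmap = ResidueTypeMap(matrix=2.0 * score, pair_counts=counts,
                              normalized=True)
        r = lambda_contact_correlation(tmap, t, score="product_half")
        assert r == pytest.approx(1.0)

    def test_too_few_pairs_is_error(self):
        from slabsim.contacts import ResidueTypeMap
        from slabsim.params import default_table

        mat = np.full((20, 20), np.nan)
        counts = np.zeros((20, 20), dtype=int)
        mat[0, 0] = 0.5
        counts[0, 0] = 1
        tmap = ResidueTypeMap(matrix=mat, pair_counts=counts, normalized=True)
        with pytest.raises(ValueError, match="3 type pairs"):
            lambda_contact_correlation(tmap, default_table())
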