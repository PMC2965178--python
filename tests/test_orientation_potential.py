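"""Orientation descriptor geometry, reference probabilities, training."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import chisquare, norm

from rwpot.orientation_potential import (DEFAULT_VECTOR_PAIRS,
                                         DIRECTION_REF_PROBS,
                                         DegenerateGeometryError,
                                         N_ORIENTATION_BINS,
                                         N_TORSION_BINS, N_VECTOR_PAIR_TYPES,
                                         OrientationBin, build_frame,
                                         direction_bin, direction_bins,
                                         in_contact, load_orientation_table,
                                         orientation_reference_probs,
                                         reference_probability,
                                         relative_orientation,
                                         save_orientation_table,
                                         score_orientation, train_orientation)

from conftest import rigid_transform


class TestVectorPairDefs:
    def test_twenty_types_18_sidechain_2_backbone(self):
        assert N_VECTOR_PAIR_TYPES == 20
        side = [d for d in DEFAULT_VECTOR_PAIRS if d.residue_scope != "backbone"]
        back = [d for d in DEFAULT_VECTOR_PAIRS if d.residue_scope == "backbone"]
        assert len(side) == 18 and len(back) == 2
        assert {d.residue_scope for d in side} \
            == {"ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "HIS", "ILE",
                "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
                "TYR", "VAL"}  # every residue except GLY and ALA


class TestFrames:
    def test_canonical_triple_gives_identity_frame(self):
        f = build_frame((0, 0, 0), (0, 0, 1), (1, 0, 0))
        assert np.allclose(f, np.eye(3))

    def test_equivariance_under_rotation(self):
        rng = np.random.default_rng(3)
        p = rng.normal(size=(3, 3))
        f0 = build_frame(*p)
        for seed in range(3):
            R = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
            f1 = build_frame(*(p @ R.T))
            assert np.allclose(f1, f0 @ R.T, atol=1e-12)

    def test_collinear_triple_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            build_frame((0, 0, 0), (0, 0, 1), (0, 0, 2))
        with pytest.raises(DegenerateGeometryError):
            build_frame((0, 0, 0), (0, 0, 0), (1, 0, 0))


class TestDirectionBins:
    def test_polar_caps(self):
        for phi in (0.0, 1.0, 5.0):
            assert direction_bin(0.1, phi) == 0
            assert direction_bin(np.pi - 0.1, phi) == 1

    def test_fine_grid_hits_exactly_26_bins(self):
        theta = np.linspace(0, np.pi, 400)
        phi = np.linspace(0, 2 * np.pi, 800, endpoint=False)
        tt, pp = np.meshgrid(theta, phi)
        bins = direction_bins(tt.ravel(), pp.ravel())
        assert set(bins.tolist()) == set(range(26))

    def test_sector_boundary_is_half_open(self):
        theta = np.pi / 2
        opening = direction_bin(theta, np.pi / 8)
        before = direction_bin(theta, np.pi / 8 - 1e-9)
        assert opening != before
        # the sector below pi/8 is the wrap-around one
        assert before == direction_bin(theta, 15 * np.pi / 8 + 1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            direction_bin(-0.1, 0.0)
        with pytest.raises(ValueError):
            direction_bin(1.0, 2 * np.pi)


class TestReferenceProbabilities:
    def test_direction_probs_partition_the_sphere(self):
        assert DIRECTION_REF_PROBS.sum() == pytest.approx(1.0, abs=1e-15)
        assert reference_probability(0) == pytest.approx((1 - np.sqrt(3) / 2) / 2)
        assert reference_probability(10) == pytest.approx(0.0625)  # equator
        assert reference_probability(2) == reference_probability(25)

    def test_full_orientation_reference_sums_to_one(self):
        p = orientation_reference_probs()
        assert p.shape == (2704,)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_monte_carlo_agreement(self):
        """A uniform sphere sample reproduces every bin's area fraction
        within family-corrected 3-sigma binomial error."""
        n = 1_000_000
        rng = np.random.default_rng(12345)
        u = rng.uniform(-1, 1, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        bins = direction_bins(np.arccos(u), phi)
        obs = np.bincount(bins, minlength=26)
        p = DIRECTION_REF_PROBS
        sd = np.sqrt(n * p * (1 - p))
        zstar = norm.isf(0.0027 / (2 * 26))
        assert np.all(np.abs(obs - n * p) < zstar * sd)


def make_triple(rng, origin=np.zeros(3)):
    return origin + rng.normal(scale=2.0, size=(3, 3))


class TestRelativeOrientation:
    def test_flat_index_bijection(self):
        for flat in range(N_ORIENTATION_BINS):
            assert OrientationBin.from_flat(flat).flat_index == flat

    def test_swap_symmetry(self):
        # swapping A and B swaps the two direction bins; the torsion is
        # unchanged because a dihedral is invariant under reversing its
        # atom sequence (A1-A0-B0-B1 vs B1-B0-A0-A1)
        rng = np.random.default_rng(0)
        for _ in range(200):
            a = make_triple(rng)
            b = make_triple(rng, origin=np.array([8.0, 0, 0]))
            ab = relative_orientation(a, b)
            ba = relative_orientation(b, a)
            assert (ab.dir_ab, ab.dir_ba) == (ba.dir_ba, ba.dir_ab)
            assert ba.torsion == ab.torsion

    def test_rigid_invariance(self):
        rng = np.random.default_rng(1)
        a = make_triple(rng)
        b = make_triple(rng, origin=np.array([7.0, 1.0, 0]))
        o0 = relative_orientation(a, b)
        for seed in range(5):
            R = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
            t = np.array([3.0, -2.0, 9.0])
            assert relative_orientation(a @ R.T + t, b @ R.T + t) == o0

    def test_coincident_origins_rejected(self):
        rng = np.random.default_rng(2)
        a = make_triple(rng)
        b = a.copy()
        with pytest.raises(DegenerateGeometryError):
            relative_orientation(a, b)

    def test_torsion_uniform_under_axial_rotation(self):
        """Rotating B about the A0-B0 axis sweeps the torsion uniformly."""
        rng = np.random.default_rng(4)
        a = make_triple(rng)
        b = make_triple(rng, origin=np.array([9.0, 0, 0]))
        axis = b[0] - a[0]
        axis = axis / np.linalg.norm(axis)
        counts = np.zeros(4)
        angles = rng.uniform(0, 2 * np.pi, 10_000)
        for ang in angles:
            R = Rotation.from_rotvec(ang * axis).as_matrix()
            b_rot = b[0] + (b - b[0]) @ R.T
            counts[relative_orientation(a, b_rot).torsion] += 1
        assert chisquare(counts).pvalue > 1e-3


class TestContacts:
    def test_strict_cutoff(self):
        from rwpot.structures_io import Residue, TypedAtom
        mk = lambda i, x: Residue(i, "GLY", [
            TypedAtom(i, "GLY", "CA", 54, np.array([x, 0.0, 0.0]))])
        assert in_contact(mk(0, 0.0), mk(3, 9.99))
        assert not in_contact(mk(0, 0.0), mk(3, 10.0))

    def test_matches_brute_force(self, fixture30):
        for ra, rb in itertools.combinations(fixture30.residues, 2):
            expect = any(
                np.linalg.norm(x.position - y.position) < 10.0
                for x in ra.atoms for y in rb.atoms)
            assert in_contact(ra, rb) == expect


class TestTrainingAndScoring:
    def test_expected_equals_observed_totals(self, fixture50):
        pot, counts = train_orientation([fixture50], return_counts=True)
        ref = orientation_reference_probs()
        totals = counts.sum(axis=-1)
        expected = totals[:, :, None] * ref
        assert np.allclose(expected.sum(axis=-1), totals)

    def test_no_contacts_scores_zero(self):
        from rwpot.synthetic_data import make_orientation_set
        s = make_orientation_set(5, seed=0)
        pot = train_orientation([s])
        # push every pair apart: scale all coordinates 10x
        far = s.with_coords(s.coords * 10.0)
        assert score_orientation(far, pot) == 0.0

    def test_rigid_invariance(self, fixture50):
        pot = train_orientation([fixture50])
        e0 = score_orientation(fixture50, pot)
        assert e0 != 0.0
        for seed in range(3):
            assert score_orientation(rigid_transform(fixture50, seed), pot) \
                == pytest.approx(e0, abs=1e-6)

    def test_matches_brute_force_oracle(self, fixture30, fixture50):
        """Independent re-summation with scalar geometry primitives."""
        pot = train_orientation([fixture50])
        total = 0.0
        defs_for = {}
        for res in fixture30.residues:
            lst = []
            for d in DEFAULT_VECTOR_PAIRS:
                if d.residue_scope not in ("backbone", res.name):
                    continue
                atoms = [res.atom(n) for n in d.atoms]
                if all(a is not None for a in atoms):
                    lst.append((d.vp_type,
                                np.stack([a.position for a in atoms])))
            defs_for[res.index] = lst
        for ra, rb in itertools.combinations(fixture30.residues, 2):
            if rb.index - ra.index < 2 or not in_contact(ra, rb):
                continue
            for ta, tra in defs_for[ra.index]:
                for tb, trb in defs_for[rb.index]:
                    o = relative_orientation(tra, trb)
                    total += pot.energy[ta, tb, o.flat_index]
        assert score_orientation(fixture30, pot) == pytest.approx(total,
                                                                  abs=1e-9)

    def test_table_roundtrip(self, fixture50, tmp_path):
        pot = train_orientation([fixture50])
        save_orientation_table(pot, tmp_path / "o.tsv")
        back = load_orientation_table(tmp_path / "o.tsv")
        assert np.array_equal(back.energy, pot.energy)
        assert back.w_orient == pot.w_orient
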