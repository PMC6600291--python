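import numpy as np
import pytest

from ecfuse.io_formats import STANDARD20, ProteinStructure, Residue
from ecfuse.structure_features import (
    AngleHistogramSpec,
    DistanceHistogramSpec,
    build_xa,
    build_xd,
    compute_torsion_angles,
    dihedral,
    map_to_extended23,
    pairwise_ca_distances,
    smooth_histogram_2d,
)
from ecfuse.synthetic_data import TorsionRegime, generate_structure


def _dihedral_oracle(p0, p1, p2, p3):
    """Independent arccos-with-sign construction from plane normals."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    return -180.0 if ang >= 180.0 else ang


class TestMapToExtended23:
    def test_ala_first(self):
        assert map_to_extended23("ALA") == 0

    def test_nonstandard_to_other(self):
        assert map_to_extended23("THP") == 22
        assert map_to_extended23("ASE") == 22
        assert map_to_extended23("MSE") == 22

    def test_ambiguity_codes(self):
        assert map_to_extended23("ASX") == 20
        assert map_to_extended23("GLX") == 21

    def test_standard_channels_match_sort_oracle(self):
        order = sorted(STANDARD20)
        got = [map_to_extended23(c) for c in STANDARD20]
        assert got == [order.index(c) for c in STANDARD20]
        assert sorted(got) == list(range(20))

    def test_empty_code(self):
        with pytest.raises(ValueError):
            map_to_extended23("")


class TestDihedral:
    def test_planar_cis_zero(self):
        p = [np.array(v, float) for v in
             [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)]]
        assert dihedral(*p) == pytest.approx(0.0, abs=1e-12)

    def test_trans_returns_minus_180(self):
        p = [np.array(v, float) for v in
             [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)]]
        assert dihedral(*p) == -180.0

    def test_matches_cross_product_oracle(self):
        rng = np.random.default_rng(42)
        n_checked = 0
        for _ in range(1000):
            pts = rng.normal(size=(4, 3)) * 5
            # skip near-degenerate quadruples
            if (np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[1])) < 1e-6
                    or np.linalg.norm(np.cross(pts[2] - pts[1], pts[3] - pts[2])) < 1e-6):
                continue
            assert dihedral(*pts) == pytest.approx(
                _dihedral_oracle(*pts), abs=1e-9
            )
            n_checked += 1
        assert n_checked > 990


class TestComputeTorsions:
    def test_helix_round_trip(self):
        regime = TorsionRegime(modes=((-57.0, -47.0),), noise_sd=0.0)
        structure, phi, psi = generate_structure(15, regime, seed=3)
        t = compute_torsion_angles(structure)
        np.testing.assert_allclose(t.phi[1:], np.full(14, -57.0), atol=1e-6)
        np.testing.assert_allclose(t.psi[:-1], np.full(14, -47.0), atol=1e-6)
        assert np.isnan(t.phi[0]) and np.isnan(t.psi[-1])

    def test_missing_atom_gives_nan(self, helix_structure):
        helix_structure.residues[3].c = None
        t = compute_torsion_angles(helix_structure)
        assert np.isnan(t.phi[3])  # needs C(3)
        assert np.isnan(t.phi[4])  # needs C(3) as previous C
        assert np.isnan(t.psi[3])
        assert not np.isnan(t.phi[2])

    def test_short_chain_all_undefined(self):
        s = ProteinStructure("x", [Residue("ALA", *np.eye(3))])
        t = compute_torsion_angles(s)
        assert np.all(np.isnan(t.phi)) and np.all(np.isnan(t.psi))


class TestBuildXA:
    def test_single_type_single_angle(self):
        regime = TorsionRegime(modes=((-57.0, -47.0),), noise_sd=0.0)
        structure, _, _ = generate_structure(
            20, regime, seed=5, sequence=["ALA"] * 20
        )
        xa = build_xa(structure)
        assert xa.shape == (19, 19, 23)
        nonzero_channels = [c for c in range(23) if xa[:, :, c].sum() > 0]
        assert nonzero_channels == [0]
        assert xa[:, :, 0].sum() == pytest.approx(1.0, abs=1e-9)
        # mass concentrated around one cell after smoothing
        peak = np.unravel_index(np.argmax(xa[:, :, 0]), (19, 19))
        w = 360.0 / 19
        assert peak[0] == int((-57.0 + 180.0) // w)
        assert peak[1] == int((-47.0 + 180.0) // w)

    def test_shape_any_input(self, random_structure):
        assert build_xa(random_structure).shape == (19, 19, 23)

    def test_unsmoothed_counts_match_loop_oracle(self, random_structure):
        t = compute_torsion_angles(random_structure)
        xa = build_xa(random_structure, t, normalize=False, smooth=False)
        oracle = np.zeros((19, 19, 23))
        w = 360.0 / 19
        for res, phi, psi in zip(random_structure.residues, t.phi, t.psi):
            if np.isnan(phi) or np.isnan(psi):
                continue
            a = min(int(np.floor((phi + 180.0) / w)), 18)
            b = min(int(np.floor((psi + 180.0) / w)), 18)
            oracle[a, b, map_to_extended23(res.name)] += 1
        np.testing.assert_array_equal(xa, oracle)

    def test_channel_mass_one_or_zero(self, random_structure):
        xa = build_xa(random_structure)
        for c in range(23):
            s = xa[:, :, c].sum()
            assert s == pytest.approx(1.0, abs=1e-9) or s == 0.0
        assert np.all(xa >= 0.0)


class TestPairwiseDistances:
    def test_3_4_5_triangle(self):
        s = ProteinStructure("x", [
            Residue("ALA", ca=np.array([0.0, 0.0, 0.0])),
            Residue("GLY", ca=np.array([3.0, 4.0, 0.0])),
        ])
        pairs = pairwise_ca_distances(s)
        assert len(pairs) == 1
        assert pairs[0] == ("ALA", "GLY", 5.0)

    def test_pair_count(self, random_structure):
        n = sum(1 for r in random_structure.residues if r.ca is not None)
        assert len(pairwise_ca_distances(random_structure)) == n * (n - 1) // 2

    def test_matches_double_loop_oracle(self):
        regime = TorsionRegime(modes=((-57.0, -47.0),), noise_sd=15.0)
        structure, _, _ = generate_structure(20, regime, seed=21)
        pairs = pairwise_ca_distances(structure)
        cas = [r.ca for r in structure.residues]
        k = 0
        for i in range(20):
            for j in range(i + 1, 20):
                expected = np.sqrt(sum((cas[i][d] - cas[j][d]) ** 2 for d in range(3)))
                assert pairs[k][2] == pytest.approx(expected, abs=1e-12)
                k += 1

    def test_min_separation(self, helix_structure):
        all_pairs = pairwise_ca_distances(helix_structure, min_separation=0)
        sep = pairwise_ca_distances(helix_structure, min_separation=3)
        assert len(sep) < len(all_pairs)

    def test_fewer_than_two_cas(self):
        s = ProteinStructure("x", [Residue("ALA", ca=np.zeros(3)), Residue("GLY")])
        assert pairwise_ca_distances(s) == []


class TestBuildXD:
    def test_long_distance_clipped_to_last_bin(self):
        xd = build_xd([("ALA", "GLY", 45.0)])
        slice_ = xd[0, map_to_extended23("GLY")]
        assert slice_.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.argmax(slice_) == 7
        # unsmoothed: all mass exactly in the last bin
        raw = build_xd([("ALA", "GLY", 45.0)], smooth=False)
        assert raw[0, map_to_extended23("GLY"), 7] == 1.0

    def test_below_range_discarded(self):
        xd = build_xd([("ALA", "GLY", 3.0)])
        assert xd.sum() == 0.0

    def test_symmetry(self, random_structure):
        xd = build_xd(pairwise_ca_distances(random_structure))
        np.testing.assert_array_equal(xd, np.transpose(xd, (1, 0, 2)))
        assert xd.shape == (23, 23, 8)

    def test_unsmoothed_counts_match_loop_oracle(self, rng):
        codes = list(STANDARD20) + ["THP", "ASX"]
        pairs = [
            (codes[rng.integers(len(codes))], codes[rng.integers(len(codes))],
             float(rng.uniform(0, 50)))
            for _ in range(100)
        ]
        xd = build_xd(pairs, normalize=False, smooth=False)
        oracle = np.zeros((23, 23, 8))
        width = 35.0 / 8
        for a, b, d in pairs:
            if d < 5.0:
                continue
            k = min(int(np.floor((d - 5.0) / width)), 7)
            ci, cj = map_to_extended23(a), map_to_extended23(b)
            oracle[ci, cj, k] += 1
            if ci != cj:
                oracle[cj, ci, k] += 1
        np.testing.assert_array_equal(xd, oracle)

    def test_slice_mass(self, random_structure):
        xd = build_xd(pairwise_ca_distances(random_structure))
        for i in range(23):
            for j in range(23):
                s = xd[i, j].sum()
                assert s == pytest.approx(1.0, abs=1e-9) or s == 0.0


class TestInvariances:
    def test_rigid_motion_invariance(self, random_structure):
        rng = np.random.default_rng(17)
        # random rotation via QR
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = rng.normal(size=3) * 30
        moved = ProteinStructure(
            "moved",
            [
                Residue(
                    res.name,
                    *(None if p is None else q @ p + t for p in (res.n, res.ca, res.c)),
                )
                for res in random_structure.residues
            ],
        )
        np.testing.assert_allclose(
            build_xa(random_structure), build_xa(moved), atol=1e-9
        )
        np.testing.assert_allclose(
            build_xd(pairwise_ca_distances(random_structure)),
            build_xd(pairwise_ca_distances(moved)),
            atol=1e-9,
        )

    def test_2d_smoothing_mass_conservation(self, rng):
        H = rng.random((19, 19))
        out = smooth_histogram_2d(H, 0.5)
        assert out.sum() == pytest.approx(H.sum(), abs=1e-9)
        assert np.all(out >= 0.0)

    def test_shape_invariance_over_lengths(self):
        regime = TorsionRegime(modes=((-57.0, -47.0),), noise_sd=30.0)
        for L, seed in ((5, 1), (37, 2), (120, 3)):
            s, _, _ = generate_structure(L, regime, seed=seed)
            assert build_xa(s).shape == (19, 19, 23)
            assert build_xd(pairwise_ca_distances(s)).shape == (23, 23, 8)
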