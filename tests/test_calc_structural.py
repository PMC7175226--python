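import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from structkit.calc_structural import (
    GENERAL,
    GLYCINE,
    PRE_PROLINE,
    PROLINE,
    ContactMap,
    contact_map,
    crmsd_ca,
    dihedral,
    kabsch_superpose,
    pairwise_crmsd_matrix,
    phi_psi,
    ring_frame,
    stacking_pairs,
)
from structkit.core_model import Chain, PdbAtom, Residue, Structure, Vec3, ca_trace
from structkit.fixtures import (
    build_backbone,
    make_aromatic_pair,
    make_trajectory,
    random_rotation,
)

coord = st.floats(-50, 50, allow_nan=False)


# ---------------------------------------------------------------- dihedral

def _angle_diff(x, y):
    d = abs(x - y) % 360.0
    return min(d, 360.0 - d)


def dihedral_oracle(a, b, c, d):
    """Second, independent torsion formula: project the outer bonds onto
    the plane perpendicular to the central bond."""
    a, b, c, d = (np.asarray(p, float) for p in (a, b, c, d))
    axis = c - b
    axis = axis / np.linalg.norm(axis)
    u = (a - b) - np.dot(a - b, axis) * axis
    v = (d - c) - np.dot(d - c, axis) * axis
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    ang = math.degrees(math.acos(np.clip(cosang, -1, 1)))
    if np.dot(np.cross(u, v), axis) < 0:
        ang = -ang
    return ang


class TestDihedral:
    def test_planar_cis_zero(self):
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)) == pytest.approx(0.0, abs=1e-12)

    def test_planar_trans_180(self):
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)) == pytest.approx(180.0)

    def test_zero_central_bond_error(self):
        with pytest.raises(ValueError, match="central bond"):
            dihedral((0, 1, 0), (0, 0, 0), (0, 0, 0), (1, 1, 0))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_projection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            pts = rng.uniform(-5, 5, size=(4, 3))
            if all(np.linalg.norm(pts[i + 1] - pts[i]) > 0.5 for i in range(3)):
                break
        assert dihedral(*pts) == pytest.approx(dihedral_oracle(*pts), abs=1e-9)

    @given(st.integers(0, 10 ** 9))
    @settings(max_examples=200, deadline=None)
    def test_reversal_and_mirror_symmetry(self, seed):
        # reversing the quadruple preserves the torsion; mirroring negates it
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-5, 5, size=(4, 3))
        if any(np.linalg.norm(pts[i + 1] - pts[i]) < 1e-3 for i in range(3)):
            return
        fwd = dihedral(*pts)
        rev = dihedral(*pts[::-1])
        assert _angle_diff(fwd, rev) < 1e-8
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert _angle_diff(dihedral(*mirrored), -fwd) < 1e-8

    def test_range_half_open(self):
        # trans gives exactly +180, never -180
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)) == 180.0


# ---------------------------------------------------------------- phi/psi

class TestPhiPsi:
    def test_helix_recovery(self):
        s = build_backbone([(-57.0, -47.0)] * 10)
        recs = phi_psi(s.chains[0])
        assert recs[0].phi is None and recs[-1].psi is None
        for r in recs[1:]:
            assert r.phi == pytest.approx(-57.0, abs=0.5)
        for r in recs[:-1]:
            assert r.psi == pytest.approx(-47.0, abs=0.5)

    def test_terminal_undefined_exactly(self):
        s = build_backbone([(-60.0, -40.0)] * 4)
        recs = phi_psi(s.chains[0])
        assert [r.phi is None for r in recs] == [True, False, False, False]
        assert [r.psi is None for r in recs] == [False, False, False, True]

    @pytest.mark.parametrize(
        "sequence,expected",
        [
            ("AP", [PRE_PROLINE, PROLINE]),
            ("GP", [GLYCINE, PROLINE]),  # identity outranks context
            ("PP", [PROLINE, PROLINE]),
            ("AG", [GENERAL, GLYCINE]),
            ("AA", [GENERAL, GENERAL]),
            ("GA", [GLYCINE, GENERAL]),
        ],
    )
    def test_classification(self, sequence, expected):
        s = build_backbone([(-60.0, 140.0)] * len(sequence), sequence=sequence)
        assert [r.klass for r in phi_psi(s.chains[0])] == expected

    def test_missing_backbone_warns_not_crashes(self):
        s = build_backbone([(-60.0, -40.0)] * 3)
        del s.chains[0].residues[1].atoms[1]  # remove a CA
        with pytest.warns(UserWarning, match="lacks backbone"):
            recs = phi_psi(s.chains[0])
        assert len(recs) == 3
        assert recs[1].phi is None and recs[1].psi is None

    def test_single_residue(self):
        s = build_backbone([(-60.0, -40.0)])
        recs = phi_psi(s.chains[0])
        assert recs[0].phi is None and recs[0].psi is None


# ---------------------------------------------------------------- kabsch

def grid_crmsd_oracle(P, Q, n_samples=20000, seed=0):
    """Brute-force minimum RMSD over sampled rotations (quaternion grid)."""
    rng = np.random.default_rng(seed)
    q = rng.normal(size=(n_samples, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    R = np.empty((n_samples, 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - w * z)
    R[:, 0, 2] = 2 * (x * z + w * y)
    R[:, 1, 0] = 2 * (x * y + w * z)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - w * x)
    R[:, 2, 0] = 2 * (x * z - w * y)
    R[:, 2, 1] = 2 * (y * z + w * x)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    moved = np.einsum("kij,nj->kni", R, P0)
    rmsd = np.sqrt(np.mean(np.sum((moved - Q0) ** 2, axis=2), axis=1))
    return float(rmsd.min())


class TestKabsch:
    def test_identical_sets(self):
        P = np.random.default_rng(0).uniform(-5, 5, (8, 3))
        res = kabsch_superpose(P, P)
        assert res.crmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        P = rng.uniform(-5, 5, (10, 3))
        theta = math.pi / 2
        R = np.array(
            [[math.cos(theta), -math.sin(theta), 0],
             [math.sin(theta), math.cos(theta), 0],
             [0, 0, 1]]
        )
        Q = P @ R.T + np.array([3.0, -2.0, 7.0])
        res = kabsch_superpose(P, Q)
        assert res.crmsd < 1e-9
        np.testing.assert_allclose(res.transform(P), Q, atol=1e-8)

    def test_rotation_is_proper_orthonormal(self):
        rng = np.random.default_rng(2)
        res = kabsch_superpose(rng.uniform(-5, 5, (10, 3)), rng.uniform(-5, 5, (10, 3)))
        np.testing.assert_allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-8)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_not_worse_than_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.uniform(-5, 5, (10, 3))
        Q = rng.uniform(-5, 5, (10, 3))
        analytic = kabsch_superpose(P, Q).crmsd
        grid = grid_crmsd_oracle(P, Q, n_samples=5000, seed=seed)
        assert analytic <= grid + 1e-9
        assert grid - analytic < 0.3  # grid resolution slack

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="differ in size"):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="3 points"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_rigid_invariance(self):
        rng = np.random.default_rng(3)
        P = rng.uniform(-5, 5, (12, 3))
        Q = rng.uniform(-5, 5, (12, 3))
        base = kabsch_superpose(P, Q).crmsd
        R = random_rotation(rng)
        t = rng.uniform(-10, 10, 3)
        assert kabsch_superpose(P @ R.T + t, Q).crmsd == pytest.approx(base, abs=1e-9)
        assert kabsch_superpose(P, Q @ R.T + t).crmsd == pytest.approx(base, abs=1e-9)


class TestCrmsdCa:
    def test_self_zero(self, helix):
        assert crmsd_ca(helix, helix) < 1e-12

    def test_rigid_copy_zero(self, helix):
        moved, _ = make_trajectory(helix, 2, mode="rigid", seed=4, round_coords=False)
        assert crmsd_ca(moved[0], moved[1]) < 1e-9

    def test_unequal_counts_reported(self, helix):
        short = build_backbone([(-57.0, -47.0)] * 5)
        with pytest.raises(ValueError, match="10.*5|5.*10"):
            crmsd_ca(helix, short)

    def test_matrix_matches_pairwise_calls(self, helix):
        models, _ = make_trajectory(helix, 4, mode="noise", sigma=0.8, seed=6, round_coords=False)
        d = pairwise_crmsd_matrix(models)
        for i in range(4):
            for j in range(4):
                expected = 0.0 if i == j else crmsd_ca(models[i], models[j])
                assert d.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_matrix_permutation_equivariance(self, helix):
        models, _ = make_trajectory(helix, 5, mode="noise", sigma=0.5, seed=7)
        d = pairwise_crmsd_matrix(models)
        perm = [3, 0, 4, 1, 2]
        d2 = pairwise_crmsd_matrix([models[i] for i in perm])
        np.testing.assert_allclose(d2.values, d.values[np.ix_(perm, perm)], atol=1e-12)

    def test_identical_models_zero_matrix(self, helix):
        models, _ = make_trajectory(helix, 3, mode="rigid", seed=8, round_coords=False)
        assert pairwise_crmsd_matrix(models).values.max() < 1e-9

    def test_pseudo_metric_on_triples(self, helix):
        models, _ = make_trajectory(helix, 6, mode="noise", sigma=1.0, seed=9)
        d = pairwise_crmsd_matrix(models).values
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                assert d[i, j] == pytest.approx(d[j, i], abs=1e-6)
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-6


# ---------------------------------------------------------------- contacts

def contact_oracle(structures, cutoff, mode, min_seq_sep):
    """All-pairs double loop, recomputed from scratch."""
    counts = {}
    for s in structures:
        flat = []
        for ci, chain in enumerate(s.chains):
            for res in chain.residues:
                flat.append((ci, res))
        for i in range(len(flat)):
            for j in range(i + 1, len(flat)):
                ci, ri = flat[i]
                cj, rj = flat[j]
                if ci == cj and abs(i - j) < min_seq_sep:
                    continue
                if mode == "CA":
                    ai = ri.find_atom("CA")
                    aj = rj.find_atom("CA")
                    if ai is None or aj is None:
                        continue
                    dist = (ai.pos - aj.pos).norm()
                else:
                    dists = [
                        (a.pos - b.pos).norm() for a in ri.atoms for b in rj.atoms
                    ]
                    if not dists:
                        continue
                    dist = min(dists)
                if dist < cutoff:
                    counts[(i, j)] = counts.get((i, j), 0) + 1
    return counts


def _two_ca_structure(distance):
    chain = Chain("A")
    for i, x in enumerate((0.0, distance)):
        r = Residue("ALA", i + 1)
        r.atoms.append(PdbAtom(serial=i + 1, name=" CA ", pos=Vec3(x, 0, 0), element="C"))
        chain.residues.append(r)
    return Structure(id="two", chains=[chain])


class TestContactMap:
    def test_pair_within_cutoff(self):
        s = _two_ca_structure(3.0)
        cmap = contact_map([s], cutoff=5.0, min_seq_sep=0)
        assert cmap.count(0, 1) == 1

    def test_strict_inequality(self):
        s = _two_ca_structure(3.0)
        assert contact_map([s], cutoff=2.9, min_seq_sep=0).count(0, 1) == 0
        assert contact_map([s], cutoff=3.0, min_seq_sep=0).count(0, 1) == 0

    def test_default_excludes_neighbors(self):
        s = _two_ca_structure(3.0)
        assert contact_map([s], cutoff=5.0).count(0, 1) == 0

    def test_bad_cutoff(self):
        with pytest.raises(ValueError):
            contact_map([_two_ca_structure(3.0)], cutoff=0.0)

    @pytest.mark.parametrize("mode", ["CA", "any-atom"])
    @pytest.mark.parametrize("cutoff", [4.0, 6.0, 9.0])
    def test_matches_brute_force(self, helix, mode, cutoff):
        models, _ = make_trajectory(helix, 3, mode="noise", sigma=1.0, seed=10)
        cmap = contact_map(models, cutoff=cutoff, mode=mode)
        assert cmap.pairs == contact_oracle(models, cutoff, mode, 2)

    def test_counts_bounded_by_models(self, helix):
        models, _ = make_trajectory(helix, 5, mode="noise", sigma=0.5, seed=11)
        cmap = contact_map(models, cutoff=8.0)
        assert cmap.n_models == 5
        assert all(0 < c <= 5 for c in cmap.pairs.values())


# ---------------------------------------------------------------- rings

def _hexagon_residue(center, normal, res_name="PHE", res_seq=1):
    from structkit.fixtures import _hexagon, _PHE_RING

    r = Residue(res_name=res_name, res_seq=res_seq)
    for i, (name, xyz) in enumerate(zip(_PHE_RING, _hexagon(np.asarray(center, float), np.asarray(normal, float)))):
        r.atoms.append(PdbAtom(serial=i + 1, name=f" {name:<3s}", pos=Vec3.from_array(xyz), element="C"))
    return r


class TestRingFrame:
    def test_planar_hexagon(self):
        r = _hexagon_residue((1.0, 2.0, 3.0), (0, 0, 1))
        frame = ring_frame(r)
        np.testing.assert_allclose(frame.origin, [1, 2, 3], atol=1e-12)
        assert abs(frame.z_axis[2]) == pytest.approx(1.0, abs=1e-12)

    def test_axes_orthonormal_right_handed(self):
        r = _hexagon_residue((0, 0, 0), (1, 2, 2))
        f = ring_frame(r)
        for u in (f.x_axis, f.y_axis, f.z_axis):
            assert np.linalg.norm(u) == pytest.approx(1.0, abs=1e-8)
        assert abs(np.dot(f.x_axis, f.z_axis)) < 1e-8
        np.testing.assert_allclose(np.cross(f.z_axis, f.x_axis), f.y_axis, atol=1e-8)

    def test_rotation_equivariance(self):
        r = _hexagon_residue((0, 0, 0), (0, 0, 1))
        f0 = ring_frame(r)
        R = random_rotation(np.random.default_rng(12))
        r2 = Residue(res_name="PHE", res_seq=1)
        for a in r.atoms:
            r2.atoms.append(
                PdbAtom(serial=a.serial, name=a.name, pos=Vec3.from_array(R @ a.pos.to_array()), element="C")
            )
        f1 = ring_frame(r2)
        np.testing.assert_allclose(f1.z_axis, R @ f0.z_axis, atol=1e-8)
        np.testing.assert_allclose(f1.x_axis, R @ f0.x_axis, atol=1e-8)

    def test_puckered_ring_normal_stable(self):
        rng = np.random.default_rng(13)
        r = _hexagon_residue((0, 0, 0), (0, 0, 1))
        for a in r.atoms:
            a.pos = Vec3(a.pos.x, a.pos.y, a.pos.z + float(rng.normal(0, 0.05)))
        f = ring_frame(r)
        angle = math.degrees(math.acos(min(1.0, abs(f.z_axis[2]))))
        assert angle < 5.0

    def test_missing_ring_atoms_listed(self):
        r = _hexagon_residue((0, 0, 0), (0, 0, 1))
        del r.atoms[3]  # CZ
        with pytest.raises(ValueError, match="CZ"):
            ring_frame(r)

    def test_non_aromatic_rejected(self):
        with pytest.raises(ValueError, match="not an aromatic"):
            ring_frame(Residue("ALA", 1))


class TestStacking:
    def test_parallel_stack(self):
        s = make_aromatic_pair(3.5, 0.0, 0.0)
        (d,) = stacking_pairs(s, cutoff=6.5)
        assert d.centroid_distance == pytest.approx(3.5, abs=1e-6)
        assert d.plane_angle == pytest.approx(0.0, abs=1e-6)
        assert d.lateral_offset == pytest.approx(0.0, abs=1e-6)

    def test_t_shape(self):
        s = make_aromatic_pair(5.0, 90.0, 0.0)
        (d,) = stacking_pairs(s, cutoff=6.5)
        assert d.plane_angle == pytest.approx(90.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_inverse_construction_recovery(self, seed):
        rng = np.random.default_rng(seed)
        dist = float(rng.uniform(3.0, 6.0))
        angle = float(rng.uniform(0.0, 90.0))
        offset = float(rng.uniform(0.0, dist * 0.9))
        s = make_aromatic_pair(dist, angle, offset, spin_b=float(rng.uniform(0, 360)))
        (d,) = stacking_pairs(s, cutoff=10.0)
        assert d.centroid_distance == pytest.approx(dist, abs=1e-6)
        assert d.plane_angle == pytest.approx(angle, abs=1e-6)
        assert d.lateral_offset == pytest.approx(offset, abs=1e-6)

    def test_matches_vector_arithmetic_oracle(self):
        s = make_aromatic_pair(4.2, 35.0, 1.3, spin_b=77.0)
        (d,) = stacking_pairs(s, cutoff=10.0)
        res_a, res_b = s.chains[0].residues
        ring_a = np.array([a.pos.to_array() for a in res_a.atoms])
        ring_b = np.array([a.pos.to_array() for a in res_b.atoms])
        oa, ob = ring_a.mean(axis=0), ring_b.mean(axis=0)

        def plane_normal(ring):
            c = ring - ring.mean(axis=0)
            _, _, vt = np.linalg.svd(c)
            return vt[2]

        za, zb = plane_normal(ring_a), plane_normal(ring_b)
        sep = ob - oa
        assert d.centroid_distance == pytest.approx(np.linalg.norm(sep), abs=1e-9)
        assert d.plane_angle == pytest.approx(
            math.degrees(math.acos(min(1.0, abs(float(np.dot(za, zb)))))), abs=1e-9
        )
        assert d.lateral_offset == pytest.approx(
            np.linalg.norm(sep - np.dot(sep, za) * za), abs=1e-9
        )

    def test_cutoff_excludes(self):
        s = make_aromatic_pair(5.0, 0.0, 0.0)
        assert stacking_pairs(s, cutoff=4.9) == []

    def test_no_aromatics_empty(self, helix):
        assert stacking_pairs(helix, cutoff=6.5) == []

    def test_plane_angle_flip_invariant(self):
        # flipping one ring's atom order flips its winding/normal sign
        s = make_aromatic_pair(4.0, 25.0, 1.0)
        res_b = s.chains[0].residues[1]
        res_b.atoms.reverse()
        (d,) = stacking_pairs(s, cutoff=10.0)
        assert d.plane_angle == pytest.approx(25.0, abs=1e-6)
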