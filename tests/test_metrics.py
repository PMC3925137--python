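"""Conformational metrics against independent oracles.

Oracles: Horn's quaternion method for superposition, two-pass variance
for the order parameter, O(n^2) pair enumeration for hydrogen bonds, a
refined spherical mesh (and biotite) for SASA.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from fibrilmech import metrics
from fibrilmech.errors import GeometryError
from fibrilmech.structures import FibrilStructure, Trajectory
from fibrilmech.zipper import FibrilBuildParams, build_zipper_fibril, zipper_class


# ---------------------------------------------------------------------------
# superposition / RMSD
# ---------------------------------------------------------------------------

def quaternion_rmsd(mobile, reference):
    """Independent superposition oracle: Horn's quaternion eigenvalue method."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    s = x.T @ y
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam_max = np.linalg.eigvalsh(k)[-1]
    e0 = (x ** 2).sum() + (y ** 2).sum()
    msd = max((e0 - 2.0 * lam_max) / len(mobile), 0.0)
    return np.sqrt(msd)


class TestSuperpose:
    def test_identity_on_identical_sets(self):
        pts = np.random.default_rng(1).normal(size=(8, 3))
        rot, trans, rmsd = metrics.superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(trans, 0.0, atol=1e-10)

    def test_pure_translation_recovered(self):
        pts = np.random.default_rng(2).normal(size=(6, 3))
        shift = np.array([3.0, -1.0, 2.5])
        rot, trans, rmsd = metrics.superpose(pts + shift, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(trans, -shift, atol=1e-10)

    def test_matches_quaternion_oracle_on_noisy_rotation(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            pts = rng.normal(size=(5, 3))
            rot = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
            noisy = pts @ rot.T + 0.1 * rng.normal(size=(5, 3)) + rng.normal(size=3)
            _, _, rmsd = metrics.superpose(noisy, pts)
            assert rmsd == pytest.approx(quaternion_rmsd(noisy, pts), abs=1e-9)

    def test_proper_rotation_even_for_reflected_optimum(self):
        # near-planar set whose naive optimum is a reflection
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.01]], float)
        mirrored = pts * np.array([1, 1, -1])
        rot, _, _ = metrics.superpose(mirrored, pts)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_atoms(self):
        with pytest.raises(GeometryError):
            metrics.superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_rmsd_invariant_under_rigid_transform(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(7, 3))
        b = rng.normal(size=(7, 3))
        rot = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        moved = a @ rot.T + rng.normal(size=3)
        assert metrics.superpose(moved, b)[2] == pytest.approx(
            metrics.superpose(a, b)[2], abs=1e-9)


class TestRmsdSeries:
    def test_constant_trajectory_is_zero(self, straight_fibril):
        frames = np.repeat(straight_fibril.coordinates[None], 4, axis=0)
        traj = Trajectory(frames=frames, structure=straight_fibril)
        np.testing.assert_allclose(metrics.rmsd_series(traj), 0.0, atol=1e-12)

    def test_rotated_frame_gives_zero(self, straight_fibril):
        rot = Rotation.from_rotvec([0.3, 0.5, -0.2]).as_matrix()
        frames = np.stack([straight_fibril.coordinates,
                           straight_fibril.coordinates @ rot.T + 5.0])
        traj = Trajectory(frames=frames, structure=straight_fibril)
        np.testing.assert_allclose(metrics.rmsd_series(traj), 0.0, atol=1e-9)

    def test_matches_per_frame_oracle(self, beam_spec):
        from fibrilmech import sampler

        traj = sampler.sample_beam_trajectory(beam_spec, n_frames=10, seed=9)
        series = metrics.rmsd_series(traj, ref_frame_index=0)
        for i in range(traj.n_frames):
            assert series[i] == pytest.approx(
                quaternion_rmsd(traj.frames[i], traj.frames[0]), abs=1e-9)


# ---------------------------------------------------------------------------
# layer dihedrals, bending angle, order parameter, pitch
# ---------------------------------------------------------------------------

class TestLayerDihedral:
    @pytest.mark.parametrize("twist", [0.0, 10.0, 25.0])
    def test_builder_twist_recovered_exactly(self, twist):
        fib = build_zipper_fibril(
            zipper_class("co-pho"),
            FibrilBuildParams(n_layers=6, twist_per_layer=twist))
        dihedrals = metrics.layer_dihedral(fib.coordinates, fib.layer_indices)
        np.testing.assert_allclose(dihedrals, twist, atol=1e-6)

    def test_antiparallel_class_twist_recovered(self):
        fib = build_zipper_fibril(
            zipper_class("aa-apho"),
            FibrilBuildParams(n_layers=6, twist_per_layer=10.0))
        dihedrals = metrics.layer_dihedral(fib.coordinates, fib.layer_indices)
        np.testing.assert_allclose(dihedrals, 10.0, atol=1e-6)

    def test_degenerate_layer_rejected(self):
        coords = np.zeros((4, 3))
        coords[2:] += [0, 0, 4.8]
        with pytest.raises(GeometryError):
            metrics.layer_dihedral(coords, np.array([0, 0, 1, 1]))


class TestBendingAngle:
    def test_straight_fibril_is_zero(self, straight_fibril):
        assert metrics.bending_angle(
            straight_fibril.coordinates,
            straight_fibril.layer_indices) == pytest.approx(0.0, abs=1e-9)

    def test_right_angle_centroids(self):
        # three 2-atom layers whose centroids form a right angle at the middle
        coords = np.array([
            [10.0, 1.0, 0.0], [10.0, -1.0, 0.0],   # layer 0 at (10, 0, 0)
            [0.0, 1.0, 0.0], [0.0, -1.0, 0.0],     # layer 1 at origin
            [0.0, 1.0, 10.0], [0.0, -1.0, 10.0],   # layer 2 at (0, 0, 10)
        ])
        layers = np.array([0, 0, 1, 1, 2, 2])
        assert metrics.bending_angle(coords, layers) == pytest.approx(90.0)

    def test_single_bending_mode_matches_shape_geometry(self, beam_spec):
        """A frame displaced along the first bending shape has the bending
        angle predicted by evaluating the shape at the three probe layers."""
        import dataclasses

        from fibrilmech import sampler

        spec = dataclasses.replace(beam_spec, background_rms=0.0)
        structure = sampler.reference_structure(spec)
        modes, _ = sampler.mode_displacement_matrix(spec)
        amp = 40.0  # A
        frame = structure.coordinates + amp * modes[:, 0].reshape(-1, 3)
        got = metrics.bending_angle(frame, structure.layer_indices)
        # oracle: angle from the three displaced layer centroids directly
        cents = np.array([frame[structure.layer_indices == k].mean(axis=0)
                          for k in range(spec.n_beads)])
        a, m, b = cents[0], cents[spec.n_beads // 2], cents[-1]
        v1, v2 = a - m, b - m
        expected = 180.0 - np.degrees(np.arccos(
            v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2)))
        assert got == pytest.approx(expected, abs=1e-9)
        assert got > 1.0  # a 40 A first-mode amplitude visibly bends the beam

    def test_needs_three_layers(self):
        coords = np.array([[0, 1, 0], [0, -1, 0], [0, 1, 5], [0, -1, 5]], float)
        with pytest.raises(GeometryError):
            metrics.bending_angle(coords, np.array([0, 0, 1, 1]))


class TestOrderParameter:
    def test_uniform_twist_gives_zero(self):
        assert metrics.order_parameter([10.0] * 7) == pytest.approx(0.0, abs=1e-15)

    def test_two_point_variance(self):
        a_deg = 12.0
        a_rad = np.deg2rad(a_deg)
        assert metrics.order_parameter([a_deg, -a_deg]) == pytest.approx(
            a_rad ** 2, rel=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-60, 60), min_size=2, max_size=12))
    def test_matches_two_pass_variance_oracle(self, values):
        # far from the wrap-around point the circular variance equals the
        # ordinary two-pass population variance
        got = metrics.order_parameter(values)
        rad = np.deg2rad(np.asarray(values))
        mean = rad.mean()
        oracle = float(np.mean((rad - mean) ** 2))
        assert got == pytest.approx(oracle, abs=1e-12)
        assert got >= 0.0

    def test_disorder_flag_threshold(self):
        assert not metrics.is_disordered(0.04)
        assert metrics.is_disordered(0.08)

    def test_needs_two_layers(self):
        with pytest.raises(GeometryError):
            metrics.order_parameter([10.0])


class TestStrandsPerPitch:
    @pytest.mark.parametrize("dihedral,strands,expected", [
        (10.0, 2, 72),
        (360.0, 2, 2),
        (12.857, 2, 56),
        (25.0, 2, 28),  # the high-twist polymorph regime
    ])
    def test_pitch_values(self, dihedral, strands, expected):
        assert metrics.strands_per_pitch(dihedral, strands) == expected

    def test_invalid_dihedral(self):
        with pytest.raises(GeometryError):
            metrics.strands_per_pitch(0.0, 2)
        with pytest.raises(GeometryError):
            metrics.strands_per_pitch(-5.0, 2)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def brute_force_hbond_count(structure, coords, criteria):
    """O(n^2) enumeration oracle with the same geometric criterion."""
    donors = np.flatnonzero(structure.atom_names == "N")
    acceptors = np.flatnonzero(structure.atom_names == "O")
    h_idx = np.flatnonzero(structure.elements == "H")
    count = 0
    for d in donors:
        h_near = [h for h in h_idx
                  if np.linalg.norm(coords[h] - coords[d]) <= 1.3]
        if not h_near:
            continue
        h = h_near[0]
        for a in acceptors:
            if (structure.strand_indices[d] == structure.strand_indices[a]
                    and abs(int(structure.residue_indices[d])
                            - int(structure.residue_indices[a])) <= 1):
                continue
            if np.linalg.norm(coords[a] - coords[d]) > criteria.distance_cutoff:
                continue
            v1 = coords[d] - coords[h]
            v2 = coords[a] - coords[h]
            cosang = v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2)
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= criteria.angle_cutoff:
                count += 1
    return count


def minimal_donor_acceptor(distance, angle_deg):
    """One N-H donor and one O acceptor at prescribed D...A geometry."""
    a = np.deg2rad(180.0 - angle_deg)
    coords = np.array([
        [0.0, 0.0, 0.0],                                  # N
        [np.sin(a), 0.0, np.cos(a)],                      # H (1 A from N)
        [0.0, 0.0, distance],                             # O
        [5.0, 5.0, 5.0],                                  # spectator C
    ])
    return FibrilStructure(
        elements=np.array(["N", "H", "O", "C"], dtype=object),
        atom_names=np.array(["N", "H", "O", "C"], dtype=object),
        residue_indices=np.array([0, 0, 5, 7]),
        strand_indices=np.array([0, 0, 0, 0]),
        layer_indices=np.array([0, 0, 1, 1]),
        coordinates=coords,
    )


class TestHBonds:
    def test_ideal_geometry_detected(self):
        s = minimal_donor_acceptor(2.9, 180.0)
        bonds = metrics.detect_hbonds(s)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.9)
        assert bonds[0].angle == pytest.approx(180.0, abs=1e-6)

    def test_long_distance_rejected(self):
        assert metrics.detect_hbonds(minimal_donor_acceptor(4.5, 180.0)) == []

    def test_bent_geometry_rejected(self):
        assert metrics.detect_hbonds(minimal_donor_acceptor(2.9, 120.0)) == []

    def test_builder_fibril_matches_brute_force(self, backbone_fibril):
        criteria = metrics.HBondCriteria()
        bonds = metrics.detect_hbonds(backbone_fibril, criteria=criteria)
        expected = brute_force_hbond_count(backbone_fibril,
                                           backbone_fibril.coordinates, criteria)
        assert len(bonds) == expected
        assert expected > 0  # the ladder is bonded

    def test_count_invariant_under_rigid_transform(self, backbone_fibril):
        rot = Rotation.from_rotvec([0.3, -0.7, 1.1]).as_matrix()
        moved = backbone_fibril.coordinates @ rot.T + np.array([5.0, -3.0, 2.0])
        assert len(metrics.detect_hbonds(backbone_fibril, moved)) == \
            len(metrics.detect_hbonds(backbone_fibril))

    def test_distance_only_fallback_without_hydrogens(self):
        s = minimal_donor_acceptor(2.9, 180.0)
        stripped = s.subset(s.elements != "H")
        bonds = metrics.detect_hbonds(stripped)
        assert len(bonds) == 1
        assert bonds[0].hydrogen is None
        # outside the tighter distance-only cutoff: rejected
        far = minimal_donor_acceptor(3.4, 180.0)
        assert metrics.detect_hbonds(far.subset(far.elements != "H")) == []

    def test_per_residue_series(self, backbone_fibril):
        frames = np.repeat(backbone_fibril.coordinates[None], 3, axis=0)
        traj = Trajectory(frames=frames, structure=backbone_fibril)
        series = metrics.hbonds_per_residue(traj)
        assert series.shape == (3,)
        assert np.all(series == series[0])
        assert 0 < series[0] <= 2.0


# ---------------------------------------------------------------------------
# SASA and nonpolar solvation
# ---------------------------------------------------------------------------

def latlon_sasa(coords, radii, probe, n_points=10_000):
    """Independent refined-mesh SASA oracle (random sphere points, seeded)."""
    rng = np.random.default_rng(12345)
    pts = rng.normal(size=(n_points, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    expanded = radii + probe
    total = 0.0
    for i in range(len(coords)):
        test = coords[i] + expanded[i] * pts
        buried = np.zeros(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            buried |= ((test - coords[j]) ** 2).sum(axis=1) < expanded[j] ** 2
        total += (~buried).mean() * 4 * np.pi * expanded[i] ** 2
    return total


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        total, per_atom = metrics.sasa(np.zeros((1, 3)), np.array([1.9]),
                                       probe=1.4, n_sphere_points=960)
        expected = 4 * np.pi * 3.3 ** 2  # ~136.85 A^2
        assert total == pytest.approx(expected, rel=0.005)
        assert per_atom[0] == pytest.approx(total)

    def test_distant_pair_is_additive(self):
        coords = np.array([[0.0, 0, 0], [20.0, 0, 0]])
        radii = np.array([1.9, 1.5])
        total, per_atom = metrics.sasa(coords, radii, probe=1.4)
        expected = 4 * np.pi * ((1.9 + 1.4) ** 2 + (1.5 + 1.4) ** 2)
        assert total == pytest.approx(expected, rel=0.005)

    def test_overlapping_dimer_matches_refined_oracle(self):
        coords = np.array([[0.0, 0, 0], [2.5, 0.3, -0.2]])
        radii = np.array([1.9, 1.7])
        total, _ = metrics.sasa(coords, radii, probe=1.4, n_sphere_points=960)
        oracle = latlon_sasa(coords, radii, probe=1.4)
        assert total == pytest.approx(oracle, rel=0.02)

    def test_monotone_as_atoms_approach(self):
        radii = np.array([1.8, 1.8])
        areas = []
        for d in (8.0, 5.0, 3.5, 2.5, 1.5):
            coords = np.array([[0.0, 0, 0], [d, 0, 0]])
            areas.append(metrics.sasa(coords, radii, probe=1.4)[0])
        assert all(a >= b - 1e-9 for a, b in zip(areas[:-1], areas[1:]))

    def test_matches_biotite_on_small_structure(self, twisted_fibril):
        import biotite.structure as struc

        sub = twisted_fibril.subset(twisted_fibril.layer_indices < 4)
        radii = sub.vdw_radii()
        total, _ = metrics.sasa(sub.coordinates, radii, probe=1.4,
                                n_sphere_points=960)
        atoms = struc.AtomArray(sub.n_atoms)
        atoms.coord = sub.coordinates.astype(np.float32)
        atoms.element = np.array([e.upper() for e in sub.elements])
        atoms.atom_name = np.array(list(sub.atom_names))
        atoms.res_id = np.arange(sub.n_atoms)
        atoms.res_name = np.array(["GLY"] * sub.n_atoms)
        atoms.chain_id = np.array(["A"] * sub.n_atoms)
        ref = struc.sasa(atoms, probe_radius=1.4, point_number=960,
                         vdw_radii=radii).sum()
        assert total == pytest.approx(ref, rel=0.02)

    def test_point_count_floor(self):
        with pytest.raises(ValueError):
            metrics.sasa(np.zeros((1, 3)), np.array([1.5]), n_sphere_points=8)


class TestNonpolarSolvation:
    def test_intercept_at_zero_area(self):
        assert metrics.nonpolar_solvation(0.0) == pytest.approx(0.92)

    def test_linear_form(self):
        assert metrics.nonpolar_solvation(1000.0) == pytest.approx(6.34)

    def test_zero_gamma_gives_constant(self):
        params = metrics.SolvationParams(gamma=0.0)
        for area in (0.0, 100.0, 5000.0):
            assert metrics.nonpolar_solvation(area, params) == pytest.approx(0.92)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            metrics.nonpolar_solvation(-1.0)
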