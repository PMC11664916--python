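"""Cavity point placement against a brute-force oracle, and annotation."""

import numpy as np
import pytest

from catalocavity.cavity import (
    EmptyCavityError,
    annotate_properties,
    buriedness_of_points,
    icosahedral_directions,
    negative_charge_stabilization,
    partial_charges,
    procreate_cavity,
    read_cloud_json,
    write_cloud_json,
)
from catalocavity.structure_io import Structure, locate_flavin
from catalocavity.synthetic_data import (
    brute_force_cavity_points,
    make_toy_enzyme,
    random_rotation,
)

from conftest import fatty_acid, make_atom, planar_fad


def point_sets_equal(a, b, decimals=6):
    return set(map(tuple, np.round(a, decimals))) == \
        set(map(tuple, np.round(b, decimals)))


def hollow_box_structure():
    """Rectangular carbon shell with a clear 6x6x6 A interior and a short
    ligand plus flavin inside; a hand-checkable cavity geometry."""
    atoms = []
    serial = 0
    half = 6.0  # wall atom centres; with C vdW 1.7 + 0.7 clearance the
    # interior clear span is about 6x6x6 around the origin
    grid = np.arange(-half, half + 0.1, 2.0)
    for x in grid:
        for y in grid:
            for z in grid:
                on_face = (abs(abs(x) - half) < 1e-9 or abs(abs(y) - half) < 1e-9
                           or abs(abs(z) - half) < 1e-9)
                if on_face:
                    serial += 1
                    atoms.append(make_atom(serial, "CA", "C", "UNK", "A",
                                           serial, (x, y, z)))
    lig, spec = fatty_acid(2, start=(0.0, 0.0, 0.0), start_serial=5000)
    fad = planar_fad(center=(0.0, 0.0, -2.0), start_serial=6000)
    return Structure(atoms + fad + lig, id="box"), spec


class TestProcreate:
    def test_hollow_box_matches_brute_force(self):
        s, spec = hollow_box_structure()
        frame = locate_flavin(s, ligand_spec=spec)
        cloud = procreate_cavity(s, spec, frame, grid_spacing=1.0)
        oracle = brute_force_cavity_points(s, spec, frame, grid_spacing=1.0)
        assert len(cloud) > 0
        assert point_sets_equal(cloud.coords, oracle)

    @pytest.mark.parametrize("seed", range(3))
    def test_toy_enzyme_matches_brute_force(self, seed):
        s, spec, manifest = make_toy_enzyme(seed=seed)
        frame = locate_flavin(s, ligand_spec=spec)
        cloud = procreate_cavity(s, spec, frame)
        assert len(cloud) == manifest.planted["cavity_point_count"]
        oracle = brute_force_cavity_points(s, spec, frame)
        assert point_sets_equal(cloud.coords, oracle)

    def test_point_at_atom_center_excluded(self):
        s, spec = hollow_box_structure()
        frame = locate_flavin(s, ligand_spec=spec)
        cloud = procreate_cavity(s, spec, frame, grid_spacing=1.0)
        wall = s.coords_of(s.protein_heavy_atoms())
        d = np.linalg.norm(cloud.coords[:, None, :] - wall[None, :, :], axis=-1)
        assert d.min() >= 1.7  # every point clears the carbon vdW radius

    def test_no_protein_no_buriedness_keeps_ligand_envelope(self):
        lig, spec = fatty_acid(4)
        s = Structure(planar_fad() + lig, id="free")
        frame = locate_flavin(s, ligand_spec=spec)
        cloud = procreate_cavity(s, spec, frame, grid_spacing=1.0,
                                 buriedness_min=0.0, annotate=False)
        lig_xyz = np.stack([a.coords for a in lig if a.element != "H"])
        d = np.linalg.norm(cloud.coords[:, None, :] - lig_xyz[None, :, :],
                           axis=-1).min(axis=1)
        assert np.all(d <= 5.0)
        oracle = brute_force_cavity_points(s, spec, frame, grid_spacing=1.0,
                                           buriedness_min=0.0)
        assert point_sets_equal(cloud.coords, oracle)

    def test_empty_cavity_error(self):
        lig, spec = fatty_acid(2)
        s = Structure(planar_fad() + lig, id="open")
        frame = locate_flavin(s, ligand_spec=spec)
        # nothing around the ligand is buried: the solvent filter kills all
        with pytest.raises(EmptyCavityError):
            procreate_cavity(s, spec, frame, buriedness_min=0.99)

    def test_monotonic_in_parameters(self):
        s, spec, _ = make_toy_enzyme(seed=3, compute_cavity_oracle=False)
        frame = locate_flavin(s, ligand_spec=spec)
        n = [len(procreate_cavity(s, spec, frame, max_ligand_distance=d,
                                  annotate=False))
             for d in (3.0, 4.0, 5.0)]
        assert n == sorted(n)
        m = [len(procreate_cavity(s, spec, frame, probe_radius=p,
                                  annotate=False))
             for p in (1.0, 1.4, 1.8)]
        assert m == sorted(m, reverse=True)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_rigid_transform_equivariance(self, seed):
        """The annotated cloud of a moved structure is the moved cloud."""
        s, spec, _ = make_toy_enzyme(seed=seed, compute_cavity_oracle=False)
        rng = np.random.default_rng(seed + 100)
        R = random_rotation(rng)
        t = rng.uniform(-30, 30, 3)
        frame = locate_flavin(s, ligand_spec=spec)
        cloud = procreate_cavity(s, spec, frame)
        s2 = s.transformed(R, t)
        frame2 = locate_flavin(s2, ligand_spec=spec)
        cloud2 = procreate_cavity(s2, spec, frame2)
        assert len(cloud) == len(cloud2)
        moved = cloud.transformed(R, t)
        # same grid indices -> same ordering, so compare point-for-point
        np.testing.assert_allclose(cloud2.coords, moved.coords, atol=1e-6)
        np.testing.assert_allclose(cloud2.properties, cloud.properties,
                                   atol=1e-6)


class TestAnnotation:
    def test_single_positive_charge_gives_positive_potential(self):
        arg = [make_atom(1, "NE", "N", "ARG", "A", 1, (5.0, 0, 0)),
               make_atom(2, "NH1", "N", "ARG", "A", 1, (5.0, 0.8, 0)),
               make_atom(3, "NH2", "N", "ARG", "A", 1, (5.0, -0.8, 0))]
        s = Structure(arg + planar_fad(center=(0, 0, -3)), id="plus")
        pos, q = partial_charges(s)
        assert len(q) == 1 and q[0] == 1.0
        frame = locate_flavin(s)
        from catalocavity.cavity import PointCloud
        cloud = PointCloud(np.zeros((1, 3)), np.zeros((1, 5)), frame, 1.0)
        annotate_properties(cloud, s)
        assert cloud.electrostatic[0] > 0

    def test_hbond_donor_ramp_midpoint(self):
        """Arg NH1 nitrogen at 3.25 A gives exactly the half-ramp score."""
        arg = [make_atom(1, "NH1", "N", "ARG", "A", 1, (3.25, 0, 0))]
        s = Structure(arg + planar_fad(center=(0, 0, -5)), id="donor")
        frame = locate_flavin(s)
        from catalocavity.cavity import PointCloud
        cloud = PointCloud(np.zeros((1, 3)), np.zeros((1, 5)), frame, 1.0)
        annotate_properties(cloud, s)
        assert cloud.properties[0, 1] == pytest.approx(0.5, abs=1e-9)

    def test_potential_matches_hand_formula(self):
        """Two known charges: potential equals sum q / (4 r^2)."""
        atoms = [make_atom(1, "NZ", "N", "LYS", "A", 1, (3.0, 0, 0)),
                 make_atom(2, "OD1", "O", "ASP", "A", 2, (0, 4.0, 0)),
                 make_atom(3, "OD2", "O", "ASP", "A", 2, (0, 4.0, 0))]
        s = Structure(atoms + planar_fad(center=(0, 0, -5)), id="two")
        frame = locate_flavin(s)
        from catalocavity.cavity import PointCloud
        cloud = PointCloud(np.zeros((1, 3)), np.zeros((1, 5)), frame, 1.0)
        annotate_properties(cloud, s)
        expected = 1.0 / (4 * 3.0 ** 2) + (-1.0) / (4 * 4.0 ** 2)
        assert cloud.electrostatic[0] == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("residue,expected", [("ARG", True), ("ASP", False)])
    def test_charge_stabilization_sign(self, residue, expected):
        s, spec, _ = make_toy_enzyme(seed=4, arg_near_n5=False,
                                     charged_residue=residue,
                                     compute_cavity_oracle=False)
        frame = locate_flavin(s, ligand_spec=spec)
        cloud = procreate_cavity(s, spec, frame)
        assert negative_charge_stabilization(cloud) is expected
        # brute-force mean over the N5 neighbourhood agrees in sign
        near = np.linalg.norm(cloud.coords - frame.n5, axis=1) <= 4.0
        mean = float(np.mean([cloud.electrostatic[i]
                              for i in range(len(cloud)) if near[i]]))
        assert (mean > 0) is expected

    def test_stabilization_inconclusive_without_nearby_points(self):
        s, spec, _ = make_toy_enzyme(seed=4, compute_cavity_oracle=False)
        frame = locate_flavin(s, ligand_spec=spec)
        cloud = procreate_cavity(s, spec, frame)
        far = cloud.transformed(np.eye(3), np.zeros(3))
        far.coords = far.coords + 100.0  # move all points away from N5
        assert negative_charge_stabilization(far) is None


def test_icosahedral_directions_are_unit_and_symmetric():
    dirs = icosahedral_directions()
    assert dirs.shape == (42, 3)
    np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-12)
    # antipodal symmetry: the set is closed under negation
    s = set(map(tuple, np.round(dirs, 9)))
    assert set(map(tuple, np.round(-dirs, 9))) == s


def test_buriedness_fully_enclosed_point():
    """A point inside a dense closed shell sees every ray occluded."""
    rng = np.random.default_rng(0)
    dirs = icosahedral_directions()
    shell = 5.0 * dirs  # one atom straight down every ray direction
    b = buriedness_of_points(np.zeros((1, 3)), shell, np.full(42, 1.7))
    assert b[0] == 1.0


def test_cloud_json_round_trip(tmp_path):
    s, spec, _ = make_toy_enzyme(seed=6, compute_cavity_oracle=False)
    frame = locate_flavin(s, ligand_spec=spec)
    cloud = procreate_cavity(s, spec, frame)
    p = tmp_path / "cloud.json"
    write_cloud_json(cloud, p)
    back = read_cloud_json(p)
    np.testing.assert_allclose(back.coords, cloud.coords)
    np.testing.assert_allclose(back.properties, cloud.properties)
    np.testing.assert_allclose(back.frame.n5, cloud.frame.n5)
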