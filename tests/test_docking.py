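"""Grid energies, Metropolis docking, pose clustering and contacts."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nanocg import bodies, docking as dk, fixtures as fx
from nanocg import forcefield as ff


def _body(coords, species, masses=None, kind="generic", name="b"):
    coords = np.asarray(coords, dtype=float)
    masses = np.ones(len(coords)) if masses is None else np.asarray(masses)
    return bodies.body_from_beads(name, kind, coords, species, masses,
                                  orient_to_principal=False)


@pytest.fixture(scope="module")
def toy_params():
    species = {
        "P": ff.Species("P", sigma=5.0, epsilon=0.5, hindex=0.5, charge=1.0,
                        mass=0.12),
        "N": ff.Species("N", sigma=5.0, epsilon=0.5, hindex=0.5, charge=-1.0,
                        mass=0.12),
        "O": ff.Species("O", sigma=5.0, epsilon=0.5, hindex=0.5, charge=0.0,
                        mass=0.12),
    }
    return ff.FFParams(species=species, debye_length=17.6)


class TestSasa:
    def test_isolated_bead_full_sphere(self):
        sasa = dk.shrake_rupley_sasa(np.zeros((1, 3)), np.array([2.5]))
        assert sasa[0] == pytest.approx(4 * np.pi * 3.9 ** 2, rel=1e-9)

    def test_distant_beads_unscreened(self):
        sasa = dk.shrake_rupley_sasa(
            np.array([[0.0, 0, 0], [50.0, 0, 0]]), np.array([2.5, 2.5]))
        assert np.allclose(sasa, 4 * np.pi * 3.9 ** 2)

    def test_buried_bead_zero(self):
        # small bead fully inside a large one
        sasa = dk.shrake_rupley_sasa(
            np.array([[0.0, 0, 0], [0.5, 0, 0]]), np.array([1.0, 8.0]))
        assert sasa[0] == 0.0


class TestGrids:
    def test_zero_charge_solute_has_zero_potential(self, toy_params):
        body = _body([[0, 0, 0], [4, 0, 0]], ["O", "O"])
        sol = dk.make_solute(body, toy_params)
        grids = dk.build_grids(sol, toy_params, spacing=1.0, margin=8.0)
        assert np.all(grids.phi_el == 0.0)

    def test_potential_matches_direct_sum(self, toy_params):
        body = _body([[0, 0, 0], [4, 0, 0], [0, 3, 1]], ["P", "N", "P"])
        sol = dk.make_solute(body, toy_params)
        grids = dk.build_grids(sol, toy_params, spacing=0.5, margin=10.0)
        rng = np.random.default_rng(4)
        probes = rng.uniform(-4, 8, size=(60, 3))
        # trilinear interpolation degrades right at the bead surfaces; probe
        # the solvent-side region where docking actually evaluates the field
        dmin = np.min(np.linalg.norm(
            probes[:, None, :] - sol.body.body_coords[None], axis=2), axis=1)
        probes = probes[dmin > 3.5]
        assert len(probes) > 20
        interp = grids.interpolate("phi_el", probes)
        direct = _direct_phi_el(sol, probes, toy_params)
        assert np.max(np.abs(interp - direct)) < 0.05

    def test_grid_error_decreases_with_spacing(self, toy_params):
        body = _body([[0, 0, 0], [4, 0, 0], [0, 3, 1]], ["P", "N", "P"])
        sol = dk.make_solute(body, toy_params)
        rng = np.random.default_rng(7)
        probes = rng.uniform(-3, 7, size=(60, 3))
        direct = _direct_phi_el(sol, probes, toy_params)
        errs = []
        for spacing in (2.0, 1.0, 0.5):
            grids = dk.build_grids(sol, toy_params, spacing=spacing, margin=10.0)
            errs.append(np.max(np.abs(
                grids.interpolate("phi_el", probes) - direct)))
        assert errs[0] > errs[1] > errs[2]

    def test_nonpositive_spacing_rejected(self, toy_params):
        body = _body([[0, 0, 0]], ["P"])
        sol = dk.make_solute(body, toy_params)
        with pytest.raises(ValueError):
            dk.build_grids(sol, toy_params, spacing=0.0)


def _direct_phi_el(sol, points, params):
    """Grid-free potential with the same finite-bead clamp as the grids."""
    lam = params.debye_length
    out = np.zeros(len(points))
    for c, q, rad in zip(sol.body.body_coords, sol.charges, sol.radii):
        d = np.maximum(np.maximum(np.linalg.norm(points - c, axis=1), 0.5),
                       rad)
        out += params.bjerrum * q * np.exp(-d / lam) / d
    return out


def _prepared_solutes(toy_params, coords1, species1, coords2, species2,
                      spacing=0.5):
    s1 = dk.make_solute(_body(coords1, species1), toy_params)
    s2 = dk.make_solute(_body(coords2, species2), toy_params)
    s1.grids = dk.build_grids(s1, toy_params, spacing=spacing, margin=14.0)
    s2.grids = dk.build_grids(s2, toy_params, spacing=spacing, margin=14.0)
    return s1, s2


class TestSdaEnergy:
    def test_solute_swap_symmetry(self, toy_params):
        s1, s2 = _prepared_solutes(
            toy_params, [[0, 0, 0], [4, 0, 0], [0, 3, 1]], ["P", "N", "P"],
            [[0, 0, 0], [3.5, 0, 0]], ["N", "O"])
        rng = np.random.default_rng(1)
        for _ in range(5):
            quat = bodies.random_quaternion(rng)
            trans = rng.uniform(6, 12) * _unit(rng)
            pose = dk.sda_energy(s1, s2, dk.Pose(quat=quat, translation=trans))
            inv_rot = Rotation.from_quat(quat).inv()
            inv_pose = dk.Pose(quat=inv_rot.as_quat(),
                               translation=-inv_rot.apply(trans))
            swapped = dk.sda_energy(s2, s1, inv_pose)
            assert swapped.total == pytest.approx(pose.total, abs=1e-9)

    def test_zero_charges_kill_electrostatic_terms(self, toy_params):
        s1, s2 = _prepared_solutes(toy_params, [[0, 0, 0], [4, 0, 0]],
                                   ["O", "O"], [[0, 0, 0]], ["O"])
        pose = dk.sda_energy(s1, s2, dk.Pose(
            quat=bodies.IDENTITY_QUAT.copy(), translation=np.array([7.0, 0, 0])))
        assert pose.el == 0.0
        assert pose.edesolv == 0.0
        assert pose.total == pose.npdesolv + pose.softcore

    def test_matches_grid_free_direct_sum(self, toy_params):
        s1, s2 = _prepared_solutes(
            toy_params, [[0, 0, 0], [4.5, 0, 0]], ["P", "N"],
            [[0, 0, 0], [0, 4, 0], [0, 0, 4]], ["N", "O", "P"],
            spacing=0.25)
        pose = dk.Pose(quat=bodies.IDENTITY_QUAT.copy(),
                       translation=np.array([9.0, 1.0, -1.0]))
        pose = dk.sda_energy(s1, s2, pose)
        direct = _direct_sda(s1, s2, pose, toy_params)
        assert pose.total == pytest.approx(direct, abs=0.5)


def _unit(rng):
    u = rng.normal(size=3)
    return u / np.linalg.norm(u)


def _direct_sda(s1, s2, pose, params):
    """Grid-free evaluation of the same four kernels."""
    p2 = pose.apply(s2.body.body_coords)
    p1 = s1.body.body_coords
    lam = params.debye_length

    def phi_el(sources, charges, radii, points):
        out = np.zeros(len(points))
        for c, q, rad in zip(sources, charges, radii):
            d = np.maximum(np.maximum(
                np.linalg.norm(points - c, axis=1), 0.5), rad)
            out += params.bjerrum * q * np.exp(-d / lam) / d
        return out

    def surf_dist(sources, radii, points):
        d = np.full(len(points), np.inf)
        for c, r in zip(sources, radii):
            d = np.minimum(d, np.maximum(
                np.linalg.norm(points - c, axis=1), 0.5) - r)
        return d

    def edesolv(sources, radii, points):
        return dk.EDESOLV_SCALE * np.exp(
            -np.maximum(surf_dist(sources, radii, points), 0.0)
            / dk.EDESOLV_DECAY)

    def npdesolv(sources, radii, points):
        d = surf_dist(sources, radii, points)
        lo, hi = dk.NPDESOLV_SHELL
        return np.where((d >= lo) & (d <= hi), dk.NPDESOLV_BETA, 0.0)

    def softcore(sources, radii, points):
        e = np.zeros(len(points))
        for c, r in zip(sources, radii):
            d = np.maximum(np.linalg.norm(points - c, axis=1), 0.5)
            e += (2 * r / d) ** dk.SOFTCORE_EXP
        return np.minimum(e, dk.SOFTCORE_CAP)

    total = 0.5 * phi_el(p1, s1.charges, s1.radii, p2) @ s2.charges + \
        0.5 * phi_el(p2, s2.charges, s2.radii, p1) @ s1.charges
    total += edesolv(p1, s1.radii, p2) @ (s2.charges ** 2) + \
        edesolv(p2, s2.radii, p1) @ (s1.charges ** 2)
    total += npdesolv(p1, s1.radii, p2) @ s2.sasa + \
        npdesolv(p2, s2.radii, p1) @ s1.sasa
    total += 0.5 * softcore(p1, s1.radii, p2).sum() + \
        0.5 * softcore(p2, s2.radii, p1).sum()
    return float(total)


def _analytic_well_solutes(toy_params, wells):
    """Single-bead solutes with hand-built grids: the docking landscape is a
    sum of analytic Gaussian wells, so the global minimum is known exactly.

    *wells* is a list of (center, depth_kT_per_e, width_Å); only solute 1's
    electrostatic grid is populated and the probe carries charge +1, so the
    total pose energy is exactly 1/2 sum of the wells at the probe position.
    """
    s1 = dk.make_solute(_body([[0, 0, 0]], ["O"]), toy_params)
    s2 = dk.make_solute(_body([[0, 0, 0]], ["P"]), toy_params)
    spacing, half = 1.0, 30
    axis = spacing * np.arange(-half, half + 1)
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)
    phi = np.zeros(gx.shape)
    for center, depth, width in wells:
        d2 = ((pts - np.asarray(center)) ** 2).sum(axis=-1)
        phi -= depth * np.exp(-d2 / (2 * width ** 2))
    zeros = np.zeros_like(phi)
    origin = np.array([-half, -half, -half], dtype=float)
    s1.grids = dk.EnergyGrids(phi_el=phi, phi_edesolv=zeros,
                              phi_npdesolv=zeros, e_lj=zeros,
                              origin=origin, spacing=spacing)
    s2.grids = dk.EnergyGrids(phi_el=zeros.copy(), phi_edesolv=zeros,
                              phi_npdesolv=zeros, e_lj=zeros,
                              origin=origin, spacing=spacing)
    s2.charges = np.array([2.0])
    s1.charges = np.array([0.0])
    return s1, s2


class TestDocking:
    WELL = ([9.0, 3.0, -2.0], 20.0, 4.0)

    def test_determinism(self, toy_params):
        s1, s2 = _analytic_well_solutes(toy_params, [self.WELL])
        a = dk.run_docking(s1, s2, n_starts=10, seed=42, n_moves=150)
        b = dk.run_docking(s1, s2, n_starts=10, seed=42, n_moves=150)
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.translation, pb.translation)
            assert pa.total == pb.total

    def test_retained_at_most_n_starts(self, toy_params):
        s1, s2 = _analytic_well_solutes(toy_params, [self.WELL])
        poses = dk.run_docking(s1, s2, n_starts=8, seed=3, n_moves=150)
        assert len(poses) <= 8

    def test_engineered_well_is_found(self, toy_params):
        center, depth, _ = self.WELL
        s1, s2 = _analytic_well_solutes(toy_params, [self.WELL])
        poses = dk.run_docking(s1, s2, n_starts=40, seed=7, n_moves=400,
                               retention_threshold=-1.0)
        assert len(poses) >= 10
        close = [p for p in poses
                 if np.linalg.norm(p.translation - np.array(center)) < 5.0]
        assert len(close) >= 0.9 * len(poses)
        # the best pose reaches the analytic depth (1/2 * q * depth)
        assert min(p.total for p in poses) == pytest.approx(-depth, rel=0.05)

    def test_more_starts_keep_the_deepest_basin(self, toy_params):
        shallow = ([-10.0, -4.0, 5.0], 6.0, 4.0)
        s1, s2 = _analytic_well_solutes(toy_params, [self.WELL, shallow])
        small = dk.run_docking(s1, s2, n_starts=10, seed=5, n_moves=300,
                               retention_threshold=-1.0)
        large = dk.run_docking(s1, s2, n_starts=40, seed=5, n_moves=300,
                               retention_threshold=-1.0)
        assert min(p.total for p in large) <= min(p.total for p in small) + 0.5
        # the deep engineered basin is not lost when starts are scaled up
        center = np.array(self.WELL[0])
        assert any(np.linalg.norm(p.translation - center) < 5.0
                   for p in large)


class TestClustering:
    def _pose(self, xyz, total):
        p = dk.Pose(quat=bodies.IDENTITY_QUAT.copy(),
                    translation=np.asarray(xyz, dtype=float))
        p.el = total
        p.edesolv = p.npdesolv = p.softcore = 0.0
        return p

    def test_single_pose(self):
        coords = np.zeros((1, 3))
        clusters = dk.cluster_poses([self._pose([5, 0, 0], -1.0)], coords)
        assert len(clusters) == 1
        assert clusters[0].relpop == 100.0
        assert clusters[0].spread == 0.0

    def test_relpop_partition_sums_to_100(self):
        coords = np.zeros((1, 3))
        poses = [self._pose([k, 0, 0], -1.0 - 0.01 * k) for k in range(7)] + \
            [self._pose([40 + k, 0, 0], -0.5) for k in range(5)]
        clusters = dk.cluster_poses(poses, coords, rmsd_cutoff=10.0)
        assert sum(c.relpop for c in clusters) == pytest.approx(100.0, abs=0.1)
        assert sum(len(c.members) for c in clusters) == len(poses)

    def test_engineered_three_to_one_split(self):
        coords = np.zeros((1, 3))
        basin_a = [self._pose([0, 0, 0], -5.0), self._pose([1, 0, 0], -4.0),
                   self._pose([0, 1, 0], -4.5)]
        basin_b = [self._pose([50, 0, 0], -6.0)]
        clusters = dk.cluster_poses(basin_a + basin_b, coords, rmsd_cutoff=5.0)
        assert [round(c.relpop) for c in clusters] == [75, 25]

    def test_ordered_by_population(self):
        coords = np.zeros((1, 3))
        poses = [self._pose([0, 0, 0], -1.0)] + \
            [self._pose([50 + k, 0, 0], -3.0) for k in range(3)]
        clusters = dk.cluster_poses(poses, coords, rmsd_cutoff=5.0)
        assert clusters[0].relpop >= clusters[1].relpop

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dk.cluster_poses([], np.zeros((1, 3)))


class TestContacts:
    def test_distant_bodies_no_contacts(self, small_protein, ms_np):
        pose = dk.Pose(quat=bodies.IDENTITY_QUAT.copy(),
                       translation=np.array([100.0, 0, 0]))
        assert dk.contact_residues(pose, small_protein, ms_np) == []

    def test_boundary_distance_included(self):
        prot = _body([[0.0, 0, 0]], ["O"], kind="protein")
        prot.residue_ids = ["GLY1"]
        npb = fx.make_cg_np_body()
        # place the nearest NP bead exactly 5.5 Å from the residue bead
        near = npb.body_coords[1]
        pose = dk.Pose(quat=bodies.IDENTITY_QUAT.copy(),
                       translation=-(near + np.array([0.0, 0, 0])) +
                       np.array([5.5, 0, 0]) + near - near)
        # simpler: translate so bead 1 sits at (5.5, 0, 0)
        pose.translation = np.array([5.5, 0.0, 0.0]) - near
        contacts = dk.contact_residues(pose, prot, npb)
        assert contacts == ["GLY1"]

    def test_matches_brute_force(self, small_protein):
        npb = fx.make_cg_np_body()
        rng = np.random.default_rng(9)
        pose = dk.Pose(quat=bodies.random_quaternion(rng),
                       translation=rng.uniform(-20, 20, 3))
        got = dk.contact_residues(pose, small_protein, npb, cutoff=5.5)
        prot = small_protein.rotation().apply(small_protein.body_coords)
        np_coords = pose.apply(npb.body_coords)
        expected = []
        for i, rid in enumerate(small_protein.residue_ids):
            dmin = min(np.linalg.norm(prot[i] - c) for c in np_coords)
            if dmin <= 5.5:
                expected.append(rid)
        assert got == expected


class TestTsvOutput:
    def test_table_layout(self, toy_params, tmp_path):
        coords = np.zeros((1, 3))
        p = dk.Pose(quat=bodies.IDENTITY_QUAT.copy(),
                    translation=np.array([5.0, 0, 0]),
                    el=-2.0, edesolv=0.5, npdesolv=-1.0, softcore=0.25)
        clusters = dk.cluster_poses([p], coords)
        out = tmp_path / "clusters.tsv"
        dk.clusters_to_tsv(clusters, out)
        lines = out.read_text().strip().splitlines()
        assert lines[0].startswith("relpop_pct")
        fields = lines[1].split("\t")
        assert float(fields[0]) == 100.0
        assert float(fields[1]) == pytest.approx(-2.25)
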