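"""Superposition, RMSF, simplified secondary structure, angles, H-bonds."""

import numpy as np
import pytest

import allokit
from allokit.ensembles import Ensemble, Topology
from allokit.errors import DegenerateFitError
from allokit.structure import (assign_sse, hbond_series, hinge_angle, rmsf,
                               sse_persistency, superpose, SSERecord)


# ---------------------------------------------------------------------------
# backbone builders for geometric fixtures


def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom d from three predecessors by internal coordinates."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(angle),
        np.sin(angle) * np.cos(torsion),
        np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _backbone_from_dihedrals(n_res, phi, psi, omega=180.0):
    """Ideal-geometry backbone (N, CA, C, O per residue) from phi/psi."""
    coords = {"N": [], "CA": [], "C": []}
    coords["N"].append(np.array([0.0, 0.0, 0.0]))
    coords["CA"].append(np.array([1.458, 0.0, 0.0]))
    coords["C"].append(coords["CA"][0] + 1.525 * np.array(
        [np.cos(np.radians(180 - 111.2)), np.sin(np.radians(180 - 111.2)), 0.0]))
    for i in range(1, n_res):
        n_new = _nerf(coords["N"][-1], coords["CA"][-1], coords["C"][-1],
                      1.329, 116.2, psi)
        ca_new = _nerf(coords["CA"][-1], coords["C"][-1], n_new,
                       1.458, 121.7, omega)
        c_new = _nerf(coords["C"][-1], n_new, ca_new, 1.525, 111.2, phi)
        coords["N"].append(n_new)
        coords["CA"].append(ca_new)
        coords["C"].append(c_new)
    atom_names, elements, atom_residue, xyz = [], [], [], []
    for i in range(n_res):
        o_pos = _nerf(coords["N"][i], coords["CA"][i], coords["C"][i],
                      1.231, 120.8, psi + 180.0)
        for name, elem, p in (("N", "N", coords["N"][i]),
                              ("CA", "C", coords["CA"][i]),
                              ("C", "C", coords["C"][i]), ("O", "O", o_pos)):
            atom_names.append(name)
            elements.append(elem)
            atom_residue.append(i)
            xyz.append(p)
    top = Topology(
        atom_names=np.array(atom_names, dtype=object),
        elements=np.array(elements, dtype=object),
        atom_residue=np.array(atom_residue),
        res_ids=np.arange(1, n_res + 1),
        res_names=np.array(["ALA"] * n_res, dtype=object),
        chain_tags=np.array(["f"] * n_res, dtype=object),
    )
    return Ensemble(topology=top, coords=np.array(xyz)[None])


def _antiparallel_pair_fixture():
    """Eight residues; residues 1 and 6 form a mutual (antiparallel) CO/NH
    hydrogen-bond pair by explicit geometric placement; 3 and 4 sit far away."""
    placements = {}   # residue -> dict(atom -> xyz)

    def residue(i, n, ca, c, o):
        placements[i] = {"N": n, "CA": ca, "C": c, "O": o}

    far = np.array([0.0, 0.0, 50.0])
    # residue 0: provides the carbonyl that orients H of residue 1 (+y)
    residue(0, np.array([-4.5, 0.0, 0.0]), np.array([-3.5, 0.5, 0.0]),
            np.array([-2.5, 0.0, 0.0]), np.array([-2.5, -1.23, 0.0]))
    # residue 1: CO and NH both pointing +y (toward the partner strand)
    residue(1, np.array([-1.2, 1.0, 0.0]), np.array([0.0, 0.0, 0.0]),
            np.array([1.2, 0.5, 0.0]), np.array([1.2, 1.73, 0.0]))
    residue(2, far + np.array([0, 0, 0]), far + np.array([1.5, 0, 0]),
            far + np.array([3.0, 0, 0]), far + np.array([3.0, 1.23, 0]))
    for k, shift in ((3, 10.0), (4, 20.0)):
        base = far + np.array([shift, 0, 0])
        residue(k, base, base + np.array([1.5, 0, 0]),
                base + np.array([3.0, 0, 0]), base + np.array([3.0, 1.23, 0]))
    # residue 5: orients H of residue 6 (-y)
    residue(5, np.array([4.5, 5.8, 0.0]), np.array([3.5, 5.3, 0.0]),
            np.array([2.5, 5.8, 0.0]), np.array([2.5, 7.03, 0.0]))
    # residue 6: CO and NH pointing -y, facing residue 1
    residue(6, np.array([1.2, 4.63, 0.0]), np.array([0.0, 5.63, 0.0]),
            np.array([-1.2, 5.13, 0.0]), np.array([-1.2, 3.9, 0.0]))
    base = far + np.array([30.0, 0, 0])
    residue(7, base, base + np.array([1.5, 0, 0]),
            base + np.array([3.0, 0, 0]), base + np.array([3.0, 1.23, 0]))

    atom_names, elements, atom_residue, xyz = [], [], [], []
    for i in range(8):
        for name in ("N", "CA", "C", "O"):
            atom_names.append(name)
            elements.append(name[0])
            atom_residue.append(i)
            xyz.append(placements[i][name])
    top = Topology(
        atom_names=np.array(atom_names, dtype=object),
        elements=np.array(elements, dtype=object),
        atom_residue=np.array(atom_residue),
        res_ids=np.arange(1, 9),
        res_names=np.array(["ALA"] * 8, dtype=object),
        chain_tags=np.array(["f"] * 8, dtype=object),
    )
    return Ensemble(topology=top, coords=np.array(xyz)[None])


# ---------------------------------------------------------------------------


class TestSuperpose:
    def test_identical_frame_zero_rmsd(self, toy):
        top, ref = toy
        ens = Ensemble(topology=top, coords=np.repeat(ref[None], 3, axis=0))
        _, rmsd = superpose(ens, reference=ref)
        np.testing.assert_allclose(rmsd, 0.0, atol=1e-12)

    def test_rigid_motion_removed(self, toy):
        top, ref = toy
        theta = np.pi / 2
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = ref @ rot.T + np.array([5.0, -3.0, 8.0])
        ens = Ensemble(topology=top, coords=moved[None])
        _, rmsd = superpose(ens, reference=ref)
        assert rmsd[0] < 1e-6

    def test_single_displaced_atom_closed_form(self):
        # symmetric 10-Cα ring: a 1 Å radial displacement of one atom exerts
        # no torque, so the optimal rotation stays the identity and the
        # optimal translation is the mean displacement d/n; the residual is
        # exactly RMSD = |d| sqrt(n-1)/n
        n = 10
        angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
        ca = np.stack([10 * np.cos(angles), 10 * np.sin(angles),
                       np.zeros(n)], axis=1)
        top = Topology(
            atom_names=np.array(["CA"] * n, dtype=object),
            elements=np.array(["C"] * n, dtype=object),
            atom_residue=np.arange(n),
            res_ids=np.arange(1, n + 1),
            res_names=np.array(["ALA"] * n, dtype=object),
            chain_tags=np.array(["f"] * n, dtype=object),
        )
        moved = ca.copy()
        moved[0] = ca[0] * 1.1       # radial, |d| = 1 Å
        ens = Ensemble(topology=top, coords=moved[None])
        _, rmsd = superpose(ens, reference=ca)
        assert rmsd[0] == pytest.approx(np.sqrt(n - 1) / n, abs=1e-9)

    def test_idempotent_on_aligned_ensemble(self, small_ensemble):
        aligned, _ = superpose(small_ensemble)
        again, _ = superpose(aligned)
        np.testing.assert_allclose(aligned.coords, again.coords, atol=1e-9)

    def test_collinear_reference_rejected(self):
        n = 5
        ca = np.stack([np.arange(n, dtype=float), np.zeros(n), np.zeros(n)],
                      axis=1)
        top = Topology(
            atom_names=np.array(["CA"] * n, dtype=object),
            elements=np.array(["C"] * n, dtype=object),
            atom_residue=np.arange(n),
            res_ids=np.arange(1, n + 1),
            res_names=np.array(["ALA"] * n, dtype=object),
            chain_tags=np.array(["f"] * n, dtype=object),
        )
        ens = Ensemble(topology=top, coords=ca[None])
        with pytest.raises(DegenerateFitError):
            superpose(ens, reference=ca)


class TestRmsf:
    def test_static_ensemble_zero(self, toy):
        top, ref = toy
        ens = Ensemble(topology=top, coords=np.repeat(ref[None], 5, axis=0),
                       aligned=True)
        np.testing.assert_allclose(rmsf(ens), 0.0, atol=1e-12)

    def test_isotropic_gaussian_analytic_moment(self):
        # generator output carries no rigid-body motion, so it is aligned by
        # construction; re-fitting would eat ~6/(3N) of the variance
        top, ref = allokit.make_toy_topology(40, seed=1)
        sigma = 0.5
        spec = allokit.PlantedEnsembleSpec(n_residues=40, n_frames=20000,
                                           base_variance=sigma ** 2, seed=2)
        ens = allokit.sample_gaussian_ensemble(top, ref, spec)
        values = rmsf(ens.with_coords(ens.coords, aligned=True))
        assert np.mean(values) == pytest.approx(sigma * np.sqrt(3), rel=0.02)

    def test_mobile_segment_above_background(self, toy):
        top, ref = toy
        cov = np.diag(np.where(np.repeat(np.arange(10), 3) == 4, 2.0, 0.05))
        spec = allokit.PlantedEnsembleSpec(
            n_residues=10, n_frames=5000, covariance_kind="custom",
            custom_covariance=cov, seed=3)
        ens = allokit.sample_gaussian_ensemble(top, ref, spec)
        aligned, _ = superpose(ens)
        values = rmsf(aligned)
        assert values[4] > 2 * values[[0, 1, 2, 8, 9]].max()

    def test_invariant_under_global_rotation(self, small_ensemble):
        aligned, _ = superpose(small_ensemble)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        rotated = aligned.with_coords(aligned.coords @ rot.T)
        np.testing.assert_allclose(rmsf(aligned), rmsf(rotated), atol=1e-9)

    def test_single_frame_warns(self, toy):
        top, ref = toy
        ens = Ensemble(topology=top, coords=ref[None], aligned=True)
        with pytest.warns(UserWarning):
            assert np.all(rmsf(ens) == 0.0)


class TestSecondaryStructure:
    def test_ideal_alpha_helix_interior_is_helix(self):
        ens = _backbone_from_dihedrals(20, phi=-57.0, psi=-47.0)
        record = assign_sse(ens)
        interior = record.classes[0, 5:15]
        assert np.all(interior == "H")

    def test_antiparallel_bridge_pair_is_sheet(self):
        ens = _antiparallel_pair_fixture()
        record = assign_sse(ens)
        assert record.classes[0, 1] == "E"
        assert record.classes[0, 6] == "E"

    def test_random_coil_mostly_coil(self, toy):
        top, ref = toy
        ens = Ensemble(topology=top, coords=ref[None])
        record = assign_sse(ens)
        assert np.mean(record.classes == "C") >= 0.8

    def test_extended_strand_alone_is_not_helix(self):
        ens = _backbone_from_dihedrals(12, phi=-139.0, psi=135.0)
        record = assign_sse(ens)
        assert not np.any(record.classes == "H")

    def test_persistency_arithmetic(self):
        classes = np.array([["H", "C"]] * 5 + [["C", "C"]] * 5)
        record = SSERecord(nodes=["f1", "f2"], classes=classes)
        pers = sse_persistency(record, ["H", "E"])
        assert pers[0] == pytest.approx(0.5)
        assert pers[1] == 0.0
        all_match = sse_persistency(record, ["C", "C"])
        assert all_match[1] == 1.0

    def test_from_table_roundtrip(self):
        import pandas as pd
        rows = [(f, r, c) for f in range(3)
                for r, c in (("f1", "H"), ("f2", "C"))]
        table = pd.DataFrame(rows, columns=["frame", "residue", "sse"])
        record = SSERecord.from_table(table)
        assert record.classes.shape == (3, 2)
        assert set(record.nodes) == {"f1", "f2"}


class TestHingeAngle:
    def _ens_with_ca(self, points):
        n = len(points)
        top = Topology(
            atom_names=np.array(["CA"] * n, dtype=object),
            elements=np.array(["C"] * n, dtype=object),
            atom_residue=np.arange(n),
            res_ids=np.arange(1, n + 1),
            res_names=np.array(["GLY"] * n, dtype=object),
            chain_tags=np.array(["f"] * n, dtype=object),
        )
        return Ensemble(topology=top, coords=np.asarray(points, float)[None])

    def test_collinear_is_180(self):
        ens = self._ens_with_ca([[-1, 0, 0], [0, 0, 0], [1, 0, 0]])
        series = hinge_angle(ens, ("fG1", "fG2", "fG3"))
        assert series.angles[0] == pytest.approx(180.0)

    def test_perpendicular_arms_90(self):
        ens = self._ens_with_ca([[1, 0, 0], [0, 0, 0], [0, 1, 0]])
        series = hinge_angle(ens, ("fG1", "fG2", "fG3"))
        assert series.angles[0] == pytest.approx(90.0)

    def test_45_degrees(self):
        ens = self._ens_with_ca([[1, 0, 0], [0, 0, 0], [1, 1, 0]])
        series = hinge_angle(ens, ("fG1", "fG2", "fG3"))
        assert series.angles[0] == pytest.approx(45.0)

    def test_invariant_under_rigid_motion(self, small_ensemble):
        labels = small_ensemble.topology.labels
        triple = (labels[0], labels[4], labels[9])
        before = hinge_angle(small_ensemble, triple).angles
        theta = 1.1
        rot = np.array([[np.cos(theta), 0, np.sin(theta)], [0, 1, 0],
                        [-np.sin(theta), 0, np.cos(theta)]])
        moved = small_ensemble.with_coords(
            small_ensemble.coords @ rot.T + np.array([3.0, 4.0, -2.0]))
        np.testing.assert_allclose(hinge_angle(moved, triple).angles, before,
                                   atol=1e-9)

    def test_coincident_points_rejected(self):
        ens = self._ens_with_ca([[0, 0, 0], [0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError, match="frame 0"):
            hinge_angle(ens, ("fG1", "fG2", "fG3"))


class TestHbondSeries:
    def test_constant_short_distance_full_occupancy(self, toy):
        top, ref = toy
        coords = ref.copy()
        i_n = top.atom_index(3, "N")
        i_o = top.atom_index(1, "O")
        coords[i_n] = coords[i_o] + np.array([2.9, 0, 0])
        ens = Ensemble(topology=top, coords=np.repeat(coords[None], 10, axis=0))
        lbl_d = f"{top.label(3)}:N"
        lbl_a = f"{top.label(1)}:O"
        series = hbond_series(ens, lbl_d, lbl_a)
        assert series.occupancy == 1.0
        np.testing.assert_allclose(series.distances, 2.9, atol=1e-12)

    def test_planted_30_percent_occupancy(self, toy):
        top, ref = toy
        i_n = top.atom_index(3, "N")
        i_o = top.atom_index(1, "O")
        frames = []
        for k in range(10):
            c = ref.copy()
            d = 2.9 if k < 3 else 5.0
            c[i_n] = c[i_o] + np.array([d, 0, 0])
            frames.append(c)
        ens = Ensemble(topology=top, coords=np.array(frames))
        series = hbond_series(ens, f"{top.label(3)}:N", f"{top.label(1)}:O")
        assert series.occupancy == pytest.approx(0.30)

    def test_distances_match_manual_euclidean(self, small_ensemble):
        top = small_ensemble.topology
        series = hbond_series(small_ensemble.with_coords(
            small_ensemble.coords[:3]), f"{top.label(5)}:N", f"{top.label(2)}:O")
        i_n = top.atom_index(5, "N")
        i_o = top.atom_index(2, "O")
        for f in range(3):
            manual = np.sqrt(np.sum(
                (small_ensemble.coords[f, i_n] - small_ensemble.coords[f, i_o]) ** 2))
            assert series.distances[f] == pytest.approx(manual, abs=1e-12)

    def test_missing_atom_names_residue(self, small_ensemble):
        with pytest.raises(KeyError, match="f"):
            hbond_series(small_ensemble, "fZ999:N", "fA1:O")
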