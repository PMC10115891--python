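"""Generator contracts: geometry, seeded determinism, planted covariance."""

import numpy as np
import pytest

import allokit
from allokit.synthetic import (ContactShift, CouplingChange, build_covariance,
                               make_shift_table, make_study_triple,
                               make_toy_topology, make_two_state_pair,
                               sample_gaussian_ensemble, _pick_contact_pair)


class TestToyTopology:
    def test_split_arithmetic(self):
        top, _ = make_toy_topology(10, split=0.5, seed=7)
        assert int((top.chain_tags == "f").sum()) == 5
        assert int((top.chain_tags == "h").sum()) == 5

    def test_seeded_determinism(self):
        _, ref1 = make_toy_topology(12, seed=3)
        _, ref2 = make_toy_topology(12, seed=3)
        np.testing.assert_array_equal(ref1, ref2)

    def test_ca_spacing_and_sidechain_radius(self):
        top, ref = make_toy_topology(40, seed=5)
        ca = ref[top.ca_indices]
        spacing = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.all(np.abs(spacing - 3.8) <= 0.1)
        side = ~np.isin(top.atom_names, ("N", "CA", "C", "O", "H"))
        for a in np.nonzero(side)[0]:
            d = np.linalg.norm(ref[a] - ca[top.atom_residue[a]])
            assert d <= 2.5 + 1e-9

    def test_every_residue_has_one_ca(self):
        top, _ = make_toy_topology(15, seed=1)
        counts = np.bincount(top.atom_residue[top.atom_names == "CA"],
                             minlength=top.n_residues)
        assert np.all(counts == 1)

    def test_too_few_residues_rejected(self):
        with pytest.raises(ValueError):
            make_toy_topology(1)


class TestGaussianSampling:
    def test_identity_covariance_variance(self, toy):
        top, ref = toy
        spec = allokit.PlantedEnsembleSpec(n_residues=10, n_frames=20000, seed=4)
        ens = sample_gaussian_ensemble(top, ref, spec)
        disp = ens.ca_coords - ref[top.ca_indices]
        var = disp.reshape(len(disp), -1).var(axis=0)
        assert np.all(np.abs(var - 1.0) < 0.03 * 1.0 + 0.02)

    def test_planted_pair_pearson(self, toy):
        top, ref = toy
        spec = allokit.PlantedEnsembleSpec(
            n_residues=10, n_frames=20000, planted_pairs={(1, 6): 0.8}, seed=9)
        ens = sample_gaussian_ensemble(top, ref, spec)
        disp = ens.ca_coords - ref[top.ca_indices]
        for ax in range(3):
            r = np.corrcoef(disp[:, 1, ax], disp[:, 6, ax])[0, 1]
            assert abs(r - 0.8) < 0.02

    def test_temperature_scale_doubles_variance(self, toy):
        top, ref = toy
        cold = allokit.PlantedEnsembleSpec(n_residues=10, n_frames=20000, seed=2)
        hot = allokit.PlantedEnsembleSpec(n_residues=10, n_frames=20000,
                                          temperature_scale=2.0, seed=2)
        v_cold = sample_gaussian_ensemble(top, ref, cold).ca_coords.var(axis=0).mean()
        v_hot = sample_gaussian_ensemble(top, ref, hot).ca_coords.var(axis=0).mean()
        assert abs(v_hot / v_cold - 2.0) < 0.05

    def test_empirical_covariance_frobenius_convergence(self, toy):
        top, ref = toy
        spec = allokit.PlantedEnsembleSpec(
            n_residues=10, n_frames=20000,
            planted_pairs={(0, 5): 0.5, (2, 8): -0.4}, seed=21)
        ens = sample_gaussian_ensemble(top, ref, spec)
        disp = (ens.ca_coords - ref[top.ca_indices]).reshape(20000, -1)
        emp = np.cov(disp.T)
        planted = build_covariance(spec)
        rel = np.linalg.norm(emp - planted) / np.linalg.norm(planted)
        assert rel < 0.05

    def test_non_psd_covariance_names_eigenvalue(self, toy):
        top, ref = toy
        bad = -np.eye(30)
        spec = allokit.PlantedEnsembleSpec(
            n_residues=10, n_frames=100, covariance_kind="custom",
            custom_covariance=bad, seed=0)
        with pytest.raises(ValueError, match="eigenvalue"):
            sample_gaussian_ensemble(top, ref, spec)

    def test_elastic_network_covariance_psd_and_scaled(self, toy):
        top, ref = toy
        spec = allokit.PlantedEnsembleSpec(
            n_residues=10, n_frames=200, covariance_kind="elastic_network",
            temperature_scale=3.0, seed=0)
        cov = build_covariance(spec, reference_ca=ref[top.ca_indices])
        base = build_covariance(
            allokit.PlantedEnsembleSpec(n_residues=10, n_frames=200,
                                        covariance_kind="elastic_network", seed=0),
            reference_ca=ref[top.ca_indices])
        assert np.linalg.eigvalsh(cov).min() > -1e-9
        np.testing.assert_allclose(cov, 3.0 * base, rtol=1e-12)

    def test_rigid_residue_motion(self, toy):
        # all atoms of a residue carry exactly the Cα displacement
        top, ref = toy
        spec = allokit.PlantedEnsembleSpec(n_residues=10, n_frames=150, seed=5)
        ens = sample_gaussian_ensemble(top, ref, spec)
        res0 = top.atom_residue == 0
        internal = ens.coords[:, res0, :] - ref[None, res0, :]
        np.testing.assert_allclose(internal - internal[:, :1, :], 0.0, atol=1e-12)


class TestTwoStatePair:
    def test_empty_perturbation_shares_distribution(self, toy):
        top, ref = toy
        base = allokit.PlantedEnsembleSpec(n_residues=10, n_frames=200, seed=3)
        a, b, truth = make_two_state_pair(top, ref, base)
        assert truth == []
        assert a.metadata["covariance_kind"] == b.metadata["covariance_kind"]
        np.testing.assert_allclose(a.coords.mean(0), b.coords.mean(0), atol=0.5)

    def test_coupling_increase_raises_centrality(self, toy):
        top, ref = toy
        base = allokit.PlantedEnsembleSpec(n_residues=10, n_frames=20000, seed=6)
        a, b, truth = make_two_state_pair(
            top, ref, base, [CouplingChange(pair=(3, 9), delta_rho=0.5)])
        prof_a = allokit.eigenvector_centrality(allokit.build_network(a))
        prof_b = allokit.eigenvector_centrality(allokit.build_network(b))
        delta = allokit.centrality_difference(prof_a, prof_b)["delta"]
        assert truth[0]["expected_dec_sign"] == 1
        assert delta[3] > 0 and delta[9] > 0

    def test_contact_shift_plants_contact_gain(self, toy):
        top, ref = toy
        i, j = _pick_contact_pair(top, ref)
        base = allokit.PlantedEnsembleSpec(n_residues=10, n_frames=3000,
                                           base_variance=0.04, seed=8)
        a, b, truth = make_two_state_pair(
            top, ref, base, [ContactShift(pair=(i, j), distance=4.5)])
        net_a = allokit.count_contacts(a)
        net_b = allokit.count_contacts(b)
        assert net_b.matrix[i, j] - net_a.matrix[i, j] > 0
        rec = [t for t in truth if t["pair"] == [i, j]]
        assert rec and rec[0]["expected_dw_sign"] == 1

    def test_unknown_pair_raises_key_error(self, toy):
        top, ref = toy
        base = allokit.PlantedEnsembleSpec(n_residues=10, n_frames=200, seed=1)
        with pytest.raises(KeyError):
            make_two_state_pair(top, ref, base,
                                [CouplingChange(pair=(3, 99), delta_rho=0.2)])

    def test_every_perturbation_has_a_ground_truth_record(self, toy):
        top, ref = toy
        base = allokit.PlantedEnsembleSpec(n_residues=10, n_frames=200, seed=1)
        perts = [CouplingChange(pair=(0, 4), delta_rho=0.3),
                 CouplingChange(pair=(2, 6), delta_rho=-0.2)]
        _, _, truth = make_two_state_pair(top, ref, base, perts)
        recorded = {tuple(t["pair"]) for t in truth if t["kind"] == "coupling"}
        assert recorded == {(0, 4), (2, 6)}


class TestShiftTables:
    def test_noiseless_line_has_exact_slope(self):
        spec = allokit.PlantedShiftSpec(
            residues=("fL63",), temperatures=(293.0, 298.0, 303.0, 308.0),
            intercepts=(8.1,), slopes=(-4.0,), noise_sd=0.0)
        table = make_shift_table(spec)
        slope = allokit.temperature_coefficient(table, "fL63")
        assert slope == pytest.approx(-4.0, abs=1e-9)

    def test_quadratic_beats_linear_fit(self):
        spec = allokit.PlantedShiftSpec(
            residues=("fD14",), temperatures=(293.0, 299.0, 305.0, 311.0, 317.0, 323.0),
            intercepts=(8.3,), slopes=(-3.0,), quads=(0.4,), noise_sd=0.0)
        table = make_shift_table(spec)
        t = table["temperature_K"].to_numpy()
        d = table["shift_ppm"].to_numpy()
        tc = t - t.mean()
        rss_lin = np.sum((d - np.polyval(np.polyfit(tc, d, 1), tc)) ** 2)
        rss_quad = np.sum((d - np.polyval(np.polyfit(tc, d, 2), tc)) ** 2)
        assert rss_quad < rss_lin

    def test_seeded_noise_reproducible(self):
        spec = allokit.PlantedShiftSpec(
            residues=("fK60", "fG252"), temperatures=(293.0, 303.0, 313.0, 323.0),
            intercepts=(8.0, 8.5), slopes=(-4.0, -2.0), noise_sd=0.002, seed=42)
        t1 = make_shift_table(spec)
        t2 = make_shift_table(spec)
        assert t1.equals(t2)

    def test_duplicate_temperature_rejected(self):
        with pytest.raises(ValueError):
            allokit.PlantedShiftSpec(
                residues=("fL63",), temperatures=(293.0, 293.0, 303.0),
                intercepts=(8.0,), slopes=(-4.0,))


def test_study_triple_shapes_and_truth():
    study = make_study_triple(n_residues=16, n_frames=300, seed=2)
    for name in ("apo30", "apo50", "holo30"):
        assert study[name].n_frames == 300
    assert study["apo50"].metadata["temperature_scale"] > 1.0
    kinds = {t["kind"] for t in study["ground_truth"]}
    assert kinds == {"coupling", "contact"}
    # sources/dest are valid labels
    top = study["topology"]
    for lbl in [*study["sources"], study["dest"]]:
        top.find(lbl)
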