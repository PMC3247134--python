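import numpy as np
import pytest

from esfpred import contacts, evaluate as ev, features, geometry, model as mdl, synthetic
from esfpred.io import SegmentAnnotation


class TestBuildPeptide:
    def test_phi_psi_round_trip(self):
        rng = np.random.default_rng(0)
        phi = rng.uniform(-150, -50, 8)
        psi = rng.uniform(-80, 150, 8)
        chain = synthetic.build_peptide("AVLIFMGW", phi, psi)
        got_phi, got_psi = geometry.phi_psi(chain)
        np.testing.assert_allclose(got_phi[1:], phi[1:], atol=1e-6)
        np.testing.assert_allclose(got_psi[:-1], psi[:-1], atol=1e-6)

    def test_trans_ca_ca_distance(self):
        chain = synthetic.build_peptide("A" * 10, [-66.0] * 10, [-40.0] * 10)
        ca = chain.ca_coords()
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        np.testing.assert_allclose(d, 3.80, atol=0.05)

    def test_omega_180_keeps_peptide_planes_flat(self):
        chain = synthetic.build_peptide("AAAA", [-60.0] * 4, [-45.0] * 4)
        for i in range(3):
            ca_i = chain.residues[i].coord("CA")
            c_i = chain.residues[i].coord("C")
            n_j = chain.residues[i + 1].coord("N")
            ca_j = chain.residues[i + 1].coord("CA")
            omega = geometry.dihedral(ca_i, c_i, n_j, ca_j)
            assert abs(abs(omega) - 180.0) < 1e-6

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="unknown residue"):
            synthetic.build_peptide("AXB", [0.0] * 3, [0.0] * 3)


class TestBuildHelix:
    def test_ideal_geometry(self):
        h = synthetic.build_helix(20, noise_sd=0.0)
        kappa, alpha = geometry.kappa_alpha(h)
        assert np.nanmean(kappa) == pytest.approx(110.4, abs=1.5)
        assert np.nanmean(alpha) == pytest.approx(50.0, abs=1.5)

    def test_axis_is_z(self):
        h = synthetic.build_helix(20)
        ca = h.ca_coords()
        axis = geometry.fit_axis_tls(ca)
        assert geometry.vector_angle(axis, [0, 0, 1]) < 0.5

    def test_seed_reproducibility(self):
        a = synthetic.build_helix(12, noise_sd=0.3, seed=4)
        b = synthetic.build_helix(12, noise_sd=0.3, seed=4)
        np.testing.assert_array_equal(a.ca_coords(), b.ca_coords())

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            synthetic.build_helix(5)


class TestBuildKinkedHelix:
    def test_zero_kink_equals_straight_helix(self):
        straight = synthetic.build_helix(22)
        kinked = synthetic.build_kinked_helix(22, 11, 0.0)
        dev = np.abs(straight.ca_coords() - kinked.ca_coords()).max()
        assert dev < 0.1

    def test_kappa_elevated_near_kink(self):
        chain = synthetic.build_kinked_helix(24, 12, 40.0)
        kappa, _ = geometry.kappa_alpha(chain)
        near = np.nanmax(kappa[10:15])
        arms = np.nanmean(np.concatenate([kappa[4:9], kappa[16:20]]))
        assert near > arms + 5.0

    def test_invalid_kink_angle_rejected(self):
        with pytest.raises(ValueError):
            synthetic.build_kinked_helix(24, 12, 120.0)


class TestBuildBundle:
    def test_close_spacing_creates_contacts(self):
        chain, seg, _ = synthetic.build_bundle(
            [synthetic.HelixSpec(16), synthetic.HelixSpec(16)], spacing=9.0)
        out = contacts.hhc_labels(chain, seg)
        assert (out["d_interhelix"].dropna() < 3.5).any()

    def test_single_helix_has_no_hhc(self):
        chain, seg, _ = synthetic.build_bundle([synthetic.HelixSpec(16)])
        out = contacts.hhc_labels(chain, seg)
        assert out["hhc"].isna().all()

    def test_segment_midpoints_near_membrane_center(self):
        chain, seg, _ = synthetic.build_bundle(
            [synthetic.HelixSpec(18), synthetic.HelixSpec(18), synthetic.HelixSpec(18)])
        for s, e in seg.helix_segments:
            mid_z = seg.z_coord[(s + e) // 2]
            assert abs(mid_z) < 2.0

    def test_metadata_records_kinks(self):
        specs = [synthetic.HelixSpec(20, kink_pos=10, kink_deg=30.0),
                 synthetic.HelixSpec(18)]
        chain, seg, meta = synthetic.build_bundle(specs)
        assert meta["helices"][0]["kink_deg"] == 30.0
        kink_chain_pos = meta["helices"][0]["kink_pos"]
        kink = geometry.kink_angle(chain, seg)["kink"]
        assert kink[kink_chain_pos] == pytest.approx(30.0, abs=5.0)


class TestSynthPssm:
    def _bundle_with_esf(self):
        chain, seg, _ = synthetic.build_bundle(
            [synthetic.HelixSpec(16), synthetic.HelixSpec(16)])
        table = features.compute_esf(chain, seg, n_points=240)
        scaled, _ = features.esf_matrix(table)
        return chain, scaled

    def test_zero_signal_is_independent_of_esfs(self):
        chain, scaled = self._bundle_with_esf()
        pssm = synthetic.synth_pssm(chain, scaled, 0.0, seed=0)
        z = np.nan_to_num(scaled[:, 0], nan=0.5)
        rs = [abs(ev.pearson(pssm.logodds[:, j], z)) for j in range(20)]
        assert np.mean(rs) < 0.25  # chance level for L~32

    def test_full_signal_recoverable_by_linear_probe(self, small_corpus):
        X, Y = [], []
        for prot in small_corpus:
            X.append(mdl.encode_chain(prot.pssm))
            scaled, mask = features.esf_matrix(prot.esf_table)
            Y.append(np.where(mask[:, 0], scaled[:, 0], np.nan))
        X, y = np.vstack(X), np.concatenate(Y)
        keep = np.isfinite(y)
        X, y = X[keep], y[keep]
        coef, *_ = np.linalg.lstsq(np.c_[X, np.ones(len(X))], y, rcond=None)
        pred = np.c_[X, np.ones(len(X))] @ coef
        ss_res = ((y - pred) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert 1 - ss_res / ss_tot > 0.8

    def test_fixed_seed_reproducible(self):
        chain, scaled = self._bundle_with_esf()
        a = synthetic.synth_pssm(chain, scaled, 0.5, seed=9)
        b = synthetic.synth_pssm(chain, scaled, 0.5, seed=9)
        np.testing.assert_array_equal(a.logodds, b.logodds)

    def test_integer_range(self):
        chain, scaled = self._bundle_with_esf()
        pssm = synthetic.synth_pssm(chain, scaled, 1.0, seed=0)
        assert pssm.logodds.min() >= -10 and pssm.logodds.max() <= 10
        np.testing.assert_array_equal(pssm.logodds, np.round(pssm.logodds))


class TestGnmBfactors:
    def test_three_node_chain_hand_check(self):
        # path graph 1-2-3: Kirchhoff pseudoinverse diagonal is
        # (5/9, 2/9, 5/9), scaled here to mean 1
        chain = synthetic.Chain(chain_id="A")
        for i, x in enumerate([0.0, 3.8, 7.6]):
            res = synthetic.Residue(res_number=i + 1, res_name="ALA")
            res.atoms.append(synthetic.Atom("CA", "C", np.array([x, 0.0, 0.0])))
            chain.residues.append(res)
        b = synthetic.gnm_bfactors(chain, cutoff=5.0)
        expected = np.array([5 / 9, 2 / 9, 5 / 9])
        np.testing.assert_allclose(b, expected / expected.mean(), atol=1e-10)

    def test_helix_ends_more_mobile_than_core(self):
        h = synthetic.build_helix(24)
        b = synthetic.gnm_bfactors(h)
        assert b[0] > b[12] and b[-1] > b[12]

    def test_rigid_motion_invariance(self):
        from test_geometry import random_rigid_transform
        h = synthetic.build_helix(15)
        b0 = synthetic.gnm_bfactors(h)
        R, t = random_rigid_transform(7)
        synthetic.transform_chain(h, R=R, t=t)
        np.testing.assert_allclose(synthetic.gnm_bfactors(h), b0, atol=1e-8)

    def test_disconnected_graph_rejected(self):
        chain = synthetic.Chain(chain_id="A")
        for i, x in enumerate([0.0, 3.8, 100.0]):
            res = synthetic.Residue(res_number=i + 1, res_name="ALA")
            res.atoms.append(synthetic.Atom("CA", "C", np.array([x, 0.0, 0.0])))
            chain.residues.append(res)
        with pytest.raises(ValueError, match="disconnected"):
            synthetic.gnm_bfactors(chain, cutoff=5.0)


class TestMakeCorpus:
    def test_reproducible_from_seed(self):
        spec = synthetic.CorpusSpec(n_proteins=2, seed=3, asa_n_points=240)
        c1 = synthetic.make_corpus(spec)
        c2 = synthetic.make_corpus(spec)
        for p1, p2 in zip(c1, c2):
            np.testing.assert_array_equal(p1.chain.ca_coords(), p2.chain.ca_coords())
            np.testing.assert_array_equal(p1.pssm.logodds, p2.pssm.logodds)
            np.testing.assert_array_equal(p1.flex, p2.flex)

    def test_all_esfs_defined_for_interior_tm_residues(self, small_corpus):
        for prot in small_corpus:
            table = prot.esf_table
            for s, e in prot.segments.helix_segments:
                interior = table.iloc[max(s, 2) + 2:e - 2]
                assert not interior[features.ESF_NAMES].isna().any().any()

    def test_mean_kappa_matches_helical_expectation(self):
        spec = synthetic.CorpusSpec(n_proteins=4, kink_prob=0.0,
                                    coord_noise_sd=0.05, seed=5, asa_n_points=240)
        corpus = synthetic.make_corpus(spec)
        kappas = []
        for prot in corpus:
            k = prot.esf_table["kappa"].to_numpy(float)
            # residues whose 5-residue window lies fully inside the helix
            for s, e in prot.segments.helix_segments:
                vals = k[s + 2:e - 2]
                kappas.append(vals[np.isfinite(vals)])
        assert np.mean(np.concatenate(kappas)) == pytest.approx(110.5, abs=1.5)

    def test_round_trip_through_corpus_directory(self, tmp_path, small_corpus):
        synthetic.save_corpus(small_corpus[:2], tmp_path / "corpus")
        back = synthetic.load_corpus(tmp_path / "corpus")
        assert len(back) == 2
        for orig, loaded in zip(small_corpus[:2], back):
            assert loaded.protein_id == orig.protein_id
            assert len(loaded.chain) == len(orig.chain)
            np.testing.assert_allclose(loaded.chain.ca_coords(),
                                       orig.chain.ca_coords(), atol=1e-3)
            np.testing.assert_array_equal(loaded.pssm.logodds, orig.pssm.logodds)
            np.testing.assert_allclose(loaded.flex, orig.flex, rtol=1e-6)
            assert loaded.segments.helix_segments == orig.segments.helix_segments
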