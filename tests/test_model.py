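import numpy as np
import pytest

from esfpred import model as mdl
from esfpred import synthetic
from esfpred.io import PSSMProfile
from esfpred.model import EncoderConfig


def toy_pssm(L=12, seed=0):
    rng = np.random.default_rng(seed)
    logodds = rng.integers(-10, 11, size=(L, 20)).astype(float)
    comp = rng.uniform(0.5, 1.5, 20)
    comp /= comp.sum()
    return PSSMProfile(logodds, comp, sequence="A" * L)


class TestEncoder:
    def test_default_length_is_200(self):
        x = mdl.encode_residue(toy_pssm(), 5)
        assert x.shape == (200,)

    def test_terminal_padding_zero_filled(self):
        x = mdl.encode_residue(toy_pssm(), 0, EncoderConfig(window=9))
        np.testing.assert_array_equal(x[: 4 * 20], 0.0)
        assert np.all(x[4 * 20: 5 * 20] > 0)  # the residue itself is squashed

    def test_logistic_squash_of_zero_is_half(self):
        pssm = toy_pssm()
        pssm.logodds[3] = 0.0
        x = mdl.encode_residue(pssm, 3)
        np.testing.assert_allclose(x[4 * 20: 5 * 20], 0.5)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            EncoderConfig(window=8)


class TestNetworkConstruction:
    def test_integrated_hidden_is_16(self):
        net = mdl.build_network(200, 8)
        assert net.layer_sizes == (200, 16, 8)

    def test_individual_hidden_is_2(self):
        net = mdl.build_network(200, 1)
        assert net.layer_sizes == (200, 2, 1)

    def test_same_seed_same_weights(self):
        a = mdl.build_network(50, 3, seed=42)
        b = mdl.build_network(50, 3, seed=42)
        np.testing.assert_array_equal(a.W1, b.W1)
        np.testing.assert_array_equal(a.b2, b.b2)

    def test_parameter_counts(self):
        assert mdl.count_parameters((200, 16, 8)) == 3352
        assert 8 * mdl.count_parameters((200, 2, 1)) == 3240
        diff = mdl.compare_parameter_counts((200, 16, 8), [(200, 2, 1)] * 8)
        assert diff == pytest.approx(100 * 112 / 3240)
        assert 3.0 < diff < 4.0  # "about 3%"

    def test_parameter_parity_generalizes(self):
        # with 200 inputs the integrated/individual parameter gap is exactly
        # 2(n_out - 1)/405, i.e. below 5% for feature vectors up to n_out=11
        for n_out in range(4, 12):
            diff = mdl.compare_parameter_counts(
                (200, 2 * n_out, n_out), [(200, 2, 1)] * n_out)
            assert diff == pytest.approx(100 * 2 * (n_out - 1) / 405)
            assert abs(diff) < 5.0

    def test_json_round_trip(self, tmp_path):
        net = mdl.build_network(20, 2, seed=1, target_names=["tASA", "scASA"])
        net.left_out_sequence = "AVLIF"
        path = tmp_path / "m.json"
        net.to_json(path)
        back = mdl.NetworkModel.from_json(path)
        np.testing.assert_array_equal(back.W1, net.W1)
        assert back.target_names == ["tASA", "scASA"]
        assert back.left_out_sequence == "AVLIF"
        x = np.random.default_rng(0).uniform(size=(5, 20))
        np.testing.assert_allclose(back.forward(x), net.forward(x))


class TestTraining:
    def test_zero_epochs_leaves_weights_unchanged(self):
        net = mdl.build_network(10, 2, seed=0)
        rng = np.random.default_rng(1)
        out = mdl.train(net, rng.uniform(size=(20, 10)), rng.uniform(size=(20, 2)),
                        epochs=0)
        np.testing.assert_array_equal(out.W1, net.W1)

    def test_all_masked_raises(self):
        net = mdl.build_network(10, 1)
        X = np.zeros((5, 10))
        Y = np.zeros((5, 1))
        with pytest.raises(ValueError, match="masked"):
            mdl.train(net, X, Y, np.zeros((5, 1), dtype=bool))

    def test_loss_decreases_on_separable_data(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(60, 5))
        y = (X[:, 0] > 0.5).astype(float)[:, None]
        net = mdl.build_network(5, 1, seed=0)
        trained = mdl.train(net, X, y, epochs=500, lr=0.5, seed=0)
        trace = trained.loss_trace
        assert trace[-1] < trace[0]
        assert trace[-1] < 0.05

    def test_xor_with_two_hidden_units(self):
        # the classical minimal-architecture benchmark; convergence depends
        # on the initialization so a known-good seed is fixed
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([[0], [1], [1], [0]], dtype=float)
        net = mdl.build_network(2, 1, seed=1)
        trained = mdl.train(net, X, y, epochs=5000, lr=2.0, seed=1, batch_size=4)
        assert trained.loss_trace[-1] < 0.05

    def test_masked_targets_do_not_influence_training(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(30, 4))
        Y = rng.uniform(size=(30, 2))
        M = np.ones_like(Y, dtype=bool)
        M[:, 1] = False
        net = mdl.build_network(4, 2, seed=3)
        t1 = mdl.train(net, X, Y, M, epochs=50, seed=0)
        Y2 = Y.copy()
        Y2[:, 1] = rng.uniform(size=30)  # garbage in the masked column
        t2 = mdl.train(net, X, Y2, M, epochs=50, seed=0)
        np.testing.assert_array_equal(t1.W1, t2.W1)


class TestPredict:
    def test_deterministic_and_sigmoid_bounded(self):
        net = mdl.build_network(200, 8, seed=0,
                                target_names=list(mdl.ESF_NAMES))
        pssm = toy_pssm()
        s1 = mdl.predict_scaled(net, pssm)
        s2 = mdl.predict_scaled(net, pssm)
        np.testing.assert_array_equal(s1, s2)
        assert np.all((s1 > 0) & (s1 < 1))

    def test_unscaled_outputs_in_native_ranges(self):
        net = mdl.build_network(200, 8, seed=0, target_names=list(mdl.ESF_NAMES))
        table = mdl.predict(net, toy_pssm())
        assert table["kappa"].between(0, 180).all()
        assert table["phi"].between(-180, 180).all()
        assert table["tASA"].between(0, 150).all()


class TestLooProtocol:
    def _tiny_corpus(self, n=3, seed=5):
        spec = synthetic.CorpusSpec(n_proteins=n, helices_per_protein=(2, 2),
                                    helix_length=(12, 14), seed=seed,
                                    asa_n_points=240)
        return synthetic.make_corpus(spec)

    def test_left_out_protein_never_trained_on(self):
        data = mdl.corpus_to_protein_data(self._tiny_corpus())
        res = mdl.loo_protocol(data, mode="integrated", epochs=2)
        assert len(res.models) == 3
        for pid, trained_on in res.training_ids.items():
            assert pid not in trained_on
            assert len(trained_on) == 2

    def test_individual_mode_trains_eight_networks_per_fold(self):
        data = mdl.corpus_to_protein_data(self._tiny_corpus())
        res = mdl.loo_protocol(data, mode="individual", epochs=1)
        for nets in res.models.values():
            assert len(nets) == 8
            assert all(n.layer_sizes[1:] == (2, 1) for n in nets)

    def test_needs_two_proteins(self):
        data = mdl.corpus_to_protein_data(self._tiny_corpus(n=2))
        with pytest.raises(ValueError):
            mdl.loo_protocol(data[:1])

    def test_tm_mode_learns_strong_signal(self):
        # TM vs loop is carried by the PSSM at full signal strength: a
        # single-output network should separate the classes well
        from esfpred import evaluate
        corpus = self._tiny_corpus(n=6, seed=11)
        data = mdl.corpus_to_protein_data(corpus, targets="tm")
        res = mdl.loo_protocol(data, mode="tm", epochs=150, seed=0)
        scores, labels = [], []
        for prot in corpus:
            scores.append(res.predictions[prot.protein_id][:, 0])
            labels.append(prot.segments.tm_flag.astype(int))
        auc = evaluate.roc_auc(np.concatenate(scores), np.concatenate(labels))
        assert auc > 0.8


class TestModelSelection:
    def _models_with_sequences(self, seqs):
        out = []
        for i, s in enumerate(seqs):
            net = mdl.build_network(10, 1, seed=i)
            net.left_out_id = f"p{i}"
            net.left_out_sequence = s
            out.append(net)
        return out

    def test_identical_query_selects_its_model(self):
        seqs = ["AVLIFMGWTS", "KKKDDDEEER", "AAAAGGGGSS"]
        models = self._models_with_sequences(seqs)
        chosen = mdl.select_model_for_query(models, "KKKDDDEEER")
        assert chosen.left_out_id == "p1"

    def test_unrelated_query_still_returns_a_model(self):
        models = self._models_with_sequences(["AAAA", "VVVV"])
        chosen = mdl.select_model_for_query(models, "WWWWWWWW")
        assert chosen in models

    def test_matches_brute_force_argmax(self):
        rng = np.random.default_rng(0)
        alpha = list("ARNDCQEGHILKMFPSTWYV")
        seqs = ["".join(rng.choice(alpha, 15)) for _ in range(5)]
        models = self._models_with_sequences(seqs)
        query = "".join(rng.choice(alpha, 15))
        ids = [mdl.sequence_identity(s, query) for s in seqs]
        chosen = mdl.select_model_for_query(models, query)
        assert chosen.left_out_id == f"p{int(np.argmax(ids))}"

    def test_empty_model_list_raises(self):
        with pytest.raises(ValueError):
            mdl.select_model_for_query([], "AAA")
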