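import numpy as np
import pytest

from tcnss.featurize import FeatureMatrix
from tcnss.nn import Tensor, no_grad
from tcnss.predictor import (AttentionSpec, BiLSTM, Classifier, ClassifierSpec,
                             LSTMCellStack, MultiHeadAttention, RecurrentSpec,
                             SSModel, forward)
from tcnss.mstcn import BidirSpec, MultiScaleSpec

from .oracles import bilstm_unrolled, lstm_unrolled


def _bilstm_weights(net: BiLSTM):
    fwd = [(c.w_x.data, c.w_h.data, c.bias.data) for c in net.forward_cells]
    bwd = [(c.w_x.data, c.w_h.data, c.bias.data) for c in net.backward_cells]
    return fwd, bwd


class TestBiLSTM:
    def test_zero_parameters_give_zero_outputs(self):
        """With all gates at zero, i=f=o=0.5 and the candidate cell is
        tanh(0)=0, so c_t and h_t stay exactly zero at every step."""
        rng = np.random.default_rng(0)
        net = BiLSTM(3, RecurrentSpec(layers=2, hidden=4, dropout=0.0), rng)
        for _, p in net.named_parameters():
            p.data[:] = 0.0
        x = np.random.default_rng(1).normal(size=(1, 6, 3))
        with no_grad():
            out = net(Tensor(x), np.array([6]))
        assert np.all(out.data == 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_hand_unrolled_recursion(self, seed):
        """The vectorized BiLSTM agrees with a plain-loop unrolling of the
        gate equations to 1e-10 on short random inputs."""
        rng = np.random.default_rng(seed)
        L = int(rng.integers(1, 6))
        net = BiLSTM(3, RecurrentSpec(layers=3, hidden=4, dropout=0.0),
                     np.random.default_rng(seed + 100))
        net.eval()
        x = rng.normal(size=(L, 3))
        with no_grad():
            out = net(Tensor(x[None]), np.array([L])).data[0]
        fwd, bwd = _bilstm_weights(net)
        expected = bilstm_unrolled(x, fwd, bwd)
        assert np.allclose(out, expected, atol=1e-10)

    def test_reversal_symmetry_with_tied_directions(self):
        """If both directions share parameters, reversing the input swaps
        the forward and backward output blocks (reversed in position)."""
        rng = np.random.default_rng(2)
        net = BiLSTM(3, RecurrentSpec(layers=1, hidden=4, dropout=0.0), rng)
        for cf, cb in zip(net.forward_cells, net.backward_cells):
            cb.w_x.data = cf.w_x.data.copy()
            cb.w_h.data = cf.w_h.data.copy()
            cb.bias.data = cf.bias.data.copy()
        x = rng.normal(size=(5, 3))
        with no_grad():
            out = net(Tensor(x[None]), np.array([5])).data[0]
            rev = net(Tensor(x[None, ::-1]), np.array([5])).data[0]
        H = 4
        assert np.allclose(rev[::-1, :H], out[:, H:], atol=1e-12)
        assert np.allclose(rev[::-1, H:], out[:, :H], atol=1e-12)

    def test_output_width_is_twice_hidden(self):
        rng = np.random.default_rng(0)
        net = BiLSTM(5, RecurrentSpec(layers=1, hidden=7, dropout=0.0), rng)
        with no_grad():
            out = net(Tensor(np.zeros((2, 4, 5))), np.array([4, 4]))
        assert out.data.shape == (2, 4, 14)

    def test_single_direction_against_loop_oracle(self):
        rng = np.random.default_rng(9)
        cell = LSTMCellStack(3, 5, rng)
        x = rng.normal(size=(4, 3))
        with no_grad():
            out = cell(Tensor(x[None])).data[0]
        expected = lstm_unrolled(x, cell.w_x.data, cell.w_h.data, cell.bias.data)
        assert np.allclose(out, expected, atol=1e-12)


class TestMultiHeadAttention:
    def test_single_position_attends_to_itself(self):
        rng = np.random.default_rng(0)
        mha = MultiHeadAttention(4, AttentionSpec(heads=2, model_width=4), rng)
        with no_grad():
            out, weights = mha(Tensor(np.ones((1, 1, 4))),
                               return_weights=True)
        for w in weights:
            assert np.allclose(w, [[[1.0]]])
        assert out.data.shape == (1, 1, 4)

    def test_identical_keys_give_uniform_weights(self):
        rng = np.random.default_rng(1)
        mha = MultiHeadAttention(3, AttentionSpec(heads=3, model_width=6), rng)
        h = np.tile(np.array([0.3, -1.2, 0.7]), (1, 5, 1))
        with no_grad():
            _, weights = mha(Tensor(h), return_weights=True)
        for w in weights:
            assert np.allclose(w, 1.0 / 5)

    def test_peaked_scores_approach_identity(self):
        """Scaled identity projections with a large scale make each
        position attend almost exclusively to itself."""
        L = 4
        scale = 50.0
        rng = np.random.default_rng(2)
        mha = MultiHeadAttention(L, AttentionSpec(heads=1, model_width=L,
                                                  d_k=L), rng)
        mha.w_q[0].data = scale * np.eye(L)
        mha.w_k[0].data = scale * np.eye(L)
        h = np.eye(L)[None]
        with no_grad():
            _, weights = mha(Tensor(h), return_weights=True)
        w = weights[0][0]
        off_diag = w[~np.eye(L, dtype=bool)]
        assert np.all(off_diag < 1e-9)

    @pytest.mark.parametrize("L,width,heads", [(3, 6, 2), (7, 9, 3), (2, 4, 4)])
    def test_rows_are_stochastic(self, L, width, heads):
        rng = np.random.default_rng(L * width)
        mha = MultiHeadAttention(width, AttentionSpec(heads=heads,
                                                      model_width=width), rng)
        h = rng.normal(size=(2, L, width))
        with no_grad():
            _, weights = mha(Tensor(h), return_weights=True)
        for w in weights:
            assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-9)

    def test_padding_positions_receive_no_weight(self):
        rng = np.random.default_rng(4)
        mha = MultiHeadAttention(3, AttentionSpec(heads=2, model_width=3), rng)
        h = rng.normal(size=(1, 6, 3))
        mask = np.zeros((1, 6, 1))
        mask[0, :4] = 1.0
        with no_grad():
            _, weights = mha(Tensor(h), mask=mask, return_weights=True)
        for w in weights:
            assert np.all(w[0, :, 4:] < 1e-12)


class TestClassifier:
    @staticmethod
    def _clf(rng, classes=3):
        return Classifier(4, 4, ClassifierSpec(classes=classes,
                                               fused_width=5), rng)

    def test_zero_dense_gives_uniform_rows(self):
        rng = np.random.default_rng(0)
        clf = self._clf(rng)
        clf.dense.weight.data[:] = 0.0
        clf.dense.bias.data[:] = 0.0
        with no_grad():
            out = clf(Tensor(np.random.default_rng(1).normal(size=(1, 5, 4))),
                      Tensor(np.random.default_rng(2).normal(size=(1, 5, 4))))
        assert np.allclose(out.data, 1.0 / 3)

    def test_bias_dominates_when_weights_zero(self):
        rng = np.random.default_rng(0)
        clf = self._clf(rng)
        clf.dense.weight.data[:] = 0.0
        clf.dense.bias.data[:] = np.array([10.0, 0.0, 0.0])
        with no_grad():
            out = clf(Tensor(np.zeros((1, 2, 4))), Tensor(np.zeros((1, 2, 4))))
        expected = np.exp([10.0, 0.0, 0.0])
        expected /= expected.sum()
        assert np.allclose(out.data[0, 0], expected, atol=1e-9)
        assert abs(out.data[0, 0, 1] - 4.5e-5) < 5e-7

    def test_row_sums_fuzzed(self):
        rng = np.random.default_rng(5)
        for seed in range(5):
            clf = self._clf(np.random.default_rng(seed), classes=4)
            with no_grad():
                out = clf(Tensor(rng.normal(size=(2, 6, 4))),
                          Tensor(rng.normal(size=(2, 6, 4))))
            assert np.allclose(out.data.sum(axis=-1), 1.0, atol=1e-6)


class TestFullModel:
    @staticmethod
    def _model(d=10, k=3, seed=0):
        tcn = BidirSpec(MultiScaleSpec(scales=(1, 3), channels=4, out_width=8))
        return SSModel(d, tcn, RecurrentSpec(layers=2, hidden=4, dropout=0.1),
                       AttentionSpec(heads=2, model_width=8),
                       ClassifierSpec(classes=k, fused_width=8), seed=seed)

    def test_single_residue_flows_through(self):
        model = self._model()
        fm = FeatureMatrix("p", np.random.default_rng(0).normal(size=(1, 10)))
        probs = forward(fm, model)
        assert probs.shape == (1, 3)
        assert np.allclose(probs.sum(), 1.0, atol=1e-6)

    def test_evaluation_repeatable(self):
        model = self._model()
        fm = FeatureMatrix("p", np.random.default_rng(1).normal(size=(12, 10)))
        assert np.array_equal(forward(fm, model), forward(fm, model))

    def test_argmax_yields_label_string(self):
        from tcnss.seqdata import Q3
        model = self._model()
        fm = FeatureMatrix("p", np.random.default_rng(2).normal(size=(9, 10)))
        probs = forward(fm, model)
        labels = "".join(Q3.states[j] for j in probs.argmax(axis=1))
        assert len(labels) == 9
        assert set(labels) <= set("HEC")

    def test_probability_rows_sum_to_one(self):
        model = self._model(k=8)
        fm = FeatureMatrix("p", np.random.default_rng(3).normal(size=(20, 10)))
        probs = forward(fm, model)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_empty_sequence_rejected(self):
        model = self._model()
        with pytest.raises(ValueError):
            forward(FeatureMatrix("p", np.zeros((0, 10))), model)
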