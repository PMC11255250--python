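import numpy as np
import pytest

from tcnss.mstcn import (BidirSpec, CausalConv1d, ImprovedTCN, MSTCN, MultiScaleSpec,
                         ResBlock, ResBlockSpec, causal_dilated_conv, run_trunk)
from tcnss.nn import Tensor, no_grad


class TestCausalDilatedConv:
    def test_identity_kernel(self):
        x = np.random.default_rng(0).normal(size=(7, 3))
        kernel = np.eye(3)[None, :, :]       # k=1, identity weight
        assert np.allclose(causal_dilated_conv(x, kernel), x)

    def test_impulse_response(self):
        """k=2, d=1, both taps weight 1: a unit impulse spreads to t0, t0+1."""
        x = np.zeros((6, 1))
        x[2, 0] = 1.0
        kernel = np.ones((2, 1, 1))
        out = causal_dilated_conv(x, kernel, dilation=1)[:, 0]
        assert np.allclose(out, [0, 0, 1, 1, 0, 0])

    def test_causality(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.normal(size=(12, 4))
            kernel = rng.normal(size=(3, 4, 2))
            base = causal_dilated_conv(x, kernel, dilation=2)
            t = 5
            x2 = x.copy()
            x2[t + 1:] += rng.normal(size=x2[t + 1:].shape)
            pert = causal_dilated_conv(x2, kernel, dilation=2)
            assert np.allclose(base[:t + 1], pert[:t + 1])

    def test_invalid_dilation(self):
        with pytest.raises(ValueError):
            causal_dilated_conv(np.zeros((3, 1)), np.ones((1, 1, 1)), dilation=0)


class TestResBlock:
    def test_zero_branch_is_identity(self):
        rng = np.random.default_rng(0)
        spec = ResBlockSpec(kernel_size=3, dilation=2, channels=4)
        block = ResBlock(4, spec, rng)     # widths match -> identity skip
        assert block.proj is None
        for conv in block.convs:
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
        x = rng.normal(size=(9, 4))
        out = run_trunk(block, x)
        assert np.allclose(out, x)

    @pytest.mark.parametrize("L", [1, 7, 100])
    def test_length_preserved(self, L):
        rng = np.random.default_rng(L)
        block = ResBlock(3, ResBlockSpec(channels=5, dilation=4), rng)
        out = run_trunk(block, rng.normal(size=(L, 3)))
        assert out.shape == (L, 5)

    @pytest.mark.parametrize("k,d", [(3, 1), (3, 2), (2, 4)])
    def test_receptive_field_by_impulse_perturbation(self, k, d):
        """3 conv layers at kernel k, dilation d see 3(k-1)d positions back.

        All-positive weights and inputs keep every ReLU active, so a
        positive perturbation provably propagates along every tap chain and
        the measured reach equals the closed-form span exactly.
        """
        rng = np.random.default_rng(7)
        spec = ResBlockSpec(kernel_size=k, dilation=d, channels=3,
                            conv_layers=3)
        block = ResBlock(3, spec, rng)
        for conv in block.convs:
            conv.weight.data = np.abs(conv.weight.data) + 0.01
            conv.bias.data = np.abs(conv.bias.data)
        span = 3 * (k - 1) * d
        L = span + 8
        x = np.abs(rng.normal(size=(L, 3))) + 0.1
        base = run_trunk(block, x)
        t = L - 1
        reach = 0
        for j in range(1, t + 1):
            x2 = x.copy()
            x2[t - j] += 1.0
            if not np.allclose(run_trunk(block, x2)[t], base[t]):
                reach = j
        assert reach == span

    def test_parameter_count_closed_form(self):
        rng = np.random.default_rng(0)
        d_in, c, k, n = 6, 5, 3, 3
        block = ResBlock(d_in, ResBlockSpec(kernel_size=k, channels=c,
                                            conv_layers=n), rng)
        conv_params = (k * d_in * c + c) + (n - 1) * (k * c * c + c)
        proj_params = d_in * c + c
        assert block.n_parameters() == conv_params + proj_params


class TestMSTCN:
    def test_single_scale_degenerates(self):
        rng = np.random.default_rng(0)
        spec = MultiScaleSpec(scales=(1,), channels=4, out_width=6)
        stack = MSTCN(3, spec, rng)
        out = run_trunk(stack, rng.normal(size=(10, 3)))
        assert out.shape == (10, 6)

    def test_causality_of_forward_stack(self):
        rng = np.random.default_rng(3)
        spec = MultiScaleSpec(scales=(1, 3, 9), channels=3, out_width=4)
        stack = MSTCN(2, spec, rng)
        x = rng.normal(size=(15, 2))
        base = run_trunk(stack, x)
        t = 6
        x2 = x.copy()
        x2[t + 1:] += 1.0
        assert np.allclose(run_trunk(stack, x2)[:t + 1], base[:t + 1])

    def test_fusion_width_arithmetic(self):
        rng = np.random.default_rng(0)
        spec = MultiScaleSpec(scales=(1, 2, 4, 8, 16), channels=32, out_width=64)
        stack = MSTCN(8, spec, rng)
        assert stack.fuse.weight.shape == (5 * 32, 64)
        out = run_trunk(stack, rng.normal(size=(4, 8)))
        assert out.shape == (4, 64)

    def test_empty_scales_rejected(self):
        with pytest.raises(ValueError):
            MultiScaleSpec(scales=())

    def test_nonincreasing_scales_rejected(self):
        with pytest.raises(ValueError):
            MultiScaleSpec(scales=(1, 9, 9))

    def test_parameter_count_linear_in_scales(self):
        rng = np.random.default_rng(0)

        def count(n_scales):
            spec = MultiScaleSpec(scales=tuple(3 ** i for i in range(n_scales)),
                                  channels=4, out_width=6, kernel_size=3)
            return MSTCN(5, spec, rng).n_parameters()

        # block params are scale-independent; fusion grows by channels*out
        per_scale = count(2) - count(1)
        assert count(4) == count(1) + 3 * per_scale


class TestImprovedTCN:
    @staticmethod
    def _model(rng, d_in=3, h=6, scales=(1, 3)):
        spec = BidirSpec(MultiScaleSpec(scales=scales, channels=4, out_width=h))
        return ImprovedTCN(d_in, spec, rng)

    def test_zero_backward_branch_reduces_to_forward(self):
        rng = np.random.default_rng(0)
        model = self._model(rng)
        for name, p in model.backward_stack.named_parameters():
            p.data[:] = 0.0
        x = np.random.default_rng(1).normal(size=(8, 3))
        full = run_trunk(model, x)
        fwd = run_trunk(model.forward_stack, x)
        with no_grad():
            z = model.dense(model.conv1x1(Tensor(fwd[None])))
            import tcnss.nn.autodiff as ad
            model.eval()
            expected = model.norm(ad.relu(z), np.ones((1, 8, 1))).data[0]
        assert np.allclose(full, expected)

    @pytest.mark.parametrize("L", [1, 5, 40])
    def test_length_preserved(self, L):
        rng = np.random.default_rng(L)
        model = self._model(rng)
        out = run_trunk(model, rng.normal(size=(L, 3)))
        assert out.shape == (L, 6)

    def test_bidirectional_dependence_on_future(self):
        """Perturbing a future position changes earlier outputs for at
        least one random parameter draw."""
        found = False
        for seed in range(20):
            rng = np.random.default_rng(seed)
            model = self._model(rng)
            x = rng.normal(size=(10, 3))
            base = run_trunk(model, x)
            x2 = x.copy()
            x2[7] += 1.0
            if not np.allclose(run_trunk(model, x2)[:7], base[:7]):
                found = True
                break
        assert found

    def test_forward_branch_strictly_causal(self):
        rng = np.random.default_rng(11)
        model = self._model(rng)
        x = rng.normal(size=(10, 3))
        base = run_trunk(model.forward_stack, x)
        x2 = x.copy()
        x2[6:] += 2.0
        assert np.allclose(run_trunk(model.forward_stack, x2)[:6], base[:6])

    def test_evaluation_mode_deterministic(self):
        rng = np.random.default_rng(0)
        model = self._model(rng)
        x = np.random.default_rng(5).normal(size=(12, 3))
        assert np.array_equal(run_trunk(model, x), run_trunk(model, x))

    def test_empty_sequence_rejected(self):
        rng = np.random.default_rng(0)
        model = self._model(rng)
        with pytest.raises(ValueError):
            with no_grad():
                model(Tensor(np.zeros((1, 0, 3))), np.array([0]),
                      np.ones((1, 0, 1)))
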