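"""SEAM attention: analytic gate bounds, closed forms, a pure scalar-loop
reference implementation of the whole forward pass, and gradient checks."""

import math

import numpy as np
import pytest

from seamseg import autograd as ag
from seamseg.seam import CSMM, SEAM, SeamConfig, exp_reweight


# ---------------------------------------------------------------------------
# independent scalar reference (nested Python loops, no engine code)
# ---------------------------------------------------------------------------

def _scalar_gelu(v):
    return 0.5 * v * (1.0 + math.erf(v / math.sqrt(2.0)))


def _scalar_sigmoid(v):
    return 1.0 / (1.0 + math.exp(-v))


def scalar_seam_reference(model: SEAM, x: np.ndarray) -> np.ndarray:
    """Evaluate SEAM with explicit loops over every index."""
    cfg = model.cfg
    n_, c_, h_, w_ = x.shape
    k = cfg.patch_size
    pad = k // 2
    pooled_branches = []
    for br in model._branches:
        dw_w, dw_b = br.depthwise.weight.data, br.depthwise.bias.data
        pw_w, pw_b = br.pointwise.weight.data, br.pointwise.bias.data
        out = np.zeros_like(x)
        for n in range(n_):
            dw = np.zeros((c_, h_, w_))
            for c in range(c_):
                for i in range(h_):
                    for j in range(w_):
                        acc = dw_b[c]
                        for ki in range(k):
                            for kj in range(k):
                                ii, jj = i + ki - pad, j + kj - pad
                                if 0 <= ii < h_ and 0 <= jj < w_:
                                    acc += dw_w[c, ki, kj] * x[n, c, ii, jj]
                        dw[c, i, j] = acc
            for o in range(c_):
                for i in range(h_):
                    for j in range(w_):
                        acc = pw_b[o]
                        for c in range(c_):
                            acc += pw_w[o, c, 0, 0] * dw[c, i, j]
                        val = _scalar_gelu(acc)
                        if cfg.residual:
                            val += x[n, o, i, j]
                        out[n, o, i, j] = val
        pooled = np.zeros((n_, c_))
        for n in range(n_):
            for c in range(c_):
                pooled[n, c] = out[n, c].sum() / (h_ * w_)
        pooled_branches.append(pooled)
    ybar = sum(pooled_branches) / len(pooled_branches)
    w1, b1 = model.fc1.weight.data, model.fc1.bias.data
    w2, b2 = model.fc2.weight.data, model.fc2.bias.data
    result = np.zeros_like(x)
    for n in range(n_):
        hidden = [_scalar_gelu(sum(w1[o, c] * ybar[n, c] for c in range(c_)) + b1[o])
                  for o in range(w1.shape[0])]
        for c in range(c_):
            g = _scalar_sigmoid(
                sum(w2[c, o] * hidden[o] for o in range(len(hidden))) + b2[c])
            result[n, c] = x[n, c] * math.exp(g)
    return result


@pytest.fixture
def seam64():
    def make(seed, channels=4, **kw):
        cfg = SeamConfig(channels=channels, **kw)
        return SEAM(cfg, rng=np.random.default_rng(seed), dtype=np.float64)
    return make


class TestDepthwiseSeparable:
    def test_identity_kernels_reproduce_input(self, rng):
        x = ag.Tensor(rng.standard_normal((1, 3, 6, 6)))
        delta = np.zeros((3, 7, 7))
        delta[:, 3, 3] = 1.0
        pointwise = np.eye(3).reshape(3, 3, 1, 1)
        dw = ag.depthwise_conv2d(x, ag.Tensor(delta), padding=3)
        out = ag.conv2d(dw, ag.Tensor(pointwise), padding=0)
        assert np.allclose(out.data, x.data, atol=1e-12)

    def test_zero_input_zero_output_without_bias(self, rng):
        x = ag.Tensor(np.zeros((1, 2, 5, 5)))
        w = ag.Tensor(rng.standard_normal((2, 3, 3)))
        assert not ag.depthwise_conv2d(x, w, padding=1).data.any()


class TestCSMM:
    def test_pure_residual_when_conv_weights_zero(self, rng):
        cfg = SeamConfig(channels=3, residual=True)
        csmm = CSMM(cfg, rng=np.random.default_rng(0), dtype=np.float64)
        csmm.depthwise.weight.data[...] = 0
        csmm.depthwise.bias.data[...] = 0
        csmm.pointwise.weight.data[...] = 0
        csmm.pointwise.bias.data[...] = 0
        x = ag.Tensor(rng.standard_normal((2, 3, 6, 6)))
        assert np.allclose(csmm(x).data, x.data, atol=1e-14)

    @pytest.mark.parametrize("shape", [(1, 2, 8, 8), (2, 5, 7, 9), (3, 1, 16, 4)])
    def test_shape_preserved(self, shape, rng):
        cfg = SeamConfig(channels=shape[1])
        csmm = CSMM(cfg, rng=np.random.default_rng(1))
        x = ag.Tensor(rng.standard_normal(shape).astype(np.float32))
        assert csmm(x).data.shape == shape

    def test_branches_differ_when_weights_differ(self, seam64, rng):
        model = seam64(seed=2)
        x = ag.Tensor(rng.standard_normal((1, 4, 8, 8)))
        outs = model.branch_outputs(x)
        assert not np.allclose(outs[0].data, outs[1].data)
        assert not np.allclose(outs[1].data, outs[2].data)


class TestGate:
    def test_zero_fc_weights_give_half(self, seam64, rng):
        model = seam64(seed=3)
        for fc in (model.fc1, model.fc2):
            fc.weight.data[...] = 0
            fc.bias.data[...] = 0
        x = ag.Tensor(rng.standard_normal((2, 4, 8, 8)))
        g = model.gate(model.branch_outputs(x))
        assert np.allclose(g.data, 0.5, atol=1e-14)

    def test_pooling_of_constant_input(self, seam64):
        model = seam64(seed=4)
        # zero the convs so each branch is the pure residual -> pooling sees x
        for br in model._branches:
            br.depthwise.weight.data[...] = 0
            br.depthwise.bias.data[...] = 0
            br.pointwise.weight.data[...] = 0
            br.pointwise.bias.data[...] = 0
        const = np.arange(1, 5, dtype=np.float64).reshape(1, 4, 1, 1)
        x = ag.Tensor(np.broadcast_to(const, (1, 4, 8, 8)).copy())
        pooled = [b.mean(axis=(2, 3)) for b in model.branch_outputs(x)]
        for p in pooled:
            assert np.allclose(p.data, const.ravel(), atol=1e-14)

    def test_gate_matches_pool_matmul_sigmoid_oracle(self, seam64, rng):
        model = seam64(seed=5)
        x = rng.standard_normal((2, 4, 8, 8))
        outs = model.branch_outputs(ag.Tensor(x))
        g = model.gate(outs).data
        ybar = np.mean([o.data.mean(axis=(2, 3)) for o in outs], axis=0)
        from scipy.special import erf, expit
        hidden = ybar @ model.fc1.weight.data.T + model.fc1.bias.data
        hidden = 0.5 * hidden * (1 + erf(hidden / np.sqrt(2)))
        ref = expit(hidden @ model.fc2.weight.data.T + model.fc2.bias.data)
        assert np.abs(g - ref).max() < 1e-6

    def test_mismatched_branch_shapes_rejected(self, seam64, rng):
        model = seam64(seed=6)
        a = ag.Tensor(rng.standard_normal((1, 4, 8, 8)))
        b = ag.Tensor(rng.standard_normal((1, 4, 4, 4)))
        with pytest.raises(ValueError, match="shape"):
            model.gate([a, b])


class TestExpReweight:
    def test_zero_gate_is_identity(self, rng):
        x = ag.Tensor(rng.standard_normal((1, 3, 4, 4)))
        g = ag.Tensor(np.zeros((1, 3)))
        assert np.allclose(exp_reweight(x, g).data, x.data, atol=1e-14)

    def test_unit_gate_scales_by_e(self, rng):
        x = ag.Tensor(rng.standard_normal((1, 3, 4, 4)))
        g = ag.Tensor(np.ones((1, 3)))
        assert np.allclose(exp_reweight(x, g).data, np.e * x.data, atol=1e-12)

    def test_random_gate_matches_scalar_loop(self, rng):
        x = rng.standard_normal((2, 3, 4, 4))
        g = rng.random((2, 3))
        out = exp_reweight(ag.Tensor(x), ag.Tensor(g)).data
        for n in range(2):
            for c in range(3):
                for i in range(4):
                    for j in range(4):
                        assert abs(out[n, c, i, j]
                                   - x[n, c, i, j] * math.exp(g[n, c])) < 1e-12

    def test_out_of_range_gate_rejected(self, rng):
        x = ag.Tensor(rng.standard_normal((1, 2, 4, 4)))
        with pytest.raises(ValueError, match="0, 1"):
            exp_reweight(x, ag.Tensor(np.array([[0.5, 1.5]])))


class TestSeamForward:
    def test_shape_preserved(self, rng):
        cfg = SeamConfig(channels=32)
        model = SEAM(cfg, rng=np.random.default_rng(0))
        x = ag.Tensor(rng.standard_normal((2, 32, 16, 16)).astype(np.float32))
        assert model(x).data.shape == (2, 32, 16, 16)

    def test_multiplier_bounds_for_nonnegative_input(self, seam64, rng):
        model = seam64(seed=7)
        x = rng.random((2, 4, 8, 8))
        out = model(ag.Tensor(x)).data
        assert (out >= x - 1e-12).all()
        assert (out <= np.e * x + 1e-12).all()
        w = model.attention_weights(ag.Tensor(x))
        assert ((w.g > 0) & (w.g < 1)).all()
        assert ((w.scale >= 1) & (w.scale <= np.e)).all()

    def test_matches_scalar_reference(self, seam64, rng):
        for seed in range(3):
            model = seam64(seed=seed, patch_size=5)
            x = np.random.default_rng(100 + seed).standard_normal((1, 4, 8, 8))
            out = model(ag.Tensor(x)).data
            ref = scalar_seam_reference(model, x)
            assert np.abs(out - ref).max() < 1e-5

    def test_zero_convs_reduce_to_closed_form(self, seam64, rng):
        """With zero conv weights + residual, SEAM is x * exp(sigmoid(mlp(pool(x))))."""
        from scipy.special import erf, expit
        model = seam64(seed=8)
        for br in model._branches:
            br.depthwise.weight.data[...] = 0
            br.depthwise.bias.data[...] = 0
            br.pointwise.weight.data[...] = 0
            br.pointwise.bias.data[...] = 0
        x = rng.standard_normal((2, 4, 8, 8))
        pooled = x.mean(axis=(2, 3))
        hidden = pooled @ model.fc1.weight.data.T + model.fc1.bias.data
        hidden = 0.5 * hidden * (1 + erf(hidden / np.sqrt(2)))
        g = expit(hidden @ model.fc2.weight.data.T + model.fc2.bias.data)
        ref = x * np.exp(g)[:, :, None, None]
        assert np.abs(model(ag.Tensor(x)).data - ref).max() < 1e-10

    def test_gradient_flows_to_every_weight(self, seam64):
        model = seam64(seed=9, channels=2, patch_size=3)
        x = ag.Tensor(np.random.default_rng(0).standard_normal((1, 2, 4, 4)),
                      requires_grad=True)
        out = ag.tensor_sum(model(x) * model(x))
        out.backward()
        for name, p in model.named_parameters():
            assert p.grad is not None, name
            assert np.isfinite(p.grad).all()

    def test_finite_difference_gradients(self, seam64):
        model = seam64(seed=10, channels=2, patch_size=3)
        x0 = np.random.default_rng(1).standard_normal((1, 2, 4, 4))

        def loss():
            return ag.tensor_sum(ag.sigmoid(model(ag.Tensor(x0, requires_grad=False))))

        out = loss()
        out.backward()
        eps = 1e-6
        for name, p in model.named_parameters():
            g_an = p.grad
            flat = p.data.ravel()
            idx = np.linspace(0, flat.size - 1, min(5, flat.size)).astype(int)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                fp = float(loss().data.sum())
                flat[i] = orig - eps
                fm = float(loss().data.sum())
                flat[i] = orig
                fd = (fp - fm) / (2 * eps)
                assert abs(g_an.ravel()[i] - fd) < 1e-3 * max(1.0, abs(fd)), name

    def test_literal_gate_product_variant(self, seam64, rng):
        model = seam64(seed=11, gate_times_pooled=True)
        x = rng.standard_normal((1, 4, 8, 8))
        out = model(ag.Tensor(x))
        assert out.data.shape == x.shape  # no range guarantee, shape contract only
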