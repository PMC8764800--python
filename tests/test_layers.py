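import numpy as np
import pytest

import brainnetga as bg
from brainnetga.layers import (Conv2DSame, E2ELayer, E2NLayer, Linear,
                               NetGABlock, leaky_relu)


def e2e_bruteforce(x, w):
    """Nested-loop oracle for the edge-to-edge cross filter."""
    h, width, c_in = x.shape
    c_out = w.bias.shape[0]
    out = np.zeros((h, width, c_out))
    for i in range(h):
        for j in range(width):
            for o in range(c_out):
                acc = w.bias[o]
                for m in range(c_in):
                    for k in range(width):
                        acc += w.row_w[o, m, k] * x[i, k, m]
                    for k in range(h):
                        acc += w.col_w[o, m, k] * x[k, j, m]
                out[i, j, o] = acc
    return out


def cov_bruteforce(x):
    """1/M-normalized sample covariance of mean-centered rows, by loops."""
    h, M = x.shape
    xc = np.array([row - row.mean() for row in x])
    out = np.zeros((h, h))
    for i in range(h):
        for j in range(h):
            out[i, j] = (xc[i] * xc[j]).sum() / M
    return out


def random_e2e_weights(rng, h, w, c_in, c_out):
    return bg.E2EWeights(rng.normal(size=(c_out, c_in, w)),
                         rng.normal(size=(c_out, c_in, h)),
                         rng.normal(size=c_out))


class TestE2EForward:
    def test_zero_weights_give_zero_output(self, rng):
        x = rng.normal(size=(4, 4, 2))
        w = bg.E2EWeights(np.zeros((3, 2, 4)), np.zeros((3, 2, 4)), np.zeros(3))
        assert np.all(bg.e2e_forward(x, w) == 0)

    def test_all_ones_row_plus_column_sum(self):
        x = np.ones((3, 3, 1))
        w = bg.E2EWeights(np.ones((1, 1, 3)), np.ones((1, 1, 3)), np.zeros(1))
        assert np.allclose(bg.e2e_forward(x, w), 6.0)

    @pytest.mark.parametrize("h,w,c_in,c_out", [(4, 4, 2, 3), (6, 6, 3, 2)])
    def test_matches_nested_loop_oracle(self, rng, h, w, c_in, c_out):
        x = rng.normal(size=(h, w, c_in))
        weights = random_e2e_weights(rng, h, w, c_in, c_out)
        got = bg.e2e_forward(x, weights)
        assert np.max(np.abs(got - e2e_bruteforce(x, weights))) < 1e-10

    def test_linear_superposition(self, rng):
        x1, x2 = rng.normal(size=(2, 5, 5, 2))
        w = random_e2e_weights(rng, 5, 5, 2, 2)
        w0 = bg.E2EWeights(w.row_w, w.col_w, np.zeros(2))
        lhs = bg.e2e_forward(2.0 * x1 + 3.0 * x2, w0)
        rhs = 2.0 * bg.e2e_forward(x1, w0) + 3.0 * bg.e2e_forward(x2, w0)
        assert np.max(np.abs(lhs - rhs)) < 1e-10

    def test_shape_mismatch_raises(self, rng):
        x = rng.normal(size=(4, 4, 2))
        w = random_e2e_weights(rng, 5, 5, 2, 1)
        with pytest.raises(ValueError):
            bg.e2e_forward(x, w)


class TestReshapeRegions:
    def test_single_channel_rows(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])[:, :, None]
        assert np.array_equal(bg.reshape_regions(x), [[1, 2], [3, 4]])

    def test_channel_varies_fastest(self):
        # h=1, w=2, c=2: row must read (j=0,c=0),(j=0,c=1),(j=1,c=0),(j=1,c=1)
        x = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        assert np.array_equal(bg.reshape_regions(x), [[1, 2, 3, 4]])

    def test_bijection(self, rng):
        x = rng.normal(size=(3, 5, 4))
        r = bg.reshape_regions(x)
        assert r.shape == (3, 20)
        assert np.array_equal(bg.layers.unreshape_regions(r, 5, 4), x)


class TestCovariancePool:
    def test_constant_rows_annihilated(self):
        x = np.outer([1.0, -2.0, 3.0], np.ones(5))
        assert np.max(np.abs(bg.covariance_pool(x))) == 0.0

    def test_worked_example(self):
        got = bg.covariance_pool(np.array([[1.0, 2.0], [3.0, 5.0]]))
        assert np.allclose(got, [[0.25, 0.5], [0.5, 1.0]], atol=1e-12)

    def test_matches_eq_form_with_centering_matrix(self, rng):
        x = rng.normal(size=(4, 7))
        M = 7
        A = (np.eye(M) - np.ones((M, M)) / M) / M
        assert np.max(np.abs(bg.covariance_pool(x) - x @ A @ x.T)) < 1e-12

    def test_oracle_sweep_symmetric_psd(self, rng):
        for _ in range(200):
            h, M = rng.integers(1, 9), rng.integers(2, 13)
            x = rng.normal(size=(h, M)) * rng.uniform(0.1, 10)
            got = bg.covariance_pool(x)
            assert np.max(np.abs(got - cov_bruteforce(x))) < 1e-10
            assert np.max(np.abs(got - got.T)) < 1e-10
            assert np.linalg.eigvalsh(got).min() >= -1e-8 * max(np.trace(got), 1e-30)

    def test_shift_invariance(self, rng):
        x = rng.normal(size=(5, 8))
        shifted = x + 3.7  # constant added to every column
        assert np.max(np.abs(bg.covariance_pool(x) - bg.covariance_pool(shifted))) < 1e-10

    def test_single_feature_rejected(self):
        with pytest.raises(ValueError):
            bg.covariance_pool(np.ones((3, 1)))


class TestRowGroupConv:
    def test_row_sums_with_ones_filters(self):
        cov = np.array([[2.0, 1.0], [1.0, 3.0]])
        got = bg.row_group_conv(cov, np.ones((2, 2)), np.zeros(2))
        assert np.allclose(got, [3.0, 4.0])

    def test_one_hot_filters_pick_diagonal(self):
        cov = np.array([[2.0, 1.0], [1.0, 3.0]])
        assert np.allclose(bg.row_group_conv(cov, np.eye(2), np.zeros(2)), [2.0, 3.0])

    def test_zero_filters_return_bias(self):
        cov = np.ones((3, 3))
        b = np.array([1.0, -2.0, 0.5])
        assert np.allclose(bg.row_group_conv(cov, np.zeros((3, 3)), b), b)

    def test_filter_count_mismatch(self):
        with pytest.raises(ValueError):
            bg.row_group_conv(np.ones((3, 3)), np.ones((2, 3)), np.zeros(3))


class TestN2GExcite:
    def test_zero_params_give_half(self):
        a = bg.n2g_excite(np.arange(4.0), np.zeros((2, 4)), np.zeros(2),
                          np.zeros((4, 2)), np.zeros(4))
        assert np.allclose(a, 0.5)

    def test_output_strictly_in_unit_interval(self, rng):
        for _ in range(20):
            a = bg.n2g_excite(rng.normal(size=6) * 100,
                              rng.normal(size=(3, 6)), rng.normal(size=3),
                              rng.normal(size=(6, 3)), rng.normal(size=6))
            assert np.all(a > 0.0) and np.all(a < 1.0)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            bg.n2g_excite(np.ones(4), np.zeros((2, 5)), np.zeros(2),
                          np.zeros((4, 2)), np.zeros(4))


class TestRowMultiply:
    def test_identity_zero_and_scaling(self, rng):
        x = rng.normal(size=(3, 4, 2))
        assert np.array_equal(bg.row_multiply(x, np.ones(3)), x)
        assert np.all(bg.row_multiply(x, np.zeros(3)) == 0)
        scaled = bg.row_multiply(x, np.array([2.0, 1.0, 1.0]))
        assert np.allclose(scaled[0], 2 * x[0]) and np.array_equal(scaled[1:], x[1:])

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            bg.row_multiply(rng.normal(size=(3, 3, 1)), np.ones(4))


class TestNetGABlock:
    def _block(self, rng, h=8, c=4, ce=2, d=3, **kw):
        return NetGABlock(h, c, ce, d, rng=np.random.default_rng(0), **kw)

    def test_preserves_shape(self, rng):
        for h, c in [(4, 1), (8, 4), (5, 3)]:
            block = NetGABlock(h, c, 2, 3, rng=np.random.default_rng(1))
            x = rng.normal(size=(2, h, h, c))
            assert block.forward(x).shape == x.shape

    def test_saturated_attention_is_identity(self, rng):
        block = self._block(rng)
        block.params["W2"][:] = 0.0
        block.params["b2"][:] = 30.0  # sigmoid(30) ~ 1 - 1e-13
        x = rng.normal(size=(8, 8, 4))
        assert np.max(np.abs(bg.netga_block(x, block) - x)) < 1e-3

    def test_composition_equals_chained_operators(self, rng):
        block = self._block(rng)
        x = rng.normal(size=(8, 8, 4))
        z = leaky_relu(bg.e2e_forward(x, block.e2e_layers[0].weights()))
        r = bg.reshape_regions(z)
        cov = bg.covariance_pool(r)
        resp = bg.row_group_conv(cov, block.params["row_f"], block.params["row_b"])
        a = bg.n2g_excite(resp, block.params["W1"], block.params["b1"],
                          block.params["W2"], block.params["b2"])
        chained = bg.row_multiply(x, a)
        assert np.max(np.abs(bg.netga_block(x, block) - chained)) < 1e-10

    def test_no_covariance_variant_reduces_reshaped_rows(self, rng):
        block = self._block(rng, use_covariance_pooling=False)
        x = rng.normal(size=(8, 8, 4))
        z = leaky_relu(bg.e2e_forward(x, block.e2e_layers[0].weights()))
        r = bg.reshape_regions(z)
        resp = bg.row_group_conv(r, block.params["row_f"], block.params["row_b"])
        a = bg.n2g_excite(resp, block.params["W1"], block.params["b1"],
                          block.params["W2"], block.params["b2"])
        assert np.max(np.abs(bg.netga_block(x, block) - bg.row_multiply(x, a))) < 1e-10

    def test_gates_bound_output_magnitude(self, rng):
        block = self._block(rng)
        x = rng.normal(size=(2, 8, 8, 4))
        out = block.forward(x)
        assert np.all(np.abs(out) <= np.abs(x) + 1e-15)

    def test_non_square_input_rejected(self, rng):
        with pytest.raises(ValueError):
            bg.netga_block(rng.normal(size=(4, 5, 2)), self._block(rng, h=4))


# ---------------------------------------------------------------------------
# analytic gradients vs central finite differences
# ---------------------------------------------------------------------------

def _check_input_grad(layer, x, rng, n_entries=5, tol=1e-4, forward=None):
    fwd = forward if forward is not None else layer.forward
    out = fwd(x)
    R = rng.normal(size=out.shape)  # random linear functional of the output
    layer.zero_grad()
    fwd(x)
    dx = layer.backward(R)
    worst = 0.0
    for _ in range(n_entries):
        idx = tuple(rng.integers(0, s) for s in x.shape)
        eps = 1e-6
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        fd = ((fwd(xp) * R).sum() - (fwd(xm) * R).sum()) / (2 * eps)
        worst = max(worst, abs(fd - dx[idx]) / max(abs(fd), abs(dx[idx]), 1e-8))
    assert worst < tol, f"input gradient mismatch: rel err {worst:.2e}"


def _check_param_grads(layer, x, rng, n_entries=5, tol=1e-4):
    params = (layer.named_params() if isinstance(layer, NetGABlock)
              else layer.params)
    out = layer.forward(x)
    R = rng.normal(size=out.shape)
    layer.zero_grad()
    layer.forward(x)
    layer.backward(R)
    grads = (layer.named_grads() if isinstance(layer, NetGABlock)
             else layer.grads)
    for name, p in params.items():
        flat = p.ravel()
        for _ in range(n_entries):
            i = rng.integers(0, flat.size)
            eps, orig = 1e-6, flat[i]
            flat[i] = orig + eps
            lp = (layer.forward(x) * R).sum()
            flat[i] = orig - eps
            lm = (layer.forward(x) * R).sum()
            flat[i] = orig
            fd = (lp - lm) / (2 * eps)
            an = grads[name].ravel()[i]
            rel = abs(fd - an) / max(abs(fd), abs(an), 1e-8)
            assert rel < tol, f"{name}: rel err {rel:.2e}"


LAYER_FACTORIES = {
    "conv3x3": lambda r: (Conv2DSame(2, 3, r), (2, 6, 6, 2)),
    "e2e": lambda r: (E2ELayer(5, 5, 2, 3, r), (2, 5, 5, 2)),
    "e2n": lambda r: (E2NLayer(5, 2, 3, r), (2, 5, 5, 2)),
    "linear": lambda r: (Linear(7, 3, r), (4, 7)),
    "netga_full": lambda r: (NetGABlock(5, 3, 2, 3, r), (2, 5, 5, 3)),
    "netga_nogcp": lambda r: (
        NetGABlock(5, 3, 2, 3, r, use_covariance_pooling=False), (2, 5, 5, 3)),
    "netga_2e2e": lambda r: (NetGABlock(5, 3, 2, 3, r, n_e2e_layers=2),
                             (2, 5, 5, 3)),
}


@pytest.mark.parametrize("name", sorted(LAYER_FACTORIES))
def test_finite_difference_matches_analytic_gradients(name, rng):
    layer, shape = LAYER_FACTORIES[name](np.random.default_rng(3))
    x = rng.normal(size=shape)
    _check_input_grad(layer, x, rng)
    _check_param_grads(layer, x, rng)
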