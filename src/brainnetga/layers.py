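"""Net-GA block operators with analytic forward/backward passes.

The block enhances an h x w x c activation tensor X (h = w = number of brain
regions at the network input) in five steps:

1. **E2E (edge-to-edge)** cross filters: the response at edge (i, j) combines
   every edge sharing row i or column j, squeezing channels c -> c'.
2. **Reshape** to an h x M region-feature matrix (M = w * c'), row i holding
   all features of region i; channel index varies fastest, then column.
3. **Global covariance pooling**: the M-normalized sample covariance of the
   mean-centered rows, ``x A x^T`` with ``A = (1/M)(I - (1/M) J J^T)`` —
   second-order statistics of region features.
4. **Row-wise group convolution (E2N)**: each region keeps its own length-h
   filter over its covariance row, giving one response per region.
5. **N2G excitation**: a bottleneck (h -> d_hidden -> h) with a final sigmoid
   yields per-region attention gates in (0, 1), which rescale the rows of the
   ORIGINAL input tensor X.

Module-level functions operate on single (unbatched) tensors and define the
reference semantics; the ``*Layer``/:class:`NetGABlock` classes hold
parameters and run batched forward/backward for training.  All arithmetic is
float64 NumPy; gradients are derived analytically and are validated against
central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

LEAKY_SLOPE = 0.01


# ---------------------------------------------------------------------------
# elementwise pieces
# ---------------------------------------------------------------------------

def leaky_relu(x: np.ndarray, slope: float = LEAKY_SLOPE) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _leaky_relu_grad(x: np.ndarray, slope: float = LEAKY_SLOPE) -> np.ndarray:
    return np.where(x > 0, 1.0, slope)


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic, clamped into the open interval (0, 1)
    so downstream gates never degenerate to exact 0/1 at float64 saturation."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return np.clip(out, np.finfo(float).tiny, 1.0 - np.finfo(float).epsneg)


def _he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-limit, limit, size=shape)


# ---------------------------------------------------------------------------
# functional reference operators (single tensor, no batch axis)
# ---------------------------------------------------------------------------

@dataclass
class E2EWeights:
    """Cross-filter weights: per output channel o and input channel m,
    a length-w row filter and a length-h column filter, plus a bias.

    ``row_w`` has shape (c_out, c_in, w); ``col_w`` (c_out, c_in, h);
    ``bias`` (c_out,).
    """

    row_w: np.ndarray
    col_w: np.ndarray
    bias: np.ndarray

    def check(self, h: int, w: int, c_in: int) -> None:
        c_out = self.bias.shape[0]
        if self.row_w.shape != (c_out, c_in, w) or self.col_w.shape != (c_out, c_in, h):
            raise ValueError(
                f"E2E weight shapes {self.row_w.shape}/{self.col_w.shape} do not "
                f"match input (h={h}, w={w}, c_in={c_in}, c_out={c_out})")


def e2e_forward(x: np.ndarray, weights: E2EWeights) -> np.ndarray:
    """Edge-to-edge cross filter.

    ``out[i,j,o] = bias_o + sum_m ( <row_w[o,m], x[i,:,m]> + <col_w[o,m], x[:,j,m]> )``
    — the response at edge (i, j) pools the whole row i and column j.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError(f"expected h x w x c tensor, got shape {x.shape}")
    h, w, c = x.shape
    weights.check(h, w, c)
    row = np.einsum("ikm,omk->io", x, weights.row_w)
    col = np.einsum("kjm,omk->jo", x, weights.col_w)
    return row[:, None, :] + col[None, :, :] + weights.bias


def reshape_regions(x: np.ndarray) -> np.ndarray:
    """Flatten an h x w x c' tensor to h x M, M = w*c'.

    Row i concatenates x[i, j, m] with the channel index m varying fastest,
    then the column index j (a plain C-order reshape; exactly invertible).
    """
    h, w, c = x.shape
    return np.ascontiguousarray(x).reshape(h, w * c)


def unreshape_regions(x: np.ndarray, w: int, c: int) -> np.ndarray:
    """Inverse of :func:`reshape_regions`."""
    return x.reshape(x.shape[0], w, c)


def covariance_pool(x: np.ndarray) -> np.ndarray:
    """Global covariance pooling: ``x A x^T``, A = (1/M)(I - (1/M) J J^T).

    Equivalently the 1/M-normalized outer product of the row-mean-centered
    matrix with itself: symmetric, positive semidefinite, and invariant to
    adding a constant to every column.
    """
    x = np.asarray(x, dtype=float)
    h, M = x.shape
    if M < 2:
        raise ValueError(f"covariance pooling needs M >= 2 features, got M={M}")
    xc = x - x.mean(axis=1, keepdims=True)
    return xc @ xc.T / M


def row_group_conv(cov: np.ndarray, filters: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Row-wise group convolution: region i keeps its own filter.

    ``response_i = bias_i + <filters[i], cov[i]>``.
    """
    cov = np.asarray(cov, dtype=float)
    h = cov.shape[0]
    if filters.shape != cov.shape or bias.shape != (h,):
        raise ValueError(
            f"need {cov.shape} filters and ({h},) bias, got {filters.shape}/{bias.shape}")
    return (filters * cov).sum(axis=1) + bias


def n2g_excite(x: np.ndarray, W1: np.ndarray, b1: np.ndarray,
               W2: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """Node-to-graph excitation: bottleneck + sigmoid attention gates.

    ``a = sigmoid(W2 . act(W1 . x + b1) + b2)`` with a leaky-rectifier
    activation; every gate lies strictly in (0, 1).
    """
    x = np.asarray(x, dtype=float)
    h = x.shape[0]
    d = W1.shape[0]
    if W1.shape != (d, h) or W2.shape != (h, d) or b1.shape != (d,) or b2.shape != (h,):
        raise ValueError("bottleneck weight shapes inconsistent with input length")
    return sigmoid(W2 @ leaky_relu(W1 @ x + b1) + b2)


def row_multiply(x: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Rescale row i of the tensor by gate a_i (shape preserved)."""
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float)
    if a.shape != (x.shape[0],):
        raise ValueError(f"need {x.shape[0]} gates, got shape {a.shape}")
    return x * a[:, None, None]


def netga_block(x: np.ndarray, block: "NetGABlock") -> np.ndarray:
    """Apply a Net-GA block to a single h x w x c tensor (h must equal w)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 3 or x.shape[0] != x.shape[1]:
        raise ValueError(f"Net-GA block needs a square h x h x c tensor, got {x.shape}")
    return block.forward(x[None])[0]


# ---------------------------------------------------------------------------
# batched trainable layers
# ---------------------------------------------------------------------------

class Layer:
    """Minimal trainable layer: named parameters, cached forward, backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._cache: dict = {}

    def zero_grad(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2DSame(Layer):
    """k x k convolution, stride 1, zero same-padding (h and w preserved)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        super().__init__()
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.params = {
            "W": _he_uniform(rng, (k, k, c_in, c_out), fan_in=k * k * c_in),
            "b": np.zeros(c_out),
        }
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (B,h,w,c,k,k)
        self._cache = {"win": win, "x_shape": x.shape}
        return np.einsum("bijckl,klcm->bijm", win, self.params["W"]) + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        win = self._cache["win"]
        self.grads["W"] += np.einsum("bijm,bijckl->klcm", dy, win)
        self.grads["b"] += dy.sum(axis=(0, 1, 2))
        Wf = self.params["W"][::-1, ::-1]  # rotated kernel for the input grad
        dyp = np.pad(dy, ((0, 0), (p, p), (p, p), (0, 0)))
        win2 = sliding_window_view(dyp, (k, k), axis=(1, 2))
        return np.einsum("bijokl,klco->bijc", win2, Wf)


class LeakyReLU(Layer):
    def __init__(self, slope: float = LEAKY_SLOPE):
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = {"x": x}
        return leaky_relu(x, self.slope)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * _leaky_relu_grad(self._cache["x"], self.slope)


class E2ELayer(Layer):
    """Batched edge-to-edge cross filter (see :func:`e2e_forward`)."""

    def __init__(self, h: int, w: int, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.h, self.w, self.c_in, self.c_out = h, w, c_in, c_out
        fan_in = c_in * (h + w)
        self.params = {
            "row_w": _he_uniform(rng, (c_out, c_in, w), fan_in),
            "col_w": _he_uniform(rng, (c_out, c_in, h), fan_in),
            "b": np.zeros(c_out),
        }
        self.zero_grad()

    def weights(self) -> E2EWeights:
        return E2EWeights(self.params["row_w"], self.params["col_w"], self.params["b"])

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1:] != (self.h, self.w, self.c_in):
            raise ValueError(f"E2E layer expects (*, {self.h}, {self.w}, {self.c_in}), "
                             f"got {x.shape}")
        self._cache = {"x": x}
        row = np.einsum("bikm,omk->bio", x, self.params["row_w"])
        col = np.einsum("bkjm,omk->bjo", x, self.params["col_w"])
        return row[:, :, None, :] + col[:, None, :, :] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache["x"]
        dR = dy.sum(axis=2)  # (B,h,o)
        dC = dy.sum(axis=1)  # (B,w,o)
        self.grads["row_w"] += np.einsum("bio,bikm->omk", dR, x)
        self.grads["col_w"] += np.einsum("bjo,bkjm->omk", dC, x)
        self.grads["b"] += dy.sum(axis=(0, 1, 2))
        dx = np.einsum("bio,omk->bikm", dR, self.params["row_w"])
        dx += np.einsum("bjo,omk->bkjm", dC, self.params["col_w"])
        return dx


class E2NLayer(Layer):
    """Edge-to-node reduction: per output channel, a length-w filter collapses
    each region's row of edge features to a scalar (used by the
    BrainNetCNN-style baseline, which has no covariance pooling)."""

    def __init__(self, w: int, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.w, self.c_in, self.c_out = w, c_in, c_out
        self.params = {
            "W": _he_uniform(rng, (c_out, c_in, w), fan_in=c_in * w),
            "b": np.zeros(c_out),
        }
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = {"x": x}
        return np.einsum("bijm,omj->bio", x, self.params["W"]) + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache["x"]
        self.grads["W"] += np.einsum("bio,bijm->omj", dy, x)
        self.grads["b"] += dy.sum(axis=(0, 1))
        return np.einsum("bio,omj->bijm", dy, self.params["W"])


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = {"shape": x.shape}
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._cache["shape"])


class Dropout(Layer):
    """Inverted dropout; active only when a generator is supplied to forward."""

    def __init__(self, rate: float = 0.5):
        super().__init__()
        self.rate = rate

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        if rng is None or self.rate == 0.0:
            self._cache = {"mask": None}
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep) / keep
        self._cache = {"mask": mask}
        return x * mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask = self._cache["mask"]
        return dy if mask is None else dy * mask


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.params = {"W": _he_uniform(rng, (d_out, d_in), fan_in=d_in),
                       "b": np.zeros(d_out)}
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = {"x": x}
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += dy.T @ self._cache["x"]
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"]


class NetGABlock(Layer):
    """The full squeeze–excite block gating the rows of its input tensor.

    Squeeze: E2E cross filters (stacked ``n_e2e_layers`` times, leaky-rectified)
    -> region-feature reshape -> covariance pooling (skipped when
    ``use_covariance_pooling=False``, the first-order ablation) -> row-wise
    group convolution.  Excite: h -> d_hidden -> h bottleneck with sigmoid
    gates; the gates multiply the rows of the ORIGINAL block input, so the
    output has exactly the input's shape.
    """

    def __init__(self, h: int, c_in: int, c_e2e: int, d_hidden: int,
                 rng: np.random.Generator, n_e2e_layers: int = 1,
                 use_covariance_pooling: bool = True):
        super().__init__()
        if h < 1 or c_e2e < 1 or d_hidden < 1 or n_e2e_layers < 1:
            raise ValueError("h, c_e2e, d_hidden, n_e2e_layers must all be >= 1")
        self.h, self.c_in, self.c_e2e = h, c_in, c_e2e
        self.d_hidden = d_hidden
        self.use_covariance_pooling = use_covariance_pooling
        self.e2e_layers: list[E2ELayer] = []
        c = c_in
        for _ in range(n_e2e_layers):
            self.e2e_layers.append(E2ELayer(h, h, c, c_e2e, rng))
            c = c_e2e
        self.M = h * c_e2e
        row_len = h if use_covariance_pooling else self.M
        self.params = {
            "row_f": _he_uniform(rng, (h, row_len), fan_in=row_len),
            "row_b": np.zeros(h),
            "W1": _he_uniform(rng, (d_hidden, h), fan_in=h),
            "b1": np.zeros(d_hidden),
            "W2": _he_uniform(rng, (h, d_hidden), fan_in=d_hidden),
            "b2": np.zeros(h),
        }
        self.zero_grad()

    # -- parameter plumbing over sub-layers -------------------------------
    def named_params(self) -> dict[str, np.ndarray]:
        out = dict(self.params)
        for i, l in enumerate(self.e2e_layers):
            out.update({f"e2e{i}.{k}": v for k, v in l.params.items()})
        return out

    def named_grads(self) -> dict[str, np.ndarray]:
        out = dict(self.grads)
        for i, l in enumerate(self.e2e_layers):
            out.update({f"e2e{i}.{k}": v for k, v in l.grads.items()})
        return out

    def zero_grad(self) -> None:
        super().zero_grad()
        for l in self.e2e_layers:
            l.zero_grad()

    # -- forward/backward ---------------------------------------------------
    def attention(self, x: np.ndarray) -> np.ndarray:
        """Per-region gates for a batch (B, h, w, c) -> (B, h)."""
        self.forward(x)
        return self._cache["a"]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, h, w, c = x.shape
        if h != w:
            raise ValueError(f"Net-GA block needs square tensors, got {x.shape[1:]}")
        z = x
        acts = []
        for layer in self.e2e_layers:
            pre = layer.forward(z)
            acts.append(pre)
            z = leaky_relu(pre)
        r = z.reshape(B, h, self.M)
        if self.use_covariance_pooling:
            rc = r - r.mean(axis=2, keepdims=True)
            feat = rc @ rc.transpose(0, 2, 1) / self.M
        else:
            rc = None
            feat = r
        resp = (feat * self.params["row_f"]).sum(axis=2) + self.params["row_b"]
        z1 = resp @ self.params["W1"].T + self.params["b1"]
        h1 = leaky_relu(z1)
        z2 = h1 @ self.params["W2"].T + self.params["b2"]
        a = sigmoid(z2)
        self._cache = {"x": x, "acts": acts, "r": r, "rc": rc, "feat": feat,
                       "resp": resp, "z1": z1, "h1": h1, "a": a}
        return x * a[:, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c = self._cache
        x, a = c["x"], c["a"]
        dx = dy * a[:, :, None, None]
        da = (dy * x).sum(axis=(2, 3))
        # excitation path
        dz2 = da * a * (1.0 - a)
        self.grads["W2"] += np.einsum("bh,bd->hd", dz2, c["h1"])
        self.grads["b2"] += dz2.sum(axis=0)
        dh1 = dz2 @ self.params["W2"]
        dz1 = dh1 * _leaky_relu_grad(c["z1"])
        self.grads["W1"] += dz1.T @ c["resp"]
        self.grads["b1"] += dz1.sum(axis=0)
        dresp = dz1 @ self.params["W1"]
        # squeeze path
        self.grads["row_f"] += np.einsum("bh,bhm->hm", dresp, c["feat"])
        self.grads["row_b"] += dresp.sum(axis=0)
        dfeat = dresp[:, :, None] * self.params["row_f"]
        if self.use_covariance_pooling:
            rc = c["rc"]
            drc = (dfeat + dfeat.transpose(0, 2, 1)) @ rc / self.M
            dr = drc - drc.mean(axis=2, keepdims=True)
        else:
            dr = dfeat
        dz = dr.reshape(x.shape[0], self.h, self.h, self.c_e2e)
        for layer, pre in zip(reversed(self.e2e_layers), reversed(c["acts"])):
            dz = layer.backward(dz * _leaky_relu_grad(pre))
        return dx + dz
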