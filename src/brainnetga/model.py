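"""The BrainNet-GA classifier: conv stages + Net-GA blocks + linear head.

The full architecture repeats ``n_stages`` times a [3x3 same-padded
convolution + leaky rectifier -> Net-GA block] stage, then flattens and maps
to two logits (SSD vs HC) through dropout and a linear layer.  Ablation
variants: ``no_gcp`` drops only the covariance pooling inside each block
(first-order squeeze), ``no_netga`` drops the blocks entirely, and
``brainnetcnn_style`` is the E2E->E2N->N2G feedforward baseline without
attention gating.

Everything is NumPy float64 with analytic backpropagation; training uses
Adam on softmax cross-entropy plus L1 and L2 penalties, fully deterministic
for a given seed.  :class:`BrainNetGAClassifier` wraps the network as a
scikit-learn estimator so it composes with pipelines and model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .io import POSITIVE_LABEL
from .layers import (Conv2DSame, Dropout, E2ELayer, E2NLayer, Flatten, Layer,
                     LeakyReLU, Linear, NetGABlock, leaky_relu)

VARIANTS = ("full", "no_gcp", "no_netga", "brainnetcnn_style")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the ablation optimum: two conv+block stages, 64 conv
    channels, one E2E layer squeezing to 16 channels, 10 bottleneck units.
    """

    n_regions: int = 116
    n_stages: int = 2
    conv_channels: int = 64
    e2e_channels: int = 16
    n_e2e_layers: int = 1
    n2g_hidden: int = 10
    variant: str = "full"
    dropout: float = 0.5

    def validate(self) -> None:
        bad = [name for name in ("n_regions", "n_stages", "conv_channels",
                                 "e2e_channels", "n_e2e_layers", "n2g_hidden")
               if getattr(self, name) < 1]
        if not 0.0 <= self.dropout < 1.0:
            bad.append("dropout")
        if self.variant not in VARIANTS:
            bad.append("variant")
        if bad:
            raise ValueError(f"invalid model config fields: {bad}")


def make_variant(cfg: ModelConfig, variant: str) -> ModelConfig:
    """Return a copy of ``cfg`` with the given ablation variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    return replace(cfg, variant=variant)


@dataclass
class ClassifierOutput:
    """Probabilities and logits in (SSD, HC) order."""

    probabilities: np.ndarray
    logits: np.ndarray


class Network:
    """Layer stack with forward, loss gradient, and input gradient."""

    def __init__(self, cfg: ModelConfig, seed: int):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        n = cfg.n_regions
        self.layers: list[Layer] = []
        self.blocks: list[NetGABlock] = []
        if cfg.variant == "brainnetcnn_style":
            c = 1
            for _ in range(cfg.n_e2e_layers):
                self.layers += [E2ELayer(n, n, c, cfg.e2e_channels, rng), LeakyReLU()]
                c = cfg.e2e_channels
            self.layers += [E2NLayer(n, c, cfg.conv_channels, rng), LeakyReLU(),
                            Flatten(),
                            Linear(n * cfg.conv_channels, cfg.n2g_hidden, rng),
                            LeakyReLU(), Dropout(cfg.dropout),
                            Linear(cfg.n2g_hidden, 2, rng)]
        else:
            c = 1
            for _ in range(cfg.n_stages):
                self.layers += [Conv2DSame(c, cfg.conv_channels, rng), LeakyReLU()]
                c = cfg.conv_channels
                if cfg.variant != "no_netga":
                    block = NetGABlock(
                        n, c, cfg.e2e_channels, cfg.n2g_hidden, rng,
                        n_e2e_layers=cfg.n_e2e_layers,
                        use_covariance_pooling=(cfg.variant != "no_gcp"))
                    self.layers.append(block)
                    self.blocks.append(block)
            self.layers += [Flatten(), Dropout(cfg.dropout),
                            Linear(n * n * c, 2, rng)]
        self._dropouts = [l for l in self.layers if isinstance(l, Dropout)]

    # -- parameters ---------------------------------------------------------
    def named_params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, l in enumerate(self.layers):
            items = l.named_params().items() if isinstance(l, NetGABlock) else l.params.items()
            out.update({f"layer{i}.{k}": v for k, v in items})
        return out

    def named_grads(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, l in enumerate(self.layers):
            items = l.named_grads().items() if isinstance(l, NetGABlock) else l.grads.items()
            out.update({f"layer{i}.{k}": v for k, v in items})
        return out

    def set_params_flat(self, params: dict[str, np.ndarray]) -> None:
        current = self.named_params()
        for k, v in params.items():
            current[k][...] = v

    def n_parameters(self) -> int:
        return sum(v.size for v in self.named_params().values())

    def zero_grad(self) -> None:
        for l in self.layers:
            l.zero_grad()

    # -- passes -------------------------------------------------------------
    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        """Logits (B, 2) in (SSD, HC) order; ``rng`` enables dropout."""
        z = x
        for l in self.layers:
            z = l.forward(z, rng) if isinstance(l, Dropout) else l.forward(z)
        return z

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dz = dlogits
        for l in reversed(self.layers):
            dz = l.backward(dz)
        return dz

    def loss_and_grads(self, x: np.ndarray, y_idx: np.ndarray, l1: float,
                       weight_decay: float,
                       rng: np.random.Generator | None = None) -> float:
        """Mean cross-entropy + penalties; gradients accumulated in layers."""
        B = x.shape[0]
        self.zero_grad()
        logits = self.forward(x, rng)
        shifted = logits - logits.max(axis=1, keepdims=True)
        logp = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
        ce = -logp[np.arange(B), y_idx].mean()
        probs = np.exp(logp)
        dlogits = probs.copy()
        dlogits[np.arange(B), y_idx] -= 1.0
        self.backward(dlogits / B)
        penalty = 0.0
        if l1 > 0 or weight_decay > 0:
            params, grads = self.named_params(), self.named_grads()
            for k, v in params.items():
                penalty += l1 * np.abs(v).sum() + weight_decay * (v ** 2).sum()
                grads[k] += l1 * np.sign(v) + 2.0 * weight_decay * v
        return float(ce + penalty)

    def input_gradient(self, x: np.ndarray, class_index: int) -> np.ndarray:
        """d(logit of class_index)/d(input), dropout off."""
        self.zero_grad()
        logits = self.forward(x)
        dlogits = np.zeros_like(logits)
        dlogits[:, class_index] = 1.0
        return self.backward(dlogits)

    # -- bookkeeping ---------------------------------------------------------
    def mac_count(self) -> int:
        """Multiply–accumulate operations for one single-subject forward."""
        n = self.cfg.n_regions
        total = 0
        for l in self.layers:
            if isinstance(l, Conv2DSame):
                total += n * n * l.k * l.k * l.c_in * l.c_out
            elif isinstance(l, E2ELayer):
                total += l.h * l.w * l.c_out * l.c_in * (l.h + l.w)
            elif isinstance(l, E2NLayer):
                total += n * l.c_out * l.c_in * l.w
            elif isinstance(l, Linear):
                total += l.params["W"].size
            elif isinstance(l, NetGABlock):
                for e in l.e2e_layers:
                    total += e.h * e.w * e.c_out * e.c_in * (e.h + e.w)
                if l.use_covariance_pooling:
                    total += l.h * l.h * l.M + l.h * l.M  # gram + centering
                total += l.params["row_f"].size
                total += 2 * l.h * l.d_hidden
                total += l.h * n * l.c_in  # row-wise gating
        return total


def build_model(cfg: ModelConfig, seed: int) -> Network:
    """Construct a network with deterministic seeded initialization."""
    return Network(cfg, seed)


def forward(net: Network, matrix: np.ndarray) -> ClassifierOutput:
    """Classify one connectivity matrix; probabilities in (SSD, HC) order."""
    matrix = np.asarray(matrix, dtype=float)
    n = net.cfg.n_regions
    if matrix.shape != (n, n):
        raise ValueError(f"matrix is {matrix.shape}, model expects ({n}, {n})")
    logits = net.forward(matrix[None, :, :, None])[0]
    shifted = logits - logits.max()
    probs = np.exp(shifted) / np.exp(shifted).sum()
    return ClassifierOutput(probabilities=probs, logits=logits)


def _cross_entropy(logits: np.ndarray, y_idx: np.ndarray) -> float:
    shifted = logits - logits.max(axis=1, keepdims=True)
    logp = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    return float(-logp[np.arange(len(y_idx)), y_idx].mean())


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class BrainNetGAClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn estimator over the BrainNet-GA network.

    Parameters mirror :class:`ModelConfig` plus the training hyperparameters.
    ``X`` may be (n_samples, n, n) stacked connectivity matrices or the
    flattened (n_samples, n*n) equivalent; ``y`` any two label values
    (by convention the strings ``"SSD"``/``"HC"``, SSD positive).

    Attributes set by :meth:`fit` (trailing underscore, sklearn convention):
    ``classes_``, ``n_regions_``, ``network_``, ``history_`` (per-epoch
    training loss), ``n_features_in_``.
    """

    def __init__(self, n_regions: int | None = None, n_stages: int = 2,
                 conv_channels: int = 64, e2e_channels: int = 16,
                 n_e2e_layers: int = 1, n2g_hidden: int = 10,
                 variant: str = "full", dropout: float = 0.5,
                 learning_rate: float = 1e-3, l1: float = 0.0,
                 weight_decay: float = 0.0, epochs: int = 100,
                 batch_size: int = 32, pos_label: str = POSITIVE_LABEL,
                 random_state: int = 0):
        self.n_regions = n_regions
        self.n_stages = n_stages
        self.conv_channels = conv_channels
        self.e2e_channels = e2e_channels
        self.n_e2e_layers = n_e2e_layers
        self.n2g_hidden = n2g_hidden
        self.variant = variant
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.l1 = l1
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.pos_label = pos_label
        self.random_state = random_state

    # -- helpers -------------------------------------------------------------
    def _as_tensors(self, X: np.ndarray, n: int | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            side = int(round(np.sqrt(X.shape[1])))
            if side * side != X.shape[1]:
                raise ValueError(f"flattened input width {X.shape[1]} is not a square")
            X = X.reshape(X.shape[0], side, side)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ValueError(f"expected (n_samples, n, n) matrices, got {X.shape}")
        if n is not None and X.shape[1] != n:
            raise ValueError(f"matrices are {X.shape[1]}x{X.shape[1]}, "
                             f"model expects {n}x{n}")
        return X[..., None]

    def _config(self, n: int) -> ModelConfig:
        return ModelConfig(n_regions=n, n_stages=self.n_stages,
                           conv_channels=self.conv_channels,
                           e2e_channels=self.e2e_channels,
                           n_e2e_layers=self.n_e2e_layers,
                           n2g_hidden=self.n2g_hidden, variant=self.variant,
                           dropout=self.dropout)

    # -- sklearn API ----------------------------------------------------------
    def fit(self, X, y, validation_data=None, patience: int = 10):
        """Train the network.

        ``validation_data=(X_val, y_val)`` enables early stopping on the
        validation cross-entropy with the given patience; the parameters from
        the best epoch are restored.  Without it, training runs for exactly
        ``epochs`` epochs.
        """
        Xt = self._as_tensors(X, self.n_regions)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"need exactly 2 classes, got {list(self.classes_)}")
        pos = self.pos_label if self.pos_label in self.classes_ else self.classes_[-1]
        self.positive_class_ = pos
        # internal logit order: (positive, negative)
        y_idx = np.where(y == pos, 0, 1)
        n = Xt.shape[1]
        self.n_regions_ = n
        self.n_features_in_ = n * n if np.asarray(X).ndim == 2 else n
        net = Network(self._config(n), seed=self.random_state)
        rng = np.random.default_rng(
            np.random.SeedSequence([self.random_state, 0xB1A1]))
        opt = _Adam(net.named_params(), lr=self.learning_rate)
        N = Xt.shape[0]
        bs = min(self.batch_size, N)
        if validation_data is not None:
            Xv = self._as_tensors(validation_data[0], n)
            yv_idx = np.where(np.asarray(validation_data[1]) == pos, 0, 1)
        best_val, best_params, since_best = np.inf, None, 0
        history = []
        for _ in range(self.epochs):
            order = rng.permutation(N)
            epoch_loss = 0.0
            for start in range(0, N, bs):
                idx = order[start:start + bs]
                loss = net.loss_and_grads(Xt[idx], y_idx[idx], self.l1,
                                          self.weight_decay, rng)
                opt.step(net.named_grads())
                epoch_loss += loss * len(idx)
            history.append(epoch_loss / N)
            if validation_data is not None:
                val = _cross_entropy(net.forward(Xv), yv_idx)
                if val < best_val - 1e-12:
                    best_val, since_best = val, 0
                    best_params = {k: v.copy() for k, v in net.named_params().items()}
                else:
                    since_best += 1
                    if since_best >= patience:
                        break
        if best_params is not None:
            net.set_params_flat(best_params)
        self.network_ = net
        self.history_ = history
        return self

    def _logits(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        Xt = self._as_tensors(X, self.n_regions_)
        # batch in chunks to bound peak memory on large inputs
        outs = [self.network_.forward(Xt[i:i + 64]) for i in range(0, len(Xt), 64)]
        return np.vstack(outs)

    def decision_function(self, X) -> np.ndarray:
        logits = self._logits(X)
        return logits[:, 0] - logits[:, 1]  # positive-class margin

    def predict_proba(self, X) -> np.ndarray:
        logits = self._logits(X)
        shifted = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(shifted)
        p /= p.sum(axis=1, keepdims=True)
        # align columns with classes_
        proba = np.empty_like(p)
        for j, cls in enumerate(self.classes_):
            proba[:, j] = p[:, 0] if cls == self.positive_class_ else p[:, 1]
        return proba

    def predict(self, X) -> np.ndarray:
        margin = self.decision_function(X)
        neg = [c for c in self.classes_ if c != self.positive_class_][0]
        return np.where(margin > 0, self.positive_class_, neg)


def save_checkpoint(clf: BrainNetGAClassifier, path) -> None:
    """Serialize a fitted classifier (weights + config) to one .npz file."""
    check_is_fitted(clf, "network_")
    import json

    meta = {"estimator_params": clf.get_params(),
            "classes": [str(c) for c in clf.classes_],
            "positive_class": str(clf.positive_class_),
            "n_regions": int(clf.n_regions_)}
    arrays = {f"param:{k}": v for k, v in clf.network_.named_params().items()}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> BrainNetGAClassifier:
    """Rebuild a fitted classifier from :func:`save_checkpoint` output."""
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        arrays = {k[len("param:"):]: data[k] for k in data.files
                  if k.startswith("param:")}
    clf = BrainNetGAClassifier(**meta["estimator_params"])
    clf.classes_ = np.array(meta["classes"])
    clf.positive_class_ = meta["positive_class"]
    clf.n_regions_ = meta["n_regions"]
    clf.n_features_in_ = clf.n_regions_ ** 2
    clf.network_ = Network(clf._config(clf.n_regions_), seed=clf.random_state)
    clf.network_.set_params_flat(arrays)
    clf.history_ = []
    return clf
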