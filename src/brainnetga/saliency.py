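"""Gradient-based saliency for connectome edges.

For a trained classifier and a target class, the saliency of edge (i, j) is
the absolute partial derivative of the target-class logit (pre-softmax) with
respect to input entry (i, j), symmetrized by averaging with (j, i) and with
the diagonal zeroed.  Per-subject maps from held-out data are linearly
integrated (elementwise mean) and scaled so the strongest edge equals 1;
nodal strength is the row sum of the aggregated map.
"""

from __future__ import annotations

import numpy as np

from .io import Atlas, POSITIVE_LABEL
from .model import BrainNetGAClassifier


def _class_index(clf: BrainNetGAClassifier, target: str) -> int:
    # internal logit order is (positive, negative)
    if target not in clf.classes_:
        raise ValueError(f"target {target!r} not among classes {list(clf.classes_)}")
    return 0 if target == clf.positive_class_ else 1


def gradient_saliency(clf: BrainNetGAClassifier, matrix: np.ndarray,
                      target: str = POSITIVE_LABEL,
                      mode: str = "gradient") -> np.ndarray:
    """Unnormalized per-subject saliency map (n x n, nonnegative, symmetric).

    ``mode="gradient"`` uses |d logit / d input|; ``mode="gradient_input"``
    multiplies the gradient by the input before taking absolute values.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = clf.n_regions_
    if matrix.shape != (n, n):
        raise ValueError(f"matrix is {matrix.shape}, model expects ({n}, {n})")
    grad = clf.network_.input_gradient(matrix[None, :, :, None],
                                       _class_index(clf, target))[0, :, :, 0]
    if mode == "gradient_input":
        grad = grad * matrix
    elif mode != "gradient":
        raise ValueError(f"unknown saliency mode {mode!r}")
    s = np.abs(grad)
    s = (s + s.T) / 2.0
    np.fill_diagonal(s, 0.0)
    return s


def aggregate_saliency(maps: list[np.ndarray]) -> np.ndarray:
    """Elementwise mean of per-subject maps, rescaled so the max entry is 1."""
    if len(maps) == 0:
        raise ValueError("no saliency maps to aggregate")
    stack = np.stack([np.asarray(m, dtype=float) for m in maps])
    mean = stack.mean(axis=0)
    top = mean.max()
    if top <= 0:
        raise ValueError("aggregate saliency is identically zero; nothing to normalize")
    return mean / top


def nodal_strength(smap: np.ndarray) -> np.ndarray:
    """Sum of edge weights attached to each node: ``strength_i = sum_j map[i, j]``."""
    smap = np.asarray(smap, dtype=float)
    return smap.sum(axis=1)


def top_edges(smap: np.ndarray, k: int, atlas: Atlas) -> list[tuple[str, str, float]]:
    """The k strongest canonical (i < j) edges, named via the atlas.

    Ties are broken by lexicographically smaller index pair first.
    """
    smap = np.asarray(smap, dtype=float)
    n = smap.shape[0]
    n_edges = n * (n - 1) // 2
    if not 1 <= k <= n_edges:
        raise ValueError(f"k must be in [1, {n_edges}], got {k}")
    iu = np.triu_indices(n, k=1)
    weights = smap[iu]
    # stable sort on -weight keeps lexicographic (i, j) order among ties
    order = np.argsort(-weights, kind="stable")[:k]
    return [(atlas.names[iu[0][o]], atlas.names[iu[1][o]], float(weights[o]))
            for o in order]


def top_edge_indices(smap: np.ndarray, k: int) -> list[tuple[int, int]]:
    """Index pairs of the k strongest canonical edges (same ordering rule)."""
    n = smap.shape[0]
    iu = np.triu_indices(n, k=1)
    order = np.argsort(-smap[iu], kind="stable")[:k]
    return [(int(iu[0][o]), int(iu[1][o])) for o in order]


def pooled_cv_saliency(oof_models, X, target: str = POSITIVE_LABEL,
                       mode: str = "gradient") -> np.ndarray:
    """Aggregate held-out saliency across CV folds.

    ``oof_models`` is a list of (fitted classifier, test-index array) pairs as
    returned by ``nested_cv(..., return_oof=True)``: each fold's model
    explains only that fold's held-out subjects, then everything is pooled
    and normalized once.
    """
    X = np.asarray(X, dtype=float)
    maps = [gradient_saliency(clf, X[i], target=target, mode=mode)
            for clf, te in oof_models for i in te]
    return aggregate_saliency(maps)
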