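"""Training protocol and evaluation: nested stratified cross-validation with
repeats, accuracy/sensitivity/specificity, ROC/AUC, and a label-permutation
significance test.

The protocol mirrors the study design: an outer stratified ten-fold split
scores every subject exactly once per repeat, an inner stratified split
selects the learning rate and L1 weight, and the whole procedure is repeated
(default 10 times) with fresh fold assignments before averaging.  The
hyperparameter search is pluggable; the default draws log-uniform candidates
at random.  All randomness (folds, init, search, permutations) derives from
one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .io import ConnectomeDataset, POSITIVE_LABEL
from .model import BrainNetGAClassifier, ModelConfig


@dataclass
class TrainConfig:
    """Optimization and protocol hyperparameters."""

    learning_rate: float = 1e-3
    l1_weight: float = 1e-5
    weight_decay: float = 0.0
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    outer_folds: int = 10
    inner_folds: int = 5
    repeats: int = 10
    search_budget: int = 1
    patience: int = 10

    def validate(self) -> None:
        if self.outer_folds < 2:
            raise ValueError("outer_folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class MetricsResult:
    """Percent-scale classification metrics plus the ROC curve."""

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    auc: float
    roc: np.ndarray  # (k, 2) array of (fpr, tpr) vertices
    per_fold: list = field(default_factory=list)


@dataclass
class PermutationResult:
    observed_stat: float
    null_stats: np.ndarray
    p_value: float


def _derived_seed(master: int, *tags: int) -> int:
    """Deterministic child seed, kept below 2**31."""
    return int(np.random.SeedSequence([master, *tags]).generate_state(1)[0] % (2 ** 31))


def _as_xy(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, ConnectomeDataset):
        return data.to_arrays()
    X, y = data
    return np.asarray(X, dtype=float), np.asarray(y)


def compute_metrics(y_true, y_pred, pos_label: str = POSITIVE_LABEL):
    """Accuracy, sensitivity, specificity in percent (positive class: SSD).

    With no positive (resp. negative) subjects in the truth, sensitivity
    (resp. specificity) is undefined and returned as None rather than 0.
    """
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.shape != y_pred.shape or len(y_true) < 1:
        raise ValueError("predictions and truth must have equal nonzero length")
    pos = y_true == pos_label
    tp = int(np.sum(pos & (y_pred == pos_label)))
    tn = int(np.sum(~pos & (y_pred != pos_label)))
    fn = int(pos.sum()) - tp
    fp = int((~pos).sum()) - tn
    accuracy = 100.0 * (tp + tn) / len(y_true)
    sensitivity = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    specificity = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else None
    return accuracy, sensitivity, specificity


def roc_auc(scores, y_true, pos_label: str = POSITIVE_LABEL):
    """AUC by pair counting (ties count 1/2) plus empirical ROC vertices.

    The pair-counting value equals the trapezoidal area under the returned
    curve; the rank formulation makes that exact rather than approximate.
    """
    scores, y_true = np.asarray(scores, dtype=float), np.asarray(y_true)
    pos = y_true == pos_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC/AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(y_true, scores, pos_label=pos_label,
                            drop_intermediate=False)
    return float(auc), np.column_stack([fpr, tpr])


def train(data, model_cfg: ModelConfig, train_cfg: TrainConfig,
          validation_data=None):
    """Fit one classifier on a dataset; returns (estimator, loss history)."""
    X, y = _as_xy(data)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    clf = _estimator(model_cfg, train_cfg, seed=train_cfg.seed)
    clf.fit(X, y, validation_data=validation_data, patience=train_cfg.patience)
    return clf, clf.history_


def _estimator(model_cfg: ModelConfig, train_cfg: TrainConfig,
               seed: int, lr: float | None = None,
               l1: float | None = None) -> BrainNetGAClassifier:
    return BrainNetGAClassifier(
        n_stages=model_cfg.n_stages, conv_channels=model_cfg.conv_channels,
        e2e_channels=model_cfg.e2e_channels, n_e2e_layers=model_cfg.n_e2e_layers,
        n2g_hidden=model_cfg.n2g_hidden, variant=model_cfg.variant,
        dropout=model_cfg.dropout,
        learning_rate=train_cfg.learning_rate if lr is None else lr,
        l1=train_cfg.l1_weight if l1 is None else l1,
        weight_decay=train_cfg.weight_decay, epochs=train_cfg.epochs,
        batch_size=train_cfg.batch_size, random_state=seed)


def random_log_uniform_search(rng: np.random.Generator, budget: int,
                              lr_range=(1e-4, 1e-2),
                              l1_range=(1e-6, 1e-3)) -> list[dict]:
    """Default hyperparameter search: log-uniform random candidates."""
    out = []
    for _ in range(budget):
        out.append({
            "learning_rate": float(np.exp(rng.uniform(*np.log(lr_range)))),
            "l1": float(np.exp(rng.uniform(*np.log(l1_range)))),
        })
    return out


def _select_hyperparams(X, y, model_cfg, train_cfg, seed, search):
    """Inner stratified CV over candidate (lr, l1); returns the best pair."""
    if train_cfg.search_budget <= 1:
        return train_cfg.learning_rate, train_cfg.l1_weight
    rng = np.random.default_rng(seed)
    candidates = search(rng, train_cfg.search_budget)
    inner = StratifiedKFold(n_splits=train_cfg.inner_folds, shuffle=True,
                            random_state=seed % (2 ** 31))
    best_acc, best = -1.0, candidates[0]
    for cand in candidates:
        accs = []
        for tr, va in inner.split(X, y):
            clf = _estimator(model_cfg, train_cfg, seed=seed,
                             lr=cand["learning_rate"], l1=cand["l1"])
            clf.fit(X[tr], y[tr], validation_data=(X[va], y[va]),
                    patience=train_cfg.patience)
            accs.append(np.mean(clf.predict(X[va]) == y[va]))
        acc = float(np.mean(accs))
        if acc > best_acc:
            best_acc, best = acc, cand
    return best["learning_rate"], best["l1"]


def nested_cv(data, model_cfg: ModelConfig, train_cfg: TrainConfig,
              search=random_log_uniform_search,
              return_oof: bool = False) -> MetricsResult:
    """Nested stratified cross-validation, repeated with fresh folds.

    Every subject is scored exactly once per repeat by a model that never saw
    it; hyperparameters are chosen on each outer-training portion only.
    Reported accuracy/sensitivity/specificity are means over folds and
    repeats; AUC is the mean over repeats of the AUC of pooled out-of-fold
    scores, and the returned ROC curve pools all repeats.
    """
    train_cfg.validate()
    X, y = _as_xy(data)
    if len(y) < train_cfg.outer_folds:
        raise ValueError(f"need at least outer_folds={train_cfg.outer_folds} subjects")
    per_fold = []
    all_scores, all_truth = [], []
    repeat_aucs = []
    oof_models = []  # (model, test indices) per fold, for saliency pooling
    for rep in range(train_cfg.repeats):
        fold_seed = _derived_seed(train_cfg.seed, 1, rep)
        outer = StratifiedKFold(n_splits=train_cfg.outer_folds, shuffle=True,
                                random_state=fold_seed)
        rep_scores = np.empty(len(y))
        for k, (tr, te) in enumerate(outer.split(X, y)):
            sub_seed = _derived_seed(train_cfg.seed, 2, rep, k)
            lr, l1 = _select_hyperparams(X[tr], y[tr], model_cfg, train_cfg,
                                         sub_seed, search)
            clf = _estimator(model_cfg, train_cfg, seed=sub_seed, lr=lr, l1=l1)
            clf.fit(X[tr], y[tr])
            pred = clf.predict(X[te])
            rep_scores[te] = clf.decision_function(X[te])
            acc, sens, spec = compute_metrics(y[te], pred)
            per_fold.append({"repeat": rep, "fold": k, "accuracy": acc,
                             "sensitivity": sens, "specificity": spec,
                             "lr": lr, "l1": l1, "test_idx": te})
            if return_oof:
                oof_models.append((clf, te))
        auc_rep, _ = roc_auc(rep_scores, y)
        repeat_aucs.append(auc_rep)
        all_scores.append(rep_scores)
        all_truth.append(y)
    scores_pool = np.concatenate(all_scores)
    truth_pool = np.concatenate(all_truth)
    _, roc_points = roc_auc(scores_pool, truth_pool)
    result = MetricsResult(
        accuracy=float(np.mean([f["accuracy"] for f in per_fold])),
        sensitivity=_nanmean([f["sensitivity"] for f in per_fold]),
        specificity=_nanmean([f["specificity"] for f in per_fold]),
        auc=100.0 * float(np.mean(repeat_aucs)),
        roc=roc_points, per_fold=per_fold)
    if return_oof:
        return result, oof_models
    return result


def _nanmean(values) -> float | None:
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else None


def cv_accuracy(X, y, model_cfg: ModelConfig, train_cfg: TrainConfig,
                seed: int) -> float:
    """Mean accuracy of one stratified CV pass (no inner search) — the
    permutation-test statistic."""
    outer = StratifiedKFold(n_splits=train_cfg.outer_folds, shuffle=True,
                            random_state=seed % (2 ** 31))
    accs = []
    for k, (tr, te) in enumerate(outer.split(X, y)):
        clf = _estimator(model_cfg, train_cfg, seed=_derived_seed(seed, 3, k))
        clf.fit(X[tr], y[tr])
        acc, _, _ = compute_metrics(y[te], clf.predict(X[te]))
        accs.append(acc)
    return float(np.mean(accs))


def permutation_test(data, model_cfg: ModelConfig, train_cfg: TrainConfig,
                     n_perm: int = 100) -> PermutationResult:
    """Label-permutation significance test for the CV accuracy.

    Null replicates shuffle the labels once (seeded) before the CV split;
    ``p = (1 + #{null >= observed}) / (1 + n_perm)``, never smaller than
    ``1/(n_perm+1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X, y = _as_xy(data)
    observed = cv_accuracy(X, y, model_cfg, train_cfg,
                           seed=_derived_seed(train_cfg.seed, 4))
    null_stats = np.empty(n_perm)
    for k in range(n_perm):
        rng = np.random.default_rng(_derived_seed(train_cfg.seed, 5, k))
        y_perm = y[rng.permutation(len(y))]
        null_stats[k] = cv_accuracy(X, y_perm, model_cfg, train_cfg,
                                    seed=_derived_seed(train_cfg.seed, 6, k))
    p = (1.0 + float(np.sum(null_stats >= observed))) / (1.0 + n_perm)
    return PermutationResult(observed_stat=observed, null_stats=null_stats,
                             p_value=p)
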