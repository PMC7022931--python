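"""Validation statistics for two-class longitudinal models.

Leave-one-pair-out cross-validation (LPOCV) holds out every ordered
(positive, negative) sample pair once; the conditional expected AUC is
the fraction of held-out pairs the refitted model ranks correctly,

    A_hat = 1/(|X+||X-|) sum_{i in X+} sum_{j in X-}
            H(f_-{i,j}(x_i) - f_-{i,j}(x_j)),

with the Heaviside step taking H(0) = 1/2 so tied scores count half (the
standard AUC tie convention).  The discriminant Q^2 is a cross-validated
R^2 that does not penalize predictions beyond the class label: squared
errors are accumulated only for class +1 samples predicted below +1 and
class -1 samples predicted above -1.

Stratified k-fold splitting (a sample-efficient generalization of LPOCV)
partitions each class into k folds and joins one fold per class, so every
test set has roughly the class proportions of the full sample set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .data import LongitudinalDataset

__all__ = [
    "EvaluationReport",
    "lpocv_pairs",
    "ce_auc",
    "dq2",
    "accuracy_nmc",
    "stratified_kfold",
    "pooled_auc",
    "evaluate_longitudinal",
]

# trainer contract: trainer(X_train, y_train) -> scorer; scorer(X_test) -> scores
Trainer = Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]]


def _heaviside(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, np.where(x == 0, 0.5, 0.0))


def lpocv_pairs(labels: Sequence[int]) -> list[tuple[int, int]]:
    """All (positive index, negative index) pairs, positive-major order."""
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == -1)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return [(int(i), int(j)) for i in pos for j in neg]


def ce_auc(X: np.ndarray, y: Sequence[int], trainer: Trainer) -> float:
    """Conditional expected AUC by leave-one-pair-out cross-validation.

    ``X`` is (d variables, n samples); ``trainer`` must be deterministic
    given its training data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    pairs = lpocv_pairs(y)
    n = X.shape[1]
    total = 0.0
    for i, j in pairs:
        keep = np.setdiff1d(np.arange(n), [i, j])
        scorer = trainer(X[:, keep], y[keep])
        s = scorer(X[:, [i, j]])
        total += float(_heaviside(np.asarray([s[0] - s[1]]))[0])
    return total / len(pairs)


def dq2(y: Sequence[int], y_hat: Sequence[float]) -> float:
    """Discriminant Q^2 = 1 - PRESSD / TSS.

    PRESSD ignores predictions beyond the class label (above +1 for class
    +1, below -1 for class -1); TSS is the total sum of squares of y about
    its mean.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have the same length")
    if not np.isin(y, (-1, 1)).all():
        raise ValueError("y must be -1 or +1")
    tss = float(np.square(y - y.mean()).sum())
    if tss == 0:
        raise ValueError("single-class y: TSS is zero")
    err = y - y_hat
    penalized = ((y == 1) & (y_hat < 1)) | ((y == -1) & (y_hat > -1))
    pressd = float(np.square(err[penalized]).sum())
    return 1.0 - pressd / tss


def accuracy_nmc(y: Sequence[int], y_hat_labels: Sequence[int]) -> tuple[float, int]:
    """(accuracy, number of misclassified samples)."""
    y = np.asarray(y)
    y_hat_labels = np.asarray(y_hat_labels)
    if y.shape != y_hat_labels.shape:
        raise ValueError("y and y_hat_labels must have the same length")
    nmc = int((y != y_hat_labels).sum())
    return 1.0 - nmc / len(y), nmc


def stratified_kfold(labels: Sequence[int], k: int, seed: int) -> list[np.ndarray]:
    """k disjoint test folds, one randomly drawn fold per class each.

    Every fold's class proportions match the full set to within one sample
    per class; the permutation is driven entirely by ``seed``.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    per_class_chunks = {}
    for cls in (1, -1):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls} has {len(idx)} samples, fewer than k={k}")
        rng.shuffle(idx)
        per_class_chunks[cls] = np.array_split(idx, k)
    folds = [
        np.sort(np.concatenate([per_class_chunks[1][f], per_class_chunks[-1][f]]))
        for f in range(k)
    ]
    return folds


def pooled_auc(y: Sequence[int], scores: Sequence[float]) -> float:
    """AUC of pooled out-of-sample scores over all positive-negative pairs,
    with ties counting one half."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y == 1]
    neg = scores[y == -1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    diff = pos[:, None] - neg[None, :]
    return float(_heaviside(diff).mean())


@dataclass
class EvaluationReport:
    """Cross-validated statistics per time point, with the pooled
    out-of-sample predictions they were computed from."""

    time_ids: list[str]
    ce_auc: np.ndarray  # (T,)
    dq2: np.ndarray  # (T,)
    acc: np.ndarray  # (T,)
    nmc: np.ndarray  # (T,) int
    y_true: list[np.ndarray]  # pooled labels per time point
    y_score: list[np.ndarray]  # pooled continuous predictions per time point
    cv: str = ""

    def metric(self, name: str) -> np.ndarray:
        values = {"ce_auc": self.ce_auc, "dq2": self.dq2, "acc": self.acc, "nmc": self.nmc}
        if name not in values:
            raise KeyError(f"unknown metric {name!r}; choose from {sorted(values)}")
        return values[name]


def evaluate_longitudinal(
    dataset: LongitudinalDataset,
    fit_fn,
    cv: str = "stratified:10",
    seed: int = 0,
) -> EvaluationReport:
    """Cross-validate a longitudinal fitting procedure.

    ``fit_fn(train_dataset)`` must return an object with
    ``decision_scores(X_raw, t)`` (e.g. a :class:`~gnnr.regression.FitResult`);
    any preprocessing (standardization) must happen inside the fit so no
    information leaks from the test fold.

    ``cv`` is ``"stratified:<k>"`` (each sample predicted once; CE_AUC is
    the pooled-pair AUC of the out-of-sample scores) or ``"lpocv"``
    (CE_AUC from same-model held-out pair comparisons; DQ2/ACC/NMC from
    the pooled per-pair predictions).
    """
    if dataset.labels.ndim != 1:
        raise ValueError("cross-validation requires shared (longitudinal) labels")
    labels = dataset.labels
    n, T = dataset.n_samples, dataset.n_timepoints
    y_true = [[] for _ in range(T)]
    y_score = [[] for _ in range(T)]

    if cv == "lpocv":
        pairs = lpocv_pairs(labels)
        wins = np.zeros(T)
        for i, j in pairs:
            keep = np.setdiff1d(np.arange(n), [i, j])
            fit = fit_fn(dataset.subset_samples(keep))
            for t in range(T):
                s = fit.decision_scores(dataset.cube[:, [i, j], t], t)
                wins[t] += float(_heaviside(np.asarray([s[0] - s[1]]))[0])
                y_true[t].extend([labels[i], labels[j]])
                y_score[t].extend([s[0], s[1]])
        auc = wins / len(pairs)
    elif cv.startswith("stratified:"):
        k = int(cv.split(":", 1)[1])
        for fold in stratified_kfold(labels, k, seed):
            keep = np.setdiff1d(np.arange(n), fold)
            fit = fit_fn(dataset.subset_samples(keep))
            for t in range(T):
                s = fit.decision_scores(dataset.cube[:, fold, t], t)
                y_true[t].extend(labels[fold])
                y_score[t].extend(s)
        auc = None
    else:
        raise ValueError(f"unknown cv scheme {cv!r}")

    y_true = [np.asarray(v) for v in y_true]
    y_score = [np.asarray(v, dtype=float) for v in y_score]
    if auc is None:
        auc = np.array([pooled_auc(y_true[t], y_score[t]) for t in range(T)])
    dq2_v = np.array([dq2(y_true[t], y_score[t]) for t in range(T)])
    acc_nmc = [accuracy_nmc(y_true[t], np.where(y_score[t] >= 0, 1, -1)) for t in range(T)]
    return EvaluationReport(
        time_ids=list(dataset.time_ids),
        ce_auc=np.asarray(auc, dtype=float),
        dq2=dq2_v,
        acc=np.array([a for a, _ in acc_nmc]),
        nmc=np.array([m for _, m in acc_nmc], dtype=int),
        y_true=y_true,
        y_score=y_score,
        cv=cv,
    )
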