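"""Validation statistics: LPOCV pairs, CE_AUC, DQ2, ACC/NMC, stratified folds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from gnnr import (
    accuracy_nmc,
    ce_auc,
    dq2,
    lpocv_pairs,
    pooled_auc,
    stratified_kfold,
)


# --- LPOCV pairs -----------------------------------------------------------


@pytest.mark.parametrize(
    "labels, n_pairs",
    [([1, 1, -1], 2), ([1, -1], 1), ([1] * 8 + [-1] * 8, 64)],
)
def test_pair_counts(labels, n_pairs):
    assert len(lpocv_pairs(labels)) == n_pairs


def test_pairs_positive_major_order():
    pairs = lpocv_pairs([1, -1, 1, -1])
    assert pairs == [(0, 1), (0, 3), (2, 1), (2, 3)]


def test_pairs_require_both_classes():
    with pytest.raises(ValueError):
        lpocv_pairs([1, 1, 1])


# --- CE_AUC ----------------------------------------------------------------


def _mean_difference_trainer(X, y):
    """Deterministic linear trainer: score along the class-mean difference."""
    w = X[:, y == 1].mean(axis=1) - X[:, y == -1].mean(axis=1)
    return lambda Xt: w @ Xt


def test_ce_auc_perfect_separation_is_one():
    X = np.array([[10.0, 11.0, 12.0, -10.0, -11.0, -12.0]])
    y = np.array([1, 1, 1, -1, -1, -1])
    assert ce_auc(X, y, _mean_difference_trainer) == 1.0


def test_ce_auc_constant_scores_is_half():
    X = np.random.default_rng(0).normal(size=(3, 6))
    y = np.array([1, 1, 1, -1, -1, -1])
    constant = lambda X_, y_: (lambda Xt: np.zeros(Xt.shape[1]))
    assert ce_auc(X, y, constant) == 0.5


def test_ce_auc_matches_brute_force_enumeration():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(3, 4))
    y = np.array([1, 1, -1, -1])
    got = ce_auc(X, y, _mean_difference_trainer)
    # independent enumeration of the four held-out pairs
    total = 0.0
    for i in (0, 1):
        for j in (2, 3):
            keep = [k for k in range(4) if k not in (i, j)]
            w = X[:, keep][:, np.array(y)[keep] == 1].mean(axis=1) - X[:, keep][
                :, np.array(y)[keep] == -1
            ].mean(axis=1)
            diff = w @ X[:, i] - w @ X[:, j]
            total += 1.0 if diff > 0 else (0.5 if diff == 0 else 0.0)
    assert got == pytest.approx(total / 4)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_ce_auc_antisymmetric_under_class_swap_with_negated_scores(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(4, 8))
    y = np.array([1, 1, 1, 1, -1, -1, -1, -1])
    w = rng.normal(size=4)  # fixed scoring direction, independent of labels
    fixed = lambda X_, y_: (lambda Xt: w @ Xt)
    a = ce_auc(X, y, fixed)
    # swapping the classes reverses every held-out pair comparison
    b = ce_auc(X, -y, fixed)
    assert a + b == pytest.approx(1.0)
    # equivalently, negating the scores under the original labels
    negated = lambda X_, y_: (lambda Xt: -(w @ Xt))
    assert ce_auc(X, y, negated) == pytest.approx(b)


# --- DQ2 -------------------------------------------------------------------


@pytest.mark.parametrize(
    "y, y_hat, expected",
    [
        ([1, -1], [1.5, -2.0], 1.0),  # beyond-label predictions are not penalized
        ([1, -1], [0.0, 0.0], 0.0),  # PRESSD = 2, TSS = 2
        ([1, 1, -1, -1], [0.5, 2.0, -0.5, -3.0], 0.875),  # PRESSD = 0.5, TSS = 4
    ],
)
def test_dq2_hand_examples(y, y_hat, expected):
    assert dq2(y, y_hat) == pytest.approx(expected)


def test_dq2_never_exceeds_one():
    rng = np.random.default_rng(0)
    for _ in range(20):
        y = rng.choice([-1, 1], size=10)
        if len(set(y)) < 2:
            continue
        assert dq2(y, rng.normal(size=10, scale=3)) <= 1.0


def test_dq2_single_class_raises():
    with pytest.raises(ValueError, match="TSS"):
        dq2([1, 1], [0.5, 0.5])


def test_dq2_constant_mean_predictor_on_balanced_labels():
    y = np.array([1, 1, -1, -1])
    # mean predictor 0: every prediction is inside the label, PRESSD = TSS
    assert dq2(y, np.zeros(4)) == pytest.approx(0.0)


# --- ACC / NMC -------------------------------------------------------------


@pytest.mark.parametrize(
    "y, yhat, expected",
    [
        ([1, -1, 1], [1, -1, 1], (1.0, 0)),
        ([1, -1], [-1, 1], (0.0, 2)),
        ([1, 1, -1, -1], [1, 1, -1, 1], (0.75, 1)),
    ],
)
def test_accuracy_nmc(y, yhat, expected):
    acc, nmc = accuracy_nmc(y, yhat)
    assert (acc, nmc) == (pytest.approx(expected[0]), expected[1])


# --- stratified k-fold -----------------------------------------------------


def test_stratified_balanced_50_50():
    labels = np.array([1] * 50 + [-1] * 50)
    folds = stratified_kfold(labels, k=10, seed=0)
    for fold in folds:
        assert (labels[fold] == 1).sum() == 5
        assert (labels[fold] == -1).sum() == 5


def test_stratified_10_10_k10():
    labels = np.array([1] * 10 + [-1] * 10)
    for fold in stratified_kfold(labels, k=10, seed=3):
        assert len(fold) == 2 and set(labels[fold]) == {1, -1}


def test_stratified_determinism():
    labels = np.array([1] * 12 + [-1] * 8)
    a = stratified_kfold(labels, 4, seed=42)
    b = stratified_kfold(labels, 4, seed=42)
    assert all(np.array_equal(x, y) for x, y in zip(a, b))


def test_stratified_small_class_raises():
    with pytest.raises(ValueError, match="fewer than k"):
        stratified_kfold([1, 1, 1, -1, -1], k=3, seed=0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    n_pos=st.integers(4, 20),
    n_neg=st.integers(4, 20),
    k=st.integers(2, 4),
    seed=st.integers(0, 1000),
)
def test_stratified_folds_partition_with_proportion_bound(n_pos, n_neg, k, seed):
    labels = np.array([1] * n_pos + [-1] * n_neg)
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    folds = stratified_kfold(labels, k, seed)
    everything = np.concatenate(folds)
    assert len(everything) == len(labels)
    assert len(np.unique(everything)) == len(labels)  # disjoint and exhaustive
    for cls, n_cls in ((1, n_pos), (-1, n_neg)):
        per_fold = [(labels[f] == cls).sum() for f in folds]
        assert max(per_fold) - min(per_fold) <= 1  # within one sample per class


# --- pooled AUC cross-check ------------------------------------------------


@pytest.mark.parametrize("seed", range(5))
def test_pooled_auc_matches_sklearn(seed):
    rng = np.random.default_rng(seed)
    y = rng.choice([-1, 1], size=30)
    if len(set(y)) < 2:
        y[0] = -y[1]
    s = rng.normal(size=30)
    assert pooled_auc(y, s) == pytest.approx(roc_auc_score(y, s))
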