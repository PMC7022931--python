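"""Solver correctness: penalty terms, reweighting, fixed point, limits."""

from dataclasses import replace

import numpy as np
import pytest
import scipy.linalg

from gnnr import (
    LongitudinalDataset,
    RegularizationConfig,
    fit_gnnr,
    fit_lfs,
    gnnr_objective,
    group_norm,
    init_coefficients,
    nuclear_norm,
    predict,
    reweight_D,
    reweight_Dtilde,
    stationarity_residual,
)
from gnnr.regression import SolverError

from conftest import random_dataset


# --- penalty terms ---------------------------------------------------------


@pytest.mark.parametrize(
    "B, expected",
    [
        ([[3.0, 4.0], [0.0, 0.0]], 5.0),
        (np.zeros((3, 2)), 0.0),
        (np.eye(2), 2.0),
    ],
)
def test_group_norm_examples(B, expected):
    assert group_norm(np.asarray(B)) == pytest.approx(expected)


@pytest.mark.parametrize(
    "B, expected",
    [
        ([[3.0, 0.0], [0.0, 4.0]], 7.0),
        ([[1.0, 1.0], [1.0, 1.0]], 2.0),
    ],
)
def test_nuclear_norm_examples(B, expected):
    assert nuclear_norm(np.asarray(B)) == pytest.approx(expected)


@pytest.mark.parametrize("seed", range(5))
def test_nuclear_norm_matches_svd_oracle(seed):
    B = np.random.default_rng(seed).normal(size=(6, 4))
    oracle = scipy.linalg.svdvals(B).sum()  # independent LAPACK route
    assert nuclear_norm(B) == pytest.approx(oracle, rel=1e-10)


def test_norms_reject_non_finite():
    with pytest.raises(ValueError):
        group_norm(np.array([[np.inf, 0.0]]))
    with pytest.raises(ValueError):
        nuclear_norm(np.array([[np.nan, 0.0]]))


def test_objective_hand_toy():
    cube = np.stack(
        [
            np.array([[1.0, 0.0, 2.0], [0.0, 1.0, 1.0]]),
            np.array([[1.0, 1.0, 0.0], [2.0, 0.0, 1.0]]),
        ],
        axis=2,
    )
    ds = LongitudinalDataset(cube=cube, labels=np.array([1, -1, 1]))
    B = np.array([[0.5, -1.0], [0.25, 2.0]])
    cfg = RegularizationConfig(gamma1=0.7, gamma2=0.3)
    # frozen from an independent element-by-element evaluation
    assert gnnr_objective(B, ds, cfg) == pytest.approx(6.469544389639594)
    # with B = 0 only the data term survives: 1/2 * sum_t ||y_t||^2 = 3
    assert gnnr_objective(np.zeros((2, 2)), ds, cfg) == pytest.approx(3.0)
    zero_pen = RegularizationConfig(gamma1=0.0, gamma2=0.0)
    assert gnnr_objective(B, ds, zero_pen) == pytest.approx(3.4375)


def test_objective_shape_mismatch():
    ds = random_dataset(0, d=3, n=4, T=2)
    with pytest.raises(ValueError, match="shape"):
        gnnr_objective(np.zeros((2, 2)), ds, RegularizationConfig())


# --- reweighting matrices --------------------------------------------------


def test_reweight_D_examples():
    B = np.array([[3.0, 4.0], [0.0, 0.0], [1.0, 1.0]])
    D = reweight_D(B, 1e-12)
    assert D[0, 0] == pytest.approx(0.1)  # 1/2 * (9 + 16)^(-1/2)
    assert D[1, 1] == pytest.approx(0.5e6)  # eps floor: 1/2 * (1e-12)^(-1/2)
    row = np.ones((1, 4))
    assert reweight_D(row, 1e-12)[0, 0] == pytest.approx(0.25)  # 1/2 * 4^(-1/2)
    assert np.count_nonzero(D - np.diag(np.diag(D))) == 0


def test_reweight_Dtilde_examples():
    Dt = reweight_Dtilde(2.0 * np.eye(2), 1e-12)
    np.testing.assert_allclose(Dt, 0.25 * np.eye(2), atol=1e-9)
    # zero matrix: pure eps floor, 1/2 * eps^(-1/2) * I
    Dt0 = reweight_Dtilde(np.zeros((3, 2)), 1e-8)
    np.testing.assert_allclose(Dt0, 0.5e4 * np.eye(3))
    # orthonormal columns scaled by s: on their span the weight is 1/(2s)
    s = 3.0
    B = s * np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
    Dt = reweight_Dtilde(B, 1e-14)
    np.testing.assert_allclose(Dt[:2, :2], np.eye(2) / (2 * s), atol=1e-6)
    # symmetric PSD by construction
    np.testing.assert_allclose(Dt, Dt.T)
    assert (np.linalg.eigvalsh(Dt) > 0).all()


# --- initialization --------------------------------------------------------


def test_init_scalar_orthogonal_response():
    # d=1, X=[1,1], y=[1,-1]: X y = 0, so ridge solution is 0 for any eps
    ds = LongitudinalDataset(cube=np.ones((1, 2, 1)), labels=np.array([1, -1]))
    B0 = init_coefficients(ds, ridge_eps=1e-10)
    assert B0[0, 0] == pytest.approx(0.0, abs=1e-12)


def test_init_orthonormal_rows_gives_Xy():
    q, _ = np.linalg.qr(np.random.default_rng(3).normal(size=(4, 4)))
    y = np.array([1, -1, 1, -1])
    ds = LongitudinalDataset(cube=q[:, :, None], labels=y)
    B0 = init_coefficients(ds, ridge_eps=1e-12)
    np.testing.assert_allclose(B0[:, 0], q @ y, atol=1e-8)


def test_init_finite_with_many_variables():
    ds = random_dataset(4, d=40, n=6, T=2)
    B0 = init_coefficients(ds)
    assert B0.shape == (40, 2)
    assert np.isfinite(B0).all()


# --- fitting ---------------------------------------------------------------


def _well_posed(seed=0, d=4, T=1):
    q, _ = np.linalg.qr(np.random.default_rng(seed).normal(size=(d, d)))
    y = np.tile([1, -1], d // 2)
    return LongitudinalDataset(cube=np.repeat(q[:, :, None], T, axis=2), labels=y), q, y


def test_unregularized_limit_is_least_squares():
    ds, q, y = _well_posed()
    cfg = RegularizationConfig(gamma1=0.0, gamma2=0.0, standardize=False)
    fit = fit_gnnr(ds, cfg)
    np.testing.assert_allclose(fit.B[:, 0], q @ y, atol=1e-10)
    assert fit.converged and fit.n_iter == 1


def test_unregularized_rank_deficient_raises():
    ds = random_dataset(1, d=20, n=5, T=1)  # d >> n: X X^T singular
    with pytest.raises(SolverError, match="regulariz"):
        fit_gnnr(ds, RegularizationConfig(gamma1=0.0, gamma2=0.0))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_lfs_equals_gnnr_with_zero_nuclear(seed):
    ds = random_dataset(seed, d=15, n=8, T=3)
    cfg = RegularizationConfig(gamma1=0.3, gamma2=0.0)
    a = fit_gnnr(ds, cfg)
    b = fit_lfs(ds, 0.3, cfg)
    np.testing.assert_allclose(a.B, b.B, atol=10 * cfg.tol)
    assert b.method == "lfs"


def test_huge_group_penalty_annihilates_coefficients():
    ds = random_dataset(2, d=10, n=8, T=2)
    cfg = RegularizationConfig(gamma1=1e6, max_iter=300)
    fit = fit_gnnr(ds, cfg)
    assert np.linalg.norm(fit.B, axis=1).max() < 1e-3
    # the solution beats the zero matrix on the smoothed objective it minimizes
    d, _, T = ds.cube.shape
    eps = cfg.eps_reweight
    at_zero = 0.5 * sum(
        np.square(ds.labels_at(t).astype(float)).sum() for t in range(T)
    ) + 0.5 * cfg.gamma1 * d * np.sqrt(eps) + 0.5 * cfg.gamma2 * min(d, T) * np.sqrt(eps)
    assert fit.objective_trace[-1] <= at_zero + 1e-9


@pytest.mark.parametrize("gamma1, gamma2", [(0.5, 0.0), (0.2, 0.3), (0.0, 0.4)])
def test_objective_trace_monotone(gamma1, gamma2):
    import warnings

    ds = random_dataset(5, d=12, n=9, T=3)
    cfg = RegularizationConfig(gamma1=gamma1, gamma2=gamma2, max_iter=400)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = fit_gnnr(ds, cfg)
    assert np.isfinite(fit.objective_trace).all()
    assert (np.diff(fit.objective_trace) <= 10 * cfg.tol).all()


def test_fixed_point_stationarity_at_convergence():
    ds = random_dataset(6, d=10, n=8, T=2)
    cfg = RegularizationConfig(gamma1=0.5, gamma2=0.0, max_iter=5000, tol=1e-8)
    fit = fit_gnnr(ds, cfg)
    assert fit.converged
    # residual of the stationarity system, D/D~ rebuilt from the final B
    scale = max(
        np.linalg.norm(ds.matrix_at(t) @ ds.labels_at(t)) for t in range(ds.n_timepoints)
    )
    assert stationarity_residual(fit, ds) < 100 * cfg.tol * max(1.0, scale)


@pytest.mark.parametrize("axis", ["gamma1", "gamma2"])
def test_shrinkage_monotone_along_penalty_ladder(axis):
    ds = random_dataset(8, d=12, n=9, T=3)
    ladder = [0.01, 0.1, 1.0, 10.0, 100.0]
    norms = []
    for g in ladder:
        cfg = RegularizationConfig(
            gamma1=g if axis == "gamma1" else 0.05,
            gamma2=g if axis == "gamma2" else 0.05,
            max_iter=500,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = fit_gnnr(ds, cfg)
        norms.append(group_norm(fit.B) if axis == "gamma1" else nuclear_norm(fit.B))
    assert all(b <= a + 1e-6 for a, b in zip(norms, norms[1:]))


def test_direct_and_lowrank_paths_agree(small_sim):
    ds, _ = small_sim
    cfg = RegularizationConfig(gamma1=0.3, gamma2=0.2, max_iter=40)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        a = fit_gnnr(ds, replace(cfg, solver="direct"))
        b = fit_gnnr(ds, replace(cfg, solver="lowrank"))
    np.testing.assert_allclose(a.B, b.B, atol=1e-9)


# --- prediction ------------------------------------------------------------


def test_predict_examples_and_tie_rule():
    B = np.zeros((3, 2))
    B[0, 1] = 1.0  # beta_2 = e1
    x = np.array([[5.0], [0.0], [0.0]])
    scores, labels = predict(B, x, 1)
    assert scores[0] == 5.0 and labels[0] == 1
    scores, labels = predict(np.zeros((3, 2)), x, 0)
    assert scores[0] == 0.0 and labels[0] == 1  # sign(0) = +1


def test_predict_shape_errors():
    with pytest.raises(ValueError, match="time index"):
        predict(np.zeros((3, 2)), np.zeros((3, 1)), 5)
    with pytest.raises(ValueError, match="variables"):
        predict(np.zeros((3, 2)), np.zeros((4, 1)), 0)


def test_config_validation():
    with pytest.raises(ValueError):
        RegularizationConfig(gamma1=-1.0)
    with pytest.raises(ValueError):
        RegularizationConfig(eps_reweight=0.0)
    with pytest.raises(ValueError):
        RegularizationConfig(max_iter=0)
    with pytest.raises(ValueError):
        RegularizationConfig(solver="admm")
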