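"""PLS-DA with VIP-score variable selection.

The cross-sectional baseline: a PLS1 regression of the class label
``y in {-1, +1}`` on the variables of a single time point, classified by
the sign of the continuous prediction.  Variable importance in projection
(VIP) summarizes each variable's contribution over the ``h`` latent
components,

    VIP_j = sqrt( p * sum_k SS_k (w_jk / ||w_k||)^2 / sum_k SS_k ),

with ``SS_k = b_k^2 t_k^T t_k`` the response variance captured by
component k; by construction the mean of the squared VIP scores is 1, so
``VIP > 1`` marks above-average contributors and the conventional
biomarker screen keeps variables with ``VIP > 2``.

The latent decomposition is delegated to scikit-learn's NIPALS
``PLSRegression``; this module owns the orientation (variables in rows),
bounds checking, the VIP computation and the classification rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression

__all__ = ["PLSModel", "fit_plsda", "vip_scores", "select_by_vip"]


@dataclass
class PLSModel:
    """Fitted PLS1 model in the quantities VIP needs.

    ``W`` (p x h) holds the unit-norm loading weights w_k, ``T_mat``
    (n x h) the scores t_k, and ``b`` (h,) the inner regression
    coefficients, so that the training prediction is
    ``y_hat = sum_k b_k t_k + y_mean``.
    """

    n_components: int
    W: np.ndarray
    T_mat: np.ndarray
    b: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    coef: np.ndarray  # (p,) regression vector on centered X (scaling absorbed)

    def decision_scores(self, X_new: np.ndarray) -> np.ndarray:
        """Continuous predictions for new samples (columns of X_new)."""
        X_new = np.asarray(X_new, dtype=float)
        return self.coef @ (X_new - self.x_mean[:, None]) + self.y_mean

    def predict(self, X_new: np.ndarray):
        """Scores and {-1, +1} labels (sign rule, sign(0) = +1)."""
        scores = self.decision_scores(X_new)
        return scores, np.where(scores >= 0, 1, -1)


def fit_plsda(X: np.ndarray, y: np.ndarray, h: int, scale: bool = False) -> PLSModel:
    """Fit a PLS-DA model on one time point.

    Parameters
    ----------
    X
        Matrix of shape (p variables, n samples).
    y
        Class labels in {-1, +1}, both classes present.
    h
        Number of latent components, ``1 <= h <= min(n - 1, p)``.
    scale
        Also unit-scale each variable (zero-variance columns get scale 1).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-d (variables x samples)")
    p, n = X.shape
    if y.shape != (n,):
        raise ValueError(f"y must have length n={n}")
    if not ((y == 1).any() and (y == -1).any()):
        raise ValueError("both classes must be present")
    if not 1 <= h <= min(n - 1, p):
        raise ValueError(f"h must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}], got {h}")

    pls = PLSRegression(n_components=h, scale=scale)
    with np.errstate(invalid="ignore"):  # constant columns handled by sklearn's guard
        pls.fit(X.T, y)
    W = pls.x_weights_  # (p, h), unit-norm columns
    T_mat = pls.x_scores_  # (n, h)
    b = pls.y_loadings_.ravel()  # (h,), y ~ T_mat @ b + y_mean
    return PLSModel(
        n_components=h,
        W=W,
        T_mat=T_mat,
        b=b,
        x_mean=np.asarray(pls._x_mean, dtype=float),
        x_scale=np.asarray(pls._x_std, dtype=float),
        y_mean=float(np.asarray(pls._y_mean).ravel()[0]),
        coef=pls.coef_.ravel(),  # prediction: coef @ (x - x_mean) + y_mean
    )


def vip_scores(model: PLSModel) -> np.ndarray:
    """VIP score per variable; mean of the squared scores is exactly 1."""
    W = model.W
    p = W.shape[0]
    ss = model.b**2 * (model.T_mat**2).sum(axis=0)  # SS(b_k t_k)
    total = ss.sum()
    if total <= 0:
        raise ValueError("degenerate fit: no component captures any response variance")
    wnorm2 = (W**2).sum(axis=0)
    wnorm2 = np.where(wnorm2 > 0, wnorm2, 1.0)
    contrib = (W**2 / wnorm2) @ ss
    return np.sqrt(p * contrib / total)


def select_by_vip(model: PLSModel, threshold: float = 2.0) -> np.ndarray:
    """Indices of variables with VIP strictly above ``threshold``, ascending."""
    vip = vip_scores(model)
    return np.flatnonzero(vip > threshold)
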