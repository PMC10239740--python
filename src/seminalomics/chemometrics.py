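"""Latent-variable modelling: PCA, NIPALS PLS1, OPLS-DA, DQ², LOO-CV.

The discriminant workflow follows standard chemometric practice for
two-class metabolomics: unit-variance scaled intensities are modelled
with orthogonal projections to latent structures (one predictive
component plus ``n_orth`` components orthogonal to the class vector),
and prediction quality is summarised by the discriminant Q² (DQ²) under
leave-one-out cross-validation. DQ² is the usual cross-validated Q²
except that residuals of predictions lying *beyond* their class label
(ŷ > +1 for the +1 class, ŷ < −1 for the −1 class) are zeroed, so a
confidently correct prediction is never penalised.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

from .normalize import UVScaler

_TOL = 1e-12
_MAX_ITER = 500


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------
@dataclass
class PcaResult:
    scores: np.ndarray            # samples x k
    loadings: np.ndarray          # variables x k, orthonormal columns
    explained_variance_pct: np.ndarray  # length k, % of total variance


def pca(X: np.ndarray, k: int) -> PcaResult:
    """First ``k`` principal components of the column-centered matrix.

    Computed by singular value decomposition; loadings are orthonormal
    and percentages are relative to the total variance, so they sum to
    100 over all possible components. ``k`` may not exceed the rank of
    the centered matrix.
    """
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank ({rank}) of the centered matrix")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-magnitude loading entry positive
    for j in range(len(s)):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    total = np.sum(s**2)
    pct = 100.0 * s[:k] ** 2 / total
    return PcaResult(
        scores=U[:, :k] * s[:k],
        loadings=Vt[:k].T,
        explained_variance_pct=pct,
    )


# ---------------------------------------------------------------------------
# NIPALS PLS1
# ---------------------------------------------------------------------------
class NipalsPLS(RegressorMixin, BaseEstimator):
    """PLS1 regression by the NIPALS algorithm.

    X and y are centered internally (training means are stored for
    prediction); scaling, when wanted, is applied by the caller so CV
    folds can refit it without leakage. Fitted attributes follow the
    standard decomposition X = T Pᵀ + E, y = T q + f with weights W;
    ``coef_`` maps centered X to centered ŷ (b = W (PᵀW)⁻¹ q).
    """

    def __init__(self, n_components: int = 1):
        self.n_components = n_components

    def fit(self, X, y) -> "NipalsPLS":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        a_max = self.n_components
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = y.mean()
        Xd = X - self.x_mean_
        yd = y - self.y_mean_
        rank = np.linalg.matrix_rank(Xd)
        if a_max > rank:
            raise ValueError(f"n_components={a_max} exceeds rank({rank}) of centered X")
        W = np.zeros((p, a_max))
        P = np.zeros((p, a_max))
        T = np.zeros((n, a_max))
        q = np.zeros(a_max)
        for a in range(a_max):
            w = Xd.T @ yd
            nw = np.linalg.norm(w)
            if nw < _TOL:
                raise ValueError("no covariance left to extract; reduce n_components")
            w /= nw
            t = Xd @ w
            tt = t @ t
            p_a = Xd.T @ t / tt
            q_a = (yd @ t) / tt
            Xd = Xd - np.outer(t, p_a)
            yd = yd - q_a * t
            W[:, a], P[:, a], T[:, a], q[a] = w, p_a, t, q_a
        self.x_weights_, self.x_loadings_, self.x_scores_, self.y_loadings_ = W, P, T, q
        self.coef_ = W @ np.linalg.solve(P.T @ W, q)
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_


def pls_fit(X, y, n_components: int) -> NipalsPLS:
    """Functional wrapper over :class:`NipalsPLS`."""
    return NipalsPLS(n_components=n_components).fit(X, y)


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------
class OPLSDA(ClassifierMixin, BaseEstimator):
    """Two-class OPLS-DA: ``n_orth`` orthogonal components + 1 predictive.

    Class labels are encoded −1/+1 in sorted label order (so the
    decision threshold is ŷ = 0). ``n_orth`` y-orthogonal components are
    stripped from centered X sequentially, then a single-component PLS
    is fitted on the filtered matrix. X is expected already scaled
    (UV-scaled in the standard workflow).

    Fitted attributes: ``w_pred_``/``p_pred_``/``t_pred_``/``q_`` for
    the predictive component, ``w_orth_``/``p_orth_``/``t_orth_``
    (columns = components) for the orthogonal part, and ``r2y_``, the
    fraction of class-vector variance explained on the training data.
    """

    def __init__(self, n_orth: int = 0):
        self.n_orth = n_orth

    def _encode(self, y) -> np.ndarray:
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"OPLS-DA needs exactly 2 classes, got {len(classes)}")
        self.classes_ = classes
        return np.where(np.asarray(y) == classes[1], 1.0, -1.0)

    def fit(self, X, y) -> "OPLSDA":
        if self.n_orth < 0:
            raise ValueError("n_orth must be >= 0")
        X = np.asarray(X, dtype=float)
        yv = self._encode(y)
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = yv.mean()
        Xd = X - self.x_mean_
        yc = yv - self.y_mean_
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw < _TOL:
            raise ValueError("class vector has no covariance with X")
        w /= nw
        p_feat = X.shape[1]
        W_o = np.zeros((p_feat, self.n_orth))
        P_o = np.zeros((p_feat, self.n_orth))
        T_o = np.zeros((len(X), self.n_orth))
        k_fit = 0
        for a in range(self.n_orth):
            t = Xd @ w
            p_vec = Xd.T @ t / (t @ t)
            w_o = p_vec - (w @ p_vec) * w
            n_wo = np.linalg.norm(w_o)
            if n_wo < 1e-10:
                break  # no orthogonal variation left
            w_o /= n_wo
            t_o = Xd @ w_o
            p_o = Xd.T @ t_o / (t_o @ t_o)
            Xd = Xd - np.outer(t_o, p_o)
            W_o[:, a], P_o[:, a], T_o[:, a] = w_o, p_o, t_o
            k_fit += 1
        self.w_orth_ = W_o[:, :k_fit]
        self.p_orth_ = P_o[:, :k_fit]
        self.t_orth_ = T_o[:, :k_fit]
        self.n_orth_ = k_fit
        # predictive component: 1-component PLS on the filtered matrix
        w_p = Xd.T @ yc
        w_p /= np.linalg.norm(w_p)
        t_p = Xd @ w_p
        tt = t_p @ t_p
        self.w_pred_ = w_p
        self.t_pred_ = t_p
        self.p_pred_ = Xd.T @ t_p / tt
        self.q_ = (yc @ t_p) / tt
        resid = yc - self.q_ * t_p
        self.r2y_ = 1.0 - (resid @ resid) / (yc @ yc)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Continuous prediction ŷ on the −1/+1 scale."""
        Xd = np.asarray(X, dtype=float) - self.x_mean_
        for a in range(self.n_orth_):
            t_o = Xd @ self.w_orth_[:, a]
            Xd = Xd - np.outer(t_o, self.p_orth_[:, a])
        return (Xd @ self.w_pred_) * self.q_ + self.y_mean_

    def predict(self, X) -> np.ndarray:
        yhat = self.decision_function(X)
        return np.where(yhat > 0, self.classes_[1], self.classes_[0])


def opls_da_fit(X, y, n_orth: int) -> OPLSDA:
    """Functional wrapper over :class:`OPLSDA`."""
    return OPLSDA(n_orth=n_orth).fit(X, y)


# ---------------------------------------------------------------------------
# DQ² and cross-validation
# ---------------------------------------------------------------------------
def dq2(y, yhat) -> float:
    """Discriminant Q² of ±1-coded labels against continuous predictions.

    Residuals of predictions beyond their class label (ŷ > +1 for
    y = +1, ŷ < −1 for y = −1) are set to zero before the usual
    1 − PRESS/TSS computation, so over-shooting a correct class is not
    penalised.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("y must be coded -1/+1")
    denom = np.sum((y - y.mean()) ** 2)
    if denom == 0:
        raise ValueError("all labels identical: DQ2 undefined")
    r = y - yhat
    r[(y > 0) & (yhat > 1.0)] = 0.0
    r[(y < 0) & (yhat < -1.0)] = 0.0
    return 1.0 - np.sum(r**2) / denom


@dataclass
class CvResult:
    """Leave-one-out summary: DQ², accuracy (%), per-sample predictions."""

    dq2y: float
    accuracy_cv: float
    yhat: np.ndarray


def loo_cv(X, y, n_orth: int, scale: bool = True) -> CvResult:
    """Leave-one-out OPLS-DA cross-validation.

    For each sample the scaler (optional) and model are refitted without
    it and it is predicted; DQ² and classification accuracy (sign of ŷ;
    exactly 0 counts as wrong) are assembled over all folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("need >= 2 samples in each of exactly 2 classes")
    yv = np.where(y == classes[1], 1.0, -1.0)
    n = len(y)
    yhat = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        if len(np.unique(yv[keep])) < 2:
            raise ValueError("a CV fold lost an entire class")
        Xtr, Xte = X[keep], X[i : i + 1]
        if scale:
            sc = UVScaler().fit(Xtr)
            Xtr, Xte = sc.transform(Xtr), sc.transform(Xte)
        model = OPLSDA(n_orth=n_orth).fit(Xtr, yv[keep])
        yhat[i] = model.decision_function(Xte)[0]
    acc = 100.0 * np.mean(np.sign(yhat) == yv)
    return CvResult(dq2y=dq2(yv, yhat), accuracy_cv=acc, yhat=yhat)


def select_n_orthogonal(
    X, y, max_orth: int, scale: bool = True, min_gain: float = 0.05
) -> int:
    """Orthogonal-component count selected by leave-one-out DQ².

    Components are added sequentially and the search stops at the first
    component whose incremental DQ² gain is not above ``min_gain`` — the
    usual significance margin for accepting a further latent variable.
    Under LOO, an extra orthogonal component yields a small chance-level
    gain (~0.02–0.03) even on data with no structured y-orthogonal
    variation, so a plain argmax systematically overfits the component
    count; ``min_gain=0`` recovers the argmax over the monotone-gain
    prefix (ties resolve toward fewer components). Deterministic for
    fixed input.
    """
    if max_orth < 0:
        raise ValueError("max_orth must be >= 0")
    best_k = 0
    best = loo_cv(X, y, 0, scale=scale).dq2y
    for k in range(1, max_orth + 1):
        v = loo_cv(X, y, k, scale=scale).dq2y
        if v <= best + min_gain:
            break
        best_k, best = k, v
    return best_k
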