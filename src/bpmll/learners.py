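"""Matrix-based multi-label learners: PLS regression, CCA, and ridge (LS-CCA).

All three share a fit/predict contract on a real feature matrix X (n x m)
and binary label matrix Y (n x k): fitting column-centres both matrices
(means are stored and restored at prediction), and prediction returns
real-valued position scores, never thresholded labels.  Determinism is
enforced by fixing the eigenvector sign convention (largest-magnitude
entry positive), so repeated fits are bit-stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

DEFAULT_N_COMPONENTS = 40
DEFAULT_RIDGE_LAMBDA = 0.01
DEFAULT_CCA_EPS = 1e-8
#: PLS deflation stops when the residual Frobenius norm falls below this
#: fraction of the initial one
PLS_DEFLATION_RTOL = 1e-10


class NumericalError(ArithmeticError):
    """Numerical failure (singularity, non-convergence)."""


def _fix_sign(p: np.ndarray, *companions):
    """Flip vector(s) so the largest-|.| entry of ``p`` is positive."""
    if p[np.argmax(np.abs(p))] < 0:
        return tuple(-v for v in (p, *companions))
    return (p, *companions)


def _center(X, Y):
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching row counts")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    return X - x_mean, Y - y_mean, x_mean, y_mean


# ---------------------------------------------------------------------------
# Partial least squares with deflation
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    P: np.ndarray        # m x tau projection weights (unit eigenvectors)
    R: np.ndarray        # k x tau regression loadings
    C: np.ndarray        # m x tau X-loadings (deflation directions)
    n_components: int
    x_mean: np.ndarray
    y_mean: np.ndarray


def pls_fit(X, Y, n_components: int = DEFAULT_N_COMPONENTS) -> PLSModel:
    """Fit PLS by iterative rank-one extraction and deflation.

    Each round takes p as the leading eigenvector of X^T Y Y^T X (computed
    as the leading left singular vector of X^T Y), forms the score u = X p,
    the loadings c = X^T u / ||u||^2 and r = Y^T u / ||u||^2, and deflates
    X by u c^T and Y by the regression residue Y - u r^T.  Deflation stops
    early once the residual X is numerically zero.
    """
    Xd, Yd, x_mean, y_mean = _center(X, Y)
    n, m = Xd.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(m, n):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_features={m}, n_samples={n})")
    x_norm0 = np.linalg.norm(Xd)
    if x_norm0 == 0:
        raise ValueError("X has zero variance; nothing to fit")

    P, R, C = [], [], []
    for _ in range(n_components):
        if np.linalg.norm(Xd) < PLS_DEFLATION_RTOL * x_norm0:
            break
        A = Xd.T @ Yd  # m x k cross-covariance
        U, s, Vt = scipy.linalg.svd(A, full_matrices=False)
        if s[0] <= PLS_DEFLATION_RTOL * max(1.0, x_norm0):
            break  # no remaining covariance with Y
        p, = _fix_sign(U[:, 0])
        u = Xd @ p
        uu = float(u @ u)
        if uu <= 0:
            break
        c = Xd.T @ u / uu
        r = Yd.T @ u / uu
        P.append(p)
        R.append(r)
        C.append(c)
        Xd = Xd - np.outer(u, c)
        Yd = Yd - np.outer(u, r)
    if not P:
        raise NumericalError("PLS extracted no components")
    return PLSModel(np.array(P).T, np.array(R).T, np.array(C).T,
                    len(P), x_mean, y_mean)


def pls_predict(model: PLSModel, X_new) -> np.ndarray:
    """Score new introns: centred X mapped through the fitted projection.

    Uses the corrected-weights form X P (C^T P)^{-1} R^T, which reduces to
    the plain X P R^T whenever the loadings are orthogonal to the weights
    (C^T P = I) and reproduces the training regression exactly in general.
    """
    X_new = np.asarray(X_new, dtype=np.float64)
    if X_new.ndim != 2 or X_new.shape[1] != model.P.shape[0]:
        raise ValueError(
            f"X_new must have {model.P.shape[0]} columns, got {X_new.shape}")
    Xc = X_new - model.x_mean
    T = model.C.T @ model.P  # unit-diagonal triangular
    coef = model.P @ scipy.linalg.solve(T, model.R.T)
    return Xc @ coef + model.y_mean


# ---------------------------------------------------------------------------
# Canonical correlation analysis
# ---------------------------------------------------------------------------

@dataclass
class CCAModel:
    P: np.ndarray          # m x tau canonical weights for X
    Q: np.ndarray          # k x tau canonical weights for Y
    eigvals: np.ndarray    # squared canonical correlations, descending
    ridge_eps: float
    x_mean: np.ndarray
    y_mean: np.ndarray


def _inv_sqrt(S: np.ndarray, ridge_eps: float, label: str) -> np.ndarray:
    """Symmetric inverse square root of a ridged Gram matrix.

    With ridge_eps = 0 a singular matrix is an error; with a positive
    ridge the matrix is positive-definite by construction, so eigenvalues
    are floored at the ridge to absorb eigensolver rounding on exactly
    collinear (e.g. one-hot) feature blocks.
    """
    w, V = scipy.linalg.eigh(S)
    if ridge_eps > 0:
        w = np.maximum(w, ridge_eps)
    else:
        tiny = np.finfo(np.float64).eps * S.shape[0] * max(w.max(), 1.0)
        if w.min() <= tiny:
            raise NumericalError(
                f"{label} Gram matrix is singular (min eigenvalue {w.min():.3g}); "
                "pass a positive ridge_eps")
    return (V / np.sqrt(w)) @ V.T


def cca_fit(X, Y, n_components: int = None,
            ridge_eps: float = DEFAULT_CCA_EPS) -> CCAModel:
    """Fit CCA via the whitened cross-covariance SVD.

    Solves the paired eigenproblems of (X^T X)^-1 X^T Y (Y^T Y)^-1 Y^T X
    (and its Y-side twin) with ridge_eps added to both Gram matrices for
    invertibility; canonical pairs are ordered by descending eigenvalue.
    """
    Xc, Yc, x_mean, y_mean = _center(X, Y)
    m, k = Xc.shape[1], Yc.shape[1]
    tau = min(m, k) if n_components is None else n_components
    if not 1 <= tau <= min(m, k):
        raise ValueError(f"n_components must be in [1, {min(m, k)}]")
    if ridge_eps < 0:
        raise ValueError("ridge_eps must be >= 0")
    Sxx = Xc.T @ Xc + ridge_eps * np.eye(m)
    Syy = Yc.T @ Yc + ridge_eps * np.eye(k)
    Wx = _inv_sqrt(Sxx, ridge_eps, "X")
    Wy = _inv_sqrt(Syy, ridge_eps, "Y")
    U, s, Vt = scipy.linalg.svd(Wx @ (Xc.T @ Yc) @ Wy, full_matrices=False)
    P = Wx @ U[:, :tau]
    Q = Wy @ Vt[:tau].T
    for i in range(tau):  # deterministic sign: flip each pair together
        P[:, i], Q[:, i] = _fix_sign(P[:, i], Q[:, i])
    return CCAModel(P, Q, s[:tau] ** 2, ridge_eps, x_mean, y_mean)


def cca_predict(model: CCAModel, X_new) -> np.ndarray:
    """Score via Y_pred = X_new P Q^{-1}: exact inverse when Q is square,
    minimum-norm pseudo-inverse otherwise."""
    X_new = np.asarray(X_new, dtype=np.float64)
    if X_new.ndim != 2 or X_new.shape[1] != model.P.shape[0]:
        raise ValueError(
            f"X_new must have {model.P.shape[0]} columns, got {X_new.shape}")
    Xc = X_new - model.x_mean
    k, tau = model.Q.shape
    Qinv = scipy.linalg.inv(model.Q) if tau == k else scipy.linalg.pinv(model.Q)
    return Xc @ model.P @ Qinv + model.y_mean


# ---------------------------------------------------------------------------
# Ridge regression (the LS-CCA objective in closed form)
# ---------------------------------------------------------------------------

@dataclass
class RidgeModel:
    W: np.ndarray        # m x k coefficients
    lam: float
    x_mean: np.ndarray
    y_mean: np.ndarray


def ridge_fit(X, Y, lam: float = DEFAULT_RIDGE_LAMBDA) -> RidgeModel:
    """Minimise sum_j ||X W_j - Y_j||^2 + lam ||W_j||^2 in closed form."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    Xc, Yc, x_mean, y_mean = _center(X, Y)
    m = Xc.shape[1]
    W = scipy.linalg.solve(Xc.T @ Xc + lam * np.eye(m), Xc.T @ Yc,
                           assume_a="pos")
    if not np.all(np.isfinite(W)):
        raise NumericalError("ridge solution is non-finite")
    return RidgeModel(W, lam, x_mean, y_mean)


def ridge_predict(model: RidgeModel, X_new) -> np.ndarray:
    X_new = np.asarray(X_new, dtype=np.float64)
    if X_new.ndim != 2 or X_new.shape[1] != model.W.shape[0]:
        raise ValueError(
            f"X_new must have {model.W.shape[0]} columns, got {X_new.shape}")
    return (X_new - model.x_mean) @ model.W + model.y_mean


# ---------------------------------------------------------------------------
# Uniform learner interface used by the ensemble grid
# ---------------------------------------------------------------------------

class _Learner:
    """Thin fit/predict adapter with per-kind hyperparameters."""

    def __init__(self, kind: str, **params):
        if kind not in LEARNER_KINDS:
            raise ValueError(f"unknown learner kind {kind!r}")
        self.kind = kind
        self.params = params
        self.model = None

    def fit(self, X, Y) -> "_Learner":
        if self.kind == "PLS":
            tau = self.params.get("n_components", DEFAULT_N_COMPONENTS)
            tau = min(tau, min(np.shape(X)[1], np.shape(X)[0]))
            self.model = pls_fit(X, Y, n_components=tau)
        elif self.kind == "CCA":
            tau = self.params.get("n_components")
            if tau is not None:
                tau = min(tau, min(np.shape(X)[1], np.shape(Y)[1]))
            self.model = cca_fit(X, Y, n_components=tau,
                                 ridge_eps=self.params.get("ridge_eps", DEFAULT_CCA_EPS))
        else:  # LSCCA
            self.model = ridge_fit(X, Y, lam=self.params.get("lam", DEFAULT_RIDGE_LAMBDA))
        return self

    def predict(self, X_new) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("learner is not fitted")
        return _PREDICTORS[self.kind](self.model, X_new)


LEARNER_KINDS = ("PLS", "CCA", "LSCCA")
_PREDICTORS = {"PLS": pls_predict, "CCA": cca_predict, "LSCCA": ridge_predict}


def make_learner(kind: str, **params) -> _Learner:
    """Factory for the canonical learner kinds PLS / CCA / LSCCA."""
    return _Learner(kind, **params)
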