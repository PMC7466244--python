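"""Independent reference implementations used only to check the package.

These deliberately take different computational routes from the library:
the PLS1 oracle regresses on an explicitly orthogonalized Krylov basis
(no NIPALS deflation, no scores/loadings), and the Whittaker oracle
solves the dense normal equations with a generic solver (no banded
structure).
"""

from __future__ import annotations

import numpy as np


def pls1_oracle_coefs(X: np.ndarray, y: np.ndarray, A: int) -> np.ndarray:
    """PLS1 regression vector via the Krylov-space characterization.

    The A-component PLS1 solution is the least-squares fit of the
    centered response on the Krylov space
    span{X'y, (X'X)X'y, ..., (X'X)^{A-1} X'y} of the centered
    predictors, built here with repeated re-orthogonalization.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    Q = np.zeros((X.shape[1], A))
    v = Xc.T @ yc
    for a in range(A):
        for _ in range(2):
            v = v - Q[:, :a] @ (Q[:, :a].T @ v)
        Q[:, a] = v / np.linalg.norm(v)
        v = Xc.T @ (Xc @ Q[:, a])
    Z = Xc @ Q
    beta, *_ = np.linalg.lstsq(Z, yc, rcond=None)
    return Q @ beta


def pls1_oracle_predict(X_fit, y_fit, X_new, A) -> np.ndarray:
    b = pls1_oracle_coefs(X_fit, y_fit, A)
    return y_fit.mean() + (np.atleast_2d(X_new) - X_fit.mean(axis=0)) @ b


def whittaker_oracle(y: np.ndarray, w: np.ndarray, lam: float,
                     diff_order: int = 2) -> np.ndarray:
    """Dense-matrix solve of (W + lam D'D) z = W y."""
    y = np.asarray(y, dtype=float)
    n = y.size
    d = np.eye(n)
    for _ in range(diff_order):
        d = d[1:] - d[:-1]
    a = np.diag(np.asarray(w, dtype=float)) + lam * d.T @ d
    return np.linalg.solve(a, np.asarray(w, dtype=float) * y)


def ols_fit_predict(X_fit, y_fit, X_new) -> np.ndarray:
    """Ordinary least squares with intercept (lstsq route)."""
    A = np.column_stack([np.ones(len(X_fit)), X_fit])
    beta, *_ = np.linalg.lstsq(A, y_fit, rcond=None)
    return np.column_stack([np.ones(len(np.atleast_2d(X_new))),
                            np.atleast_2d(X_new)]) @ beta
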