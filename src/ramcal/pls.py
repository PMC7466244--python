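"""PLS1 regression by NIPALS with venetian-blinds cross-validation.

Partial least squares with a single response projects the (mean-centered)
predictor matrix onto latent variables that maximize covariance with the
response.  For one response the NIPALS recursion is non-iterative per
component:

    w_a = X'y / ||X'y||        (weight)
    t_a = X w_a                (score)
    p_a = X't_a / (t_a't_a)    (x-loading)
    q_a = y't_a / (t_a't_a)    (inner coefficient)
    X <- X - t_a p_a',  y <- y - q_a t_a   (deflation)

The regression vector at a components is B_a = W_a (P_a'W_a)^{-1} q_a,
accumulated here through the equivalent recursion on the "R" basis so
every intermediate B_a is stored.

Model-complexity selection uses venetian-blinds cross-validation: sample
i (in dataset order) belongs to fold i mod s, centering statistics are
recomputed on each training fold, and the chosen number of latent
variables is the smallest one whose RMSECV is within a parsimony
tolerance of the minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PLSModel", "RegressionMetrics", "CVResult", "fit_pls1", "predict",
    "venetian_blinds_indices", "cross_validate", "regression_metrics",
]


@dataclass
class PLSModel:
    """Centered PLS1 decomposition with per-component regression vectors.

    ``coefs`` has one column per component count a = 1..A, so column
    a-1 is the regression vector of the a-component model on centered
    data; predictions are y_mean + (X - x_mean) @ coefs[:, a-1].
    """

    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray        # weights, channels x A, unit columns
    P: np.ndarray        # x-loadings, channels x A
    T: np.ndarray        # scores, samples x A, mutually orthogonal
    q: np.ndarray        # inner coefficients, length A
    coefs: np.ndarray    # regression vectors, channels x A
    A: int

    @property
    def n_channels(self) -> int:
        return self.x_mean.size


@dataclass
class RegressionMetrics:
    r2: float
    rmse: float
    bias: float
    context: str = "calibration"


@dataclass
class CVResult:
    """Per-component-count CV metrics plus the chosen complexity."""

    rmsecv: np.ndarray        # length A_max
    r2cv: np.ndarray
    bias: np.ndarray
    chosen_A: int
    cv_predictions: np.ndarray  # samples x A_max out-of-fold predictions
    folds: np.ndarray

    def metrics_at(self, a: int) -> RegressionMetrics:
        return RegressionMetrics(float(self.r2cv[a - 1]), float(self.rmsecv[a - 1]),
                                 float(self.bias[a - 1]), "cross_validation")


def fit_pls1(X: np.ndarray, y: np.ndarray, A: int, center: bool = True) -> PLSModel:
    """Fit a PLS1 model with A latent variables by NIPALS.

    Raises if y has zero variance or A exceeds min(n-1, n_channels).
    If the predictor residual is exhausted before A components (exactly
    low-rank data), the model is truncated to the attainable rank.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, j = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on the number of samples")
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance")
    if not 1 <= A <= min(n - 1, j):
        raise ValueError(f"A must lie in [1, {min(n - 1, j)}]")

    x_mean = X.mean(axis=0) if center else np.zeros(j)
    y_mean = float(y.mean()) if center else 0.0
    Xd = X - x_mean
    yd = y - y_mean

    W = np.zeros((j, A))
    P = np.zeros((j, A))
    T = np.zeros((n, A))
    R = np.zeros((j, A))     # R = W (P'W)^{-1}, built recursively
    q = np.zeros(A)
    coefs = np.zeros((j, A))
    eps = np.finfo(float).eps
    scale = max(np.abs(Xd).max(), eps)

    a_used = 0
    for a in range(A):
        w = Xd.T @ yd
        wn = np.linalg.norm(w)
        if wn <= 1e-12 * scale * max(np.abs(yd).max(), eps) or wn == 0.0:
            break  # residual covariance exhausted
        w /= wn
        t = Xd @ w
        tt = float(t @ t)
        if tt <= eps * scale**2:
            break
        p = Xd.T @ t / tt
        q[a] = float(yd @ t) / tt
        W[:, a], P[:, a], T[:, a] = w, p, t
        r = w - R[:, :a] @ (P[:, :a].T @ w)
        R[:, a] = r
        coefs[:, a] = (coefs[:, a - 1] if a else 0.0) + q[a] * r
        Xd = Xd - np.outer(t, p)
        yd = yd - q[a] * t
        a_used = a + 1

    if a_used == 0:
        raise ValueError("no covariance between X and y (cannot fit)")
    if a_used < A:  # rank-deficient input: truncate
        W, P, T, q, coefs = (W[:, :a_used], P[:, :a_used], T[:, :a_used],
                             q[:a_used], coefs[:, :a_used])
    return PLSModel(x_mean, y_mean, W, P, T, q, coefs, a_used)


def predict(model: PLSModel, X: np.ndarray, a: int | None = None) -> np.ndarray:
    """Predict with the a-component model (default: all A components)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_channels:
        raise ValueError(
            f"channel mismatch: model has {model.n_channels}, X has {X.shape[1]}")
    a = model.A if a is None else a
    if not 1 <= a <= model.A:
        raise ValueError(f"a must lie in [1, {model.A}]")
    return model.y_mean + (X - model.x_mean) @ model.coefs[:, a - 1]


def venetian_blinds_indices(n: int, s: int) -> np.ndarray:
    """Deterministic interleaved fold assignment: sample i -> fold i mod s."""
    if not 2 <= s <= n:
        raise ValueError(f"splits must lie in [2, {n}]")
    return np.arange(n) % s


def regression_metrics(y_ref: np.ndarray, y_hat: np.ndarray,
                       context: str = "calibration") -> RegressionMetrics:
    """R^2, RMSE (ppm) and bias (mean signed error, ppm)."""
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y_ref.size == 0 or y_ref.size != y_hat.size:
        raise ValueError("y_ref and y_hat must be equal nonzero length")
    ss_tot = float(np.sum((y_ref - y_ref.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance in y_ref: R^2 undefined")
    err = y_hat - y_ref
    rmse = float(np.sqrt(np.mean(err**2)))
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    return RegressionMetrics(r2, rmse, float(err.mean()), context)


def cross_validate(X: np.ndarray, y: np.ndarray, A_max: int, s: int = 10,
                   tol_parsimony: float = 0.02, center: bool = True) -> CVResult:
    """Venetian-blinds cross-validation of PLS1 over a = 1..A_max.

    Each fold's model (including centering) is fit on the complement;
    out-of-fold predictions cover every sample exactly once.  chosen_A is
    the smallest a with RMSECV(a) <= (1 + tol_parsimony) * min RMSECV,
    favouring parsimonious models.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    folds = venetian_blinds_indices(n, s)
    min_train = min(int(np.sum(folds != f)) for f in range(s))
    if min_train < 2:
        raise ValueError("a fold has fewer than 2 training samples")
    if A_max > min(min_train - 1, X.shape[1]):
        raise ValueError(f"A_max too large for the smallest training fold "
                         f"(limit {min(min_train - 1, X.shape[1])})")
    preds = np.empty((n, A_max))
    for f in range(s):
        test = folds == f
        model = fit_pls1(X[~test], y[~test], A_max, center=center)
        for a in range(1, A_max + 1):
            # rank-truncated models repeat their last attainable column
            preds[test, a - 1] = predict(model, X[test], min(a, model.A))
    rmsecv = np.empty(A_max)
    r2cv = np.empty(A_max)
    bias = np.empty(A_max)
    for a in range(A_max):
        m = regression_metrics(y, preds[:, a], "cross_validation")
        rmsecv[a], r2cv[a], bias[a] = m.rmse, m.r2, m.bias
    chosen = int(np.argmax(rmsecv <= (1.0 + tol_parsimony) * rmsecv.min())) + 1
    return CVResult(rmsecv, r2cv, bias, chosen, preds, folds)
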