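"""Informative-variable selection for PLS1 calibration models.

Three per-channel importance measures:

* VIP — variable importance in projection: the weighted share of the
  explained response variance attributed to each channel; mean(VIP^2)
  is exactly 1, so the conventional cutoff VIP > 1 keeps channels with
  above-average influence.
* sMC — significance multivariate correlation: an F(1, n-2) test of
  each centered channel regressed on the PLS fitted response.
* Martens' uncertainty test — a segment-jackknife on the regression
  vector: the cross-validation sub-models give per-channel coefficient
  perturbations whose pooled variance yields a t-statistic per channel.

``select_and_refit`` applies one selection pass and refits/cross-
validates the model on the retained channels only (no iterative
elimination).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pls import PLSModel, cross_validate, fit_pls1, predict, venetian_blinds_indices

__all__ = ["SelectionResult", "vip_scores", "smc_scores",
           "martens_significance", "select_and_refit"]


@dataclass
class SelectionResult:
    method: str
    scores: np.ndarray      # importance per channel (VIP, F, or |t|)
    threshold: float        # cutoff actually applied
    selected: np.ndarray    # indices of retained channels
    n_selected: int


def vip_scores(model: PLSModel, a: int | None = None) -> np.ndarray:
    """VIP_j over the first ``a`` components (default: all).

    VIP_j = sqrt( J * sum_k ssy_k (w_jk/||w_k||)^2 / sum_k ssy_k ) with
    ssy_k = q_k^2 t_k't_k the response variance captured by component k.
    """
    a = model.A if a is None else a
    if not 1 <= a <= model.A:
        raise ValueError(f"a must lie in [1, {model.A}]")
    W = model.W[:, :a]
    ssy = model.q[:a] ** 2 * np.einsum("ij,ij->j", model.T[:, :a], model.T[:, :a])
    wn2 = (W / np.linalg.norm(W, axis=0)) ** 2
    j = W.shape[0]
    return np.sqrt(j * (wn2 @ ssy) / ssy.sum())


def smc_scores(model: PLSModel, X: np.ndarray, y: np.ndarray,
               alpha: float = 0.05) -> SelectionResult:
    """F-test of each centered channel against the PLS fitted response.

    For channel j, regress x_j (centered) on y_hat (centered):
    F_j = SS_regression / (SS_residual / (n-2)), compared with the
    F(1, n-2) critical value at ``alpha``.  A channel exactly
    proportional to y_hat has zero residual; its F is capped at a large
    finite value and flagged significant.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n <= 2:
        raise ValueError("need n > 2 samples for the sMC F-test")
    yhat = predict(model, X)
    yc = yhat - yhat.mean()
    ss_yhat = float(yc @ yc)
    Xc = X - X.mean(axis=0)
    if ss_yhat == 0:
        raise ValueError("fitted response has zero variance")
    beta = Xc.T @ yc / ss_yhat
    ss_reg = beta**2 * ss_yhat
    ss_tot = np.einsum("ij,ij->j", Xc, Xc)
    ss_res = np.maximum(ss_tot - ss_reg, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ss_reg / (ss_res / (n - 2))
    f = np.where(np.isfinite(f), f, np.float64(1e30))
    f = np.where((ss_reg == 0) & (ss_res == 0), 0.0, f)
    crit = float(stats.f.ppf(1.0 - alpha, 1, n - 2))
    selected = np.flatnonzero(f > crit)
    return SelectionResult("smc", f, crit, selected, selected.size)


def martens_significance(X: np.ndarray, y: np.ndarray, A: int, s: int = 10,
                         alpha: float = 0.05) -> SelectionResult:
    """Martens' uncertainty test via the cross-validation jackknife.

    The regression vector b is refit with each venetian-blinds segment
    left out; the per-channel jackknife variance of the coefficient is
    (M-1)/M * sum_m (b_j^(m) - b_j_bar)^2 over the M segments, centered
    on the segment mean (the classical grouped-jackknife estimate, which
    keeps the type-I rate at the nominal level; centering on the
    full-data coefficient instead adds a bias term and makes the test
    markedly conservative).  Channels with |b_j| / se_j above the
    two-sided Student-t critical value (df = M-1) are significant.
    Channels with zero jackknife variance are significant iff b_j != 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    folds = venetian_blinds_indices(n, s)
    b_full = fit_pls1(X, y, A).coefs[:, -1]
    b_seg = np.empty((s, X.shape[1]))
    for f in range(s):
        train = folds != f
        model = fit_pls1(X[train], y[train], min(A, int(train.sum()) - 1))
        b_seg[f] = model.coefs[:, -1]
    se = np.sqrt(((b_seg - b_seg.mean(axis=0)) ** 2).sum(axis=0) * (s - 1) / s)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(b_full) / se
    t = np.where(se > 0, t, np.where(b_full != 0, np.inf, 0.0))
    crit = float(stats.t.ppf(1.0 - alpha / 2.0, s - 1))
    selected = np.flatnonzero(t > crit)
    return SelectionResult("martens", t, crit, selected, selected.size)


def select_and_refit(X: np.ndarray, y: np.ndarray, method: str = "vip",
                     A: int | None = None, A_max: int = 8, s: int = 10,
                     vip_threshold: float = 1.0, alpha: float = 0.05,
                     tol_parsimony: float = 0.02):
    """One-pass selection on a full-variable model, then refit + CV.

    Returns ``(SelectionResult, PLSModel, CVResult)`` where the model
    and CV result are computed on the retained channels only.  The
    component count of the initial model is chosen by cross-validation
    unless ``A`` is forced.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if A is None:
        A = cross_validate(X, y, A_max, s, tol_parsimony).chosen_A
    if method == "vip":
        model = fit_pls1(X, y, A)
        scores = vip_scores(model)
        selected = np.flatnonzero(scores > vip_threshold)
        sel = SelectionResult("vip", scores, vip_threshold, selected, selected.size)
    elif method == "smc":
        model = fit_pls1(X, y, A)
        sel = smc_scores(model, X, y, alpha)
    elif method == "martens":
        sel = martens_significance(X, y, A, s, alpha)
    else:
        raise ValueError(f"unknown selection method {method!r}")
    if sel.n_selected == 0:
        raise ValueError(
            f"{method} selected no channels; lower the threshold/alpha")
    Xs = X[:, sel.selected]
    a_refit = min(A, Xs.shape[1])
    cv = cross_validate(Xs, y, a_refit, s, tol_parsimony)
    refit = fit_pls1(Xs, y, a_refit)
    return sel, refit, cv
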