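"""Spectral pre-treatments on a shared Whittaker-smoother core.

Raman spectra of aqueous samples ride on a broad fluorescence background
that dominates the chemical signal.  Four corrections are provided:

* AsLS   — asymmetric least squares: iterate a Whittaker smooth with
  small weight ``p`` on points above the running baseline, so peaks are
  ignored and the smooth hugs the background envelope.
* airPLS — adaptive iteratively reweighted penalized least squares:
  like AsLS but the weights on below-baseline residuals grow
  exponentially with the iteration index.
* BOC    — baseline offset correction: subtract a constant (the
  per-spectrum minimum, or the mean of a reference window).
* S.G.   — Savitzky-Golay first derivative (default window 7, degree 2),
  which removes additive and slowly varying backgrounds by
  differentiation.

Every baseline method returns baseline + corrected == input exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

__all__ = [
    "PreprocessConfig", "BaselineResult", "whittaker_smooth",
    "baseline_correct", "asls_baseline", "airpls_baseline", "boc_baseline",
    "sg_derivative", "apply_preprocess",
]

METHODS = ("asls", "airpls", "boc", "sg1", "raw")


@dataclass
class PreprocessConfig:
    """Parameters of one pre-treatment.

    lam is the Whittaker smoothness penalty (dimensionless; larger =
    stiffer baseline), p the AsLS asymmetry weight in (0, 1), window /
    polyorder the Savitzky-Golay settings, diff_order the order of the
    difference penalty (2 = literature standard), boc_window an optional
    (lo, hi) cm^-1 reference window whose mean replaces the minimum as
    the BOC offset.
    """

    method: str = "asls"
    lam: float = 1e5
    p: float = 0.01
    max_iter: int = 50
    tol: float = 1e-3
    window: int = 7
    polyorder: int = 2
    diff_order: int = 2
    boc_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if not self.lam > 0 and self.method in ("asls", "airpls"):
            raise ValueError("lam must be > 0")
        if not 0 < self.p < 1:
            raise ValueError("p must lie in (0, 1)")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter >= 1 and tol > 0 required")
        if self.window % 2 == 0 or self.window < 3 or self.window <= self.polyorder:
            raise ValueError("window must be odd, >= 3 and > polyorder")

    @property
    def label(self) -> str:
        return {"asls": "AsLs", "airpls": "air-PLS", "boc": "BOC",
                "sg1": "S.G. 1st der. 7sm", "raw": "Raw"}[self.method]


@dataclass
class BaselineResult:
    baseline: np.ndarray
    corrected: np.ndarray
    weights: np.ndarray
    n_iter: int
    converged: bool


def _make_result(y: np.ndarray, z: np.ndarray, w: np.ndarray, n_iter: int,
                 converged: bool) -> BaselineResult:
    # corrected is defined as input minus baseline with no further
    # rounding, so corrected == y - baseline holds bit-exactly (the sum
    # baseline + corrected can differ from y in the last ulp, as any
    # floating-point split must)
    return BaselineResult(z, y - z, w, n_iter, converged)


def _gram_banded(n: int, order: int) -> np.ndarray:
    """Upper banded form (solveh_banded layout) of D'D for Delta^order."""
    d = sparse.eye(n, format="csc")
    for _ in range(order):
        d = d[1:] - d[:-1]
    g = (d.T @ d).tocsc()
    ab = np.zeros((order + 1, n))
    for k in range(order + 1):
        ab[order - k, k:] = g.diagonal(k)
    return ab


_GRAM_CACHE: dict[tuple[int, int], np.ndarray] = {}


def whittaker_smooth(y: np.ndarray, w: np.ndarray, lam: float,
                     diff_order: int = 2) -> np.ndarray:
    """Solve (W + lam D'D) z = W y with D the difference operator.

    Minimizes sum_i w_i (y_i - z_i)^2 + lam * sum (Delta^order z)^2.
    Solved through the symmetric banded normal equations; cost O(n).
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if y.ndim != 1 or y.size < 3 or y.shape != w.shape:
        raise ValueError("y and w must be equal-length vectors of size >= 3")
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be >= 0 and not all zero")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if lam == 0:
        if np.any(w == 0):
            raise np.linalg.LinAlgError("singular system: zero weights with lam=0")
        return y.copy()
    n = y.size
    key = (n, diff_order)
    if key not in _GRAM_CACHE:
        _GRAM_CACHE[key] = _gram_banded(n, diff_order)
    ab = lam * _GRAM_CACHE[key]
    ab[diff_order] += w
    try:
        return solveh_banded(ab, w * y, lower=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate weights
        raise np.linalg.LinAlgError(f"singular Whittaker system: {exc}") from exc


def asls_baseline(y: np.ndarray, lam: float = 1e5, p: float = 0.01,
                  max_iter: int = 50, diff_order: int = 2) -> BaselineResult:
    """AsLS baseline: w_i = p above the baseline, 1-p below, until fixed."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite input")
    w = np.ones_like(y)
    z = y.copy()
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        z = whittaker_smooth(y, w, lam, diff_order)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            converged = True
            break
        w = w_new
    return _make_result(y, z, w, n_iter, converged)


def airpls_baseline(y: np.ndarray, lam: float = 1e5, max_iter: int = 30,
                    tol: float = 1e-3, diff_order: int = 2) -> BaselineResult:
    """airPLS baseline with iteration-adaptive exponential reweighting.

    At iteration t, residuals d = y - z; channels at/above the baseline
    (d >= 0) get weight 0, channels below get exp(t*|d_i|/|d^-|) with
    |d^-| the L1 norm of the negative residuals.  Stops when
    ||d^-||_1 < tol * ||y||_1.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite input")
    w = np.ones_like(y)
    z = y.copy()
    converged = False
    n_iter = 0
    y_norm = np.abs(y).sum()
    for n_iter in range(1, max_iter + 1):
        z = whittaker_smooth(y, w, lam, diff_order)
        d = y - z
        neg = d < 0
        dssn = np.abs(d[neg]).sum()
        w = np.zeros_like(y)
        if neg.any():
            w[neg] = np.exp(n_iter * np.abs(d[neg]) / dssn)
        if dssn < tol * y_norm or not neg.any():
            converged = True
            break
    return _make_result(y, z, w, n_iter, converged)


def boc_baseline(y: np.ndarray, axis: np.ndarray | None = None,
                 window: tuple[float, float] | None = None) -> BaselineResult:
    """Constant-offset baseline: min(y), or the mean over a reference window."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite input")
    if window is not None:
        if axis is None:
            raise ValueError("axis required for a reference-window offset")
        mask = (axis >= window[0]) & (axis <= window[1])
        if not mask.any():
            raise ValueError("empty reference window")
        offset = float(y[mask].mean())
    else:
        offset = float(y.min())
    z = np.full_like(y, offset)
    return _make_result(y, z, np.ones_like(y), 1, True)


def baseline_correct(y: np.ndarray, config: PreprocessConfig,
                     axis: np.ndarray | None = None) -> BaselineResult:
    """Dispatch to the configured baseline method (asls | airpls | boc)."""
    if config.method == "asls":
        return asls_baseline(y, config.lam, config.p, config.max_iter,
                             config.diff_order)
    if config.method == "airpls":
        return airpls_baseline(y, config.lam, config.max_iter, config.tol,
                               config.diff_order)
    if config.method == "boc":
        return boc_baseline(y, axis, config.boc_window)
    raise ValueError(f"{config.method!r} is not a baseline method")


def _check_uniform_axis(axis: np.ndarray) -> None:
    d = np.diff(axis)
    if d.size and (d.max() - d.min()) > 1e-6 * abs(d.mean()):
        raise ValueError("Savitzky-Golay derivative requires a uniform axis "
                         "(relative spacing deviation > 1e-6)")


def sg_derivative(y: np.ndarray, window: int = 7, polyorder: int = 2,
                  axis: np.ndarray | None = None) -> np.ndarray:
    """Savitzky-Golay first derivative in intensity per channel index.

    The derivative is taken per index (delta = 1) so the result does not
    depend on the nominal axis spacing; after mean-centering inside the
    regression, a global axis scale cancels anyway.  Edges use the
    polynomial fitted to the terminal window (scipy mode="interp").
    """
    y = np.asarray(y, dtype=float)
    if y.size < window:
        raise ValueError("input shorter than the smoothing window")
    if axis is not None:
        _check_uniform_axis(np.asarray(axis, dtype=float))
    return savgol_filter(y, window, polyorder, deriv=1, delta=1.0, mode="interp")


def apply_preprocess(dataset, config: PreprocessConfig):
    """Apply one pre-treatment row-wise to a :class:`SpectralDataset`."""
    if config.method == "raw":
        return dataset.with_intensities(dataset.intensities.copy())
    if config.method == "sg1":
        _check_uniform_axis(dataset.axis)
        out = np.vstack([
            sg_derivative(row, config.window, config.polyorder)
            for row in dataset.intensities
        ])
        return dataset.with_intensities(out)
    out = np.vstack([
        baseline_correct(row, config, dataset.axis).corrected
        for row in dataset.intensities
    ])
    return dataset.with_intensities(out)
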