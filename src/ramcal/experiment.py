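"""Model-building experiment driver.

Reproduces the study's two designs: cross-validated models built on all
samples (one row per pre-treatment x element), and models built on a
quasi-random calibration subset and validated on the held-out samples.
Every stage is explicit — preprocess, crop, optional split, fit +
venetian-blinds CV, optional variable selection + refit, optional
validation prediction — and the result is a flat report row mirroring
the familiar chemometrics table layout (R2C/RMSEC, R2CV/RMSECV/bias,
R2P/RMSEP/bias, spectral variables, latent variables).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import SpectralDataset, average_replicates, crop_region, reference_vector
from .pls import cross_validate, fit_pls1, predict, regression_metrics
from .preprocess import PreprocessConfig, apply_preprocess
from .selection import select_and_refit

__all__ = ["PipelineConfig", "ModelReport", "PipelineError",
           "quasi_random_split", "evaluate_pipeline", "run_grid",
           "render_report_table"]


class PipelineError(RuntimeError):
    """A stage failure annotated with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """One model-building recipe.

    ``split`` is an optional (n_cal, seed) pair activating the
    calibration/validation design; ``selection`` an optional method
    name ("vip" | "smc" | "martens"); ``A`` forces the latent-variable
    count (otherwise chosen by parsimonious CV); ``exclude`` lists
    sample ids removed before modeling (explicit outlier handling).
    """

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    region: tuple[float, float] = (50.0, 3398.0)
    element: str = "Ca"
    A_max: int = 8
    A: int | None = None
    cv_splits: int = 10
    tol_parsimony: float = 0.02
    selection: str | None = None
    vip_threshold: float = 1.0
    alpha: float = 0.05
    split: tuple[int, int] | None = None
    exclude: tuple[str, ...] = ()


@dataclass
class ModelReport:
    element: str
    data_type: str
    region: tuple[float, float]
    n_cal: int
    n_val: int
    spectral_variables: int
    A: int
    R2C: float
    RMSEC: float
    R2CV: float
    RMSECV: float
    bias_cv: float
    R2P: float = float("nan")
    RMSEP: float = float("nan")
    bias_p: float = float("nan")
    error: str = ""

    def to_row(self) -> dict:
        d = {"element": self.element, "data_type": self.data_type,
             "region": f"{self.region[0]:g}-{self.region[1]:g}",
             "n_cal": self.n_cal, "n_val": self.n_val,
             "spectral_variables": self.spectral_variables, "A": self.A,
             "R2C": self.R2C, "RMSEC": self.RMSEC, "R2CV": self.R2CV,
             "RMSECV": self.RMSECV, "bias_cv": self.bias_cv,
             "R2P": self.R2P, "RMSEP": self.RMSEP, "bias_p": self.bias_p}
        if self.error:
            d["error"] = self.error
        return d


def quasi_random_split(y: np.ndarray, n_cal: int, seed: int
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Seeded rank-stratified calibration/validation split.

    Samples are ranked by the response; the global minimum and maximum
    are forced into calibration (so validation never extrapolates), and
    the remaining ranks alternate between the two sets with seeded
    jitter until the sizes are (n_cal, n - n_cal).  Deterministic for a
    given seed.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if not 2 <= n_cal < n:
        raise ValueError(f"n_cal must lie in [2, {n - 1}]")
    rng = np.random.default_rng(seed)
    order = np.argsort(y, kind="stable")
    cal = [int(order[0]), int(order[-1])]
    val: list[int] = []
    need_cal = n_cal - 2
    need_val = n - n_cal
    take_cal = True
    for idx in order[1:-1]:
        flip = rng.uniform() < 0.25  # jitter the strict alternation
        choose_cal = take_cal ^ flip
        if choose_cal and need_cal == 0:
            choose_cal = False
        if not choose_cal and need_val == 0:
            choose_cal = True
        if choose_cal:
            cal.append(int(idx))
            need_cal -= 1
        else:
            val.append(int(idx))
            need_val -= 1
        take_cal = not take_cal
    return np.sort(np.array(cal)), np.sort(np.array(val))


def _prepare(dataset: SpectralDataset, references: pd.DataFrame,
             config: PipelineConfig):
    """preprocess -> average replicates -> crop -> align y; apply exclusions."""
    try:
        data = apply_preprocess(dataset, config.preprocess)
    except Exception as exc:
        raise PipelineError("preprocess", exc) from exc
    if len(set(data.sample_ids)) < data.n_rows:
        data = average_replicates(data)
    try:
        data = crop_region(data, *config.region)
    except Exception as exc:
        raise PipelineError("crop", exc) from exc
    keep = [i for i, s in enumerate(data.sample_ids) if s not in set(config.exclude)]
    ids = [data.sample_ids[i] for i in keep]
    X = data.intensities[keep]
    try:
        y = reference_vector(references, config.element, ids)
    except Exception as exc:
        raise PipelineError("references", exc) from exc
    return X, y, ids, data.axis


def evaluate_pipeline(dataset: SpectralDataset, references: pd.DataFrame,
                      config: PipelineConfig) -> ModelReport:
    """Run one full recipe and fill every report field."""
    X, y, ids, _ = _prepare(dataset, references, config)

    if config.split is not None:
        n_cal, seed = config.split
        try:
            cal_idx, val_idx = quasi_random_split(y, n_cal, seed)
        except Exception as exc:
            raise PipelineError("split", exc) from exc
        X_cal, y_cal = X[cal_idx], y[cal_idx]
        X_val, y_val = X[val_idx], y[val_idx]
    else:
        X_cal, y_cal = X, y
        X_val = y_val = None

    try:
        if config.selection is None:
            cv = cross_validate(X_cal, y_cal, config.A_max, config.cv_splits,
                                config.tol_parsimony)
            a = config.A or cv.chosen_A
            model = fit_pls1(X_cal, y_cal, a)
            mask = np.arange(X_cal.shape[1])
        else:
            sel, model, cv = select_and_refit(
                X_cal, y_cal, config.selection, A=config.A,
                A_max=config.A_max, s=config.cv_splits,
                vip_threshold=config.vip_threshold, alpha=config.alpha,
                tol_parsimony=config.tol_parsimony)
            a = model.A
            mask = sel.selected
            X_cal = X_cal[:, mask]
        a = min(a, model.A)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("fit", exc) from exc

    cal_m = regression_metrics(y_cal, predict(model, X_cal, a), "calibration")
    a_cv = min(a, cv.cv_predictions.shape[1])
    cv_m = regression_metrics(y_cal, cv.cv_predictions[:, a_cv - 1],
                              "cross_validation")
    report = ModelReport(
        element=config.element, data_type=config.preprocess.label,
        region=config.region, n_cal=len(y_cal),
        n_val=0 if y_val is None else len(y_val),
        spectral_variables=int(model.n_channels), A=a,
        R2C=cal_m.r2, RMSEC=cal_m.rmse,
        R2CV=cv_m.r2, RMSECV=cv_m.rmse, bias_cv=cv_m.bias)
    if X_val is not None:
        try:
            pred = predict(model, X_val[:, mask], a)
        except Exception as exc:
            raise PipelineError("validation", exc) from exc
        p_m = regression_metrics(y_val, pred, "prediction")
        report.R2P, report.RMSEP, report.bias_p = p_m.r2, p_m.rmse, p_m.bias
    return report


def run_grid(dataset: SpectralDataset, references: pd.DataFrame,
             configs: list[PipelineConfig]) -> tuple[list[ModelReport], pd.DataFrame]:
    """Evaluate each recipe independently; failures become error rows.

    The returned table carries a ``best`` marker on the lowest-RMSECV
    model per element (ties broken toward fewer latent variables).
    """
    if not configs:
        raise ValueError("empty config list")
    reports = []
    for cfg in configs:
        try:
            reports.append(evaluate_pipeline(dataset, references, cfg))
        except Exception as exc:
            reports.append(ModelReport(
                element=cfg.element, data_type=cfg.preprocess.label,
                region=cfg.region, n_cal=0, n_val=0, spectral_variables=0,
                A=0, R2C=np.nan, RMSEC=np.nan, R2CV=np.nan, RMSECV=np.nan,
                bias_cv=np.nan, error=str(exc)))
    table = pd.DataFrame([r.to_row() for r in reports])
    table["best"] = ""
    for element, sub in table.groupby("element", sort=False):
        ok = sub[sub["RMSECV"].notna()]
        if len(ok):
            i = ok.sort_values(["RMSECV", "A"], kind="stable").index[0]
            table.loc[i, "best"] = "*"
    return reports, table


def render_report_table(table: pd.DataFrame) -> str:
    """Aligned text rendering of a report table."""
    show = table.copy()
    for col in ("R2C", "R2CV", "R2P"):
        if col in show:
            show[col] = show[col].map(lambda v: f"{v:.2f}" if pd.notna(v) else "")
    for col in ("RMSEC", "RMSECV", "RMSEP", "bias_cv", "bias_p"):
        if col in show:
            show[col] = show[col].map(lambda v: f"{v:.3f}" if pd.notna(v) else "")
    return show.to_string(index=False)
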