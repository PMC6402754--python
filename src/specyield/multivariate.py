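"""Full-spectrum multivariate calibration: PLSR and SVR.

The calibration protocol mirrors chemometric practice on n << p
reflectance matrices: mean-centre X and y (no scaling, configurable),
run leave-one-out cross-validation over a complexity ladder (latent
factors 1..K for PLSR; a small C/epsilon grid for SVR), select the
setting with the lowest RMSECV, refit on all calibration data, then
validate the *frozen* model on treatment subsets, reporting adjusted
R^2, RMSE and the observed-vs-predicted line.

Model selection is fully deterministic: leave-one-out has no random
fold assignment, and RMSECV ties break toward the simpler setting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import LeaveOneOut, KFold
from sklearn.svm import SVR

__all__ = [
    "CalibrationModel",
    "ValidationReport",
    "fit_calibration",
    "validate",
    "subset_validation_suite",
]


@dataclass
class CalibrationModel:
    """A frozen spectral calibration and its selection diagnostics.

    ``setting`` is ``{"n_components": k}`` for PLSR or
    ``{"kernel": ..., "C": ..., "epsilon": ...}`` for SVR; ``rmsecv``
    maps every candidate setting (as a stable string) to its
    cross-validated RMSE.
    """

    method: str
    setting: dict
    rmsecv: dict[str, float]
    x_mean: np.ndarray
    y_mean: float
    estimator: object
    wavelengths: np.ndarray
    center: bool = True
    trait: str = ""

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.x_mean.size:
            raise ValueError(
                f"band-grid mismatch: model has {self.x_mean.size} bands, "
                f"input has {X.shape[1]}"
            )
        Xc = X - self.x_mean if self.center else X
        pred = np.asarray(self.estimator.predict(Xc), dtype=float).ravel()
        return pred + (self.y_mean if self.center else 0.0)

    @property
    def selected_rmsecv(self) -> float:
        return self.rmsecv[_setting_key(self.setting)]

    def coefficients(self) -> np.ndarray | None:
        """Linear coefficient vector where the model has one (PLSR, linear SVR)."""
        est = self.estimator
        if isinstance(est, PLSRegression):
            return np.asarray(est.coef_).ravel()
        if isinstance(est, SVR) and est.kernel == "linear":
            return np.asarray(est.coef_).ravel()
        return None

    def summary(self) -> str:
        lines = [
            f"Calibration: {self.method.upper()}"
            + (f" for {self.trait}" if self.trait else ""),
            f"  bands: {self.wavelengths.size} "
            f"({self.wavelengths[0]:g}-{self.wavelengths[-1]:g} nm)",
            f"  preprocessing: {'mean-centred X and y' if self.center else 'none'}",
            f"  selected setting: {self.setting}",
            f"  RMSECV at selection: {self.selected_rmsecv:.4g}",
            f"  candidates evaluated: {len(self.rmsecv)}",
        ]
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "method": self.method,
            "trait": self.trait,
            "center": self.center,
            "setting": self.setting,
            "rmsecv": self.rmsecv,
            "y_mean": self.y_mean,
            "wavelengths": self.wavelengths.tolist(),
            "x_mean": self.x_mean.tolist(),
        }
        coef = self.coefficients()
        if coef is not None:
            payload["coefficients"] = coef.tolist()
        path = Path(path)
        path.write_text(json.dumps(payload))
        return path


@dataclass
class ValidationReport:
    """Subset validation of a frozen calibration."""

    adj_r2: float
    rmse: float
    slope: float
    intercept: float
    r2: float
    p: float
    n: int
    observed_range: tuple[float, float]
    predicted_range: tuple[float, float]
    group: str = ""
    trait: str = ""

    def summary(self) -> str:
        return (
            f"Validation [{self.group or 'all'}] n={self.n}: "
            f"adj R2={self.adj_r2:.3f}, RMSE={self.rmse:.3g}, "
            f"obs-vs-pred slope={self.slope:.3f}, intercept={self.intercept:.3g}"
        )


def _setting_key(setting: dict) -> str:
    return json.dumps(setting, sort_keys=True)


def _loo_rmse(build, X: np.ndarray, y: np.ndarray, cv) -> float:
    preds = np.empty_like(y)
    with warnings.catch_warnings():
        # factor counts above the effective rank are legitimate candidates;
        # PLS warns that the residual is exhausted, which is expected here
        warnings.filterwarnings("ignore", message=".*residual is constant.*")
        for train, test in cv.split(X):
            est = build()
            est.fit(X[train], y[train])
            preds[test] = np.asarray(est.predict(X[test])).ravel()
    return float(np.sqrt(np.mean((preds - y) ** 2)))


def fit_calibration(
    X: np.ndarray,
    y: Sequence[float],
    method: str = "plsr",
    cv_scheme: str = "loo",
    wavelengths: np.ndarray | None = None,
    max_factors: int = 20,
    svr_grid: Sequence[dict] | None = None,
    center: bool = True,
    trait: str = "",
) -> CalibrationModel:
    """Fit and select a spectral calibration by cross-validated RMSE.

    Parameters
    ----------
    X
        (n_samples, n_bands) reflectance matrix on the full working grid.
    y
        Trait values; must not be constant.
    method
        ``"plsr"`` (latent factors 1..min(max_factors, n-2, bands)) or
        ``"svr"`` (epsilon-insensitive regression over a small
        hyperparameter grid; linear kernel by default).
    cv_scheme
        ``"loo"`` (default) or ``"kfold5"``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 6:
        raise ValueError(f"need at least 6 calibration samples, got {n}")
    if y.shape != (n,):
        raise ValueError("y must align with the rows of X")
    if np.ptp(y) == 0:
        raise ValueError("trait y is constant; calibration is degenerate")
    if wavelengths is None:
        wavelengths = np.arange(p, dtype=float)
    if cv_scheme == "loo":
        cv = LeaveOneOut()
    elif cv_scheme == "kfold5":
        cv = KFold(n_splits=5, shuffle=False)
    else:
        raise ValueError(f"unknown cv_scheme {cv_scheme!r}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean if center else X.copy()
    yc = y - y_mean if center else y.copy()

    rmsecv: dict[str, float] = {}
    candidates: list[tuple[dict, callable]] = []
    if method == "plsr":
        kmax = max(1, min(max_factors, n - 2, p))
        for k in range(1, kmax + 1):
            setting = {"n_components": k}
            candidates.append(
                (setting, lambda k=k: PLSRegression(n_components=k, scale=False))
            )
    elif method == "svr":
        y_scale = float(np.std(y)) or 1.0
        if svr_grid is None:
            svr_grid = [
                {"kernel": "linear", "C": c, "epsilon": round(e * y_scale, 10)}
                for c in (0.1, 1.0, 10.0, 100.0)
                for e in (0.01, 0.1)
            ]
        for setting in svr_grid:
            candidates.append((dict(setting), lambda s=setting: SVR(**s)))
    else:
        raise ValueError(f"unknown method {method!r}")

    best: tuple[float, dict, callable] | None = None
    for setting, build in candidates:
        rmse = _loo_rmse(build, Xc, yc, cv)
        rmsecv[_setting_key(setting)] = rmse
        if best is None or rmse < best[0] - 1e-12:
            best = (rmse, setting, build)
    assert best is not None
    estimator = best[2]()
    estimator.fit(Xc, yc)
    return CalibrationModel(
        method=method,
        setting=best[1],
        rmsecv=rmsecv,
        x_mean=x_mean,
        y_mean=y_mean,
        estimator=estimator,
        wavelengths=np.asarray(wavelengths, dtype=float),
        center=center,
        trait=trait,
    )


def validate(
    model: CalibrationModel,
    X_subset: np.ndarray,
    y_subset: Sequence[float],
    group: str = "",
) -> ValidationReport:
    """Validate the frozen model on a subset; never refits.

    Adjusted R^2 uses the single-regressor correction
    1 - (1 - R^2)(n - 1)/(n - 2) of the observed-vs-predicted line.
    """
    y = np.asarray(y_subset, dtype=float)
    if y.size == 0:
        raise ValueError("validation subset is empty")
    pred = model.predict(np.asarray(X_subset, dtype=float))
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    n = y.size
    if n >= 3 and np.ptp(pred) > 0 and np.ptp(y) > 0:
        fit = stats.linregress(pred, y)
        r2 = float(fit.rvalue**2)
        slope, intercept, p = float(fit.slope), float(fit.intercept), float(fit.pvalue)
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    elif rmse == 0:
        r2, slope, intercept, p, adj = 1.0, 1.0, 0.0, 0.0, 1.0
    else:
        r2 = slope = intercept = adj = np.nan
        p = np.nan
    return ValidationReport(
        adj_r2=adj,
        rmse=rmse,
        slope=slope,
        intercept=intercept,
        r2=r2,
        p=p,
        n=n,
        observed_range=(float(y.min()), float(y.max())),
        predicted_range=(float(pred.min()), float(pred.max())),
        group=group,
        trait=model.trait,
    )


def subset_validation_suite(
    model: CalibrationModel,
    keys: Sequence,
    X: np.ndarray,
    y: Sequence[float],
) -> pd.DataFrame:
    """Validate per irrigation rate, per density and per season.

    ``keys`` are :class:`~specyield.spectra.TreatmentKey` aligned with
    the rows of ``X``; on the reference design this yields 3 + 5 + 2 =
    10 reports. Empty subgroups are skipped.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups: list[tuple[str, np.ndarray]] = []
    rates = sorted({k.irrigation for k in keys}, reverse=True)
    densities = sorted({k.density for k in keys})
    seasons = sorted({k.season for k in keys})
    for r in rates:
        groups.append((f"I{r:.2f}", np.array([k.irrigation == r for k in keys])))
    for d in densities:
        groups.append((f"D{d}", np.array([k.density == d for k in keys])))
    for s in seasons:
        groups.append((f"S{s}", np.array([k.season == s for k in keys])))
    rows = []
    for label, mask in groups:
        if not mask.any():
            continue
        rep = validate(model, X[mask], y[mask], group=label)
        rows.append(
            {
                "group": label,
                "trait": model.trait,
                "method": model.method,
                "n": rep.n,
                "adj_r2": rep.adj_r2,
                "r2": rep.r2,
                "rmse": rep.rmse,
                "slope": rep.slope,
                "intercept": rep.intercept,
                "p": rep.p,
                "obs_min": rep.observed_range[0],
                "obs_max": rep.observed_range[1],
                "pred_min": rep.predicted_range[0],
                "pred_max": rep.predicted_range[1],
            }
        )
    return pd.DataFrame(rows)
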