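"""One-step-ahead vital-sign forecasting from a sliding window.

The forecaster is epsilon-insensitive support-vector regression: find
f(x) = <w, x> + b minimising 1/2 ||w||^2 + C * sum(xi + xi*) subject to
every training residual lying inside an epsilon tube (slack xi, xi*
beyond it).  The solver is the SMO-type optimiser in scikit-learn's
``SVR``; the contract here is the objective, not the algorithm.

Two feature constructions are supported:

* ``time_index`` (default) — regress the value on the window-local
  time index rescaled to [0, 1]; the forecast extrapolates one step.
* ``lags`` — regress on the previous ``lag_order`` values.

``compare_predictors`` runs the same rolling one-step protocol for the
SVR, ordinary linear regression and a Gaussian-process regressor, and
tabulates average percentage error and RMSE per parameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, WhiteKernel
from sklearn.linear_model import LinearRegression
from sklearn.svm import SVR

from .series_io import VitalSeries


class FitError(ValueError):
    """Window unusable for model fitting."""


@dataclass
class SVRConfig:
    """Hyperparameters of the epsilon-SVR forecaster.

    ``epsilon=None`` means adaptive: 0.1 x the window's sample SD, so
    the tube is meaningful across parameters with different units.
    ``tol`` is the solver stopping tolerance; it is kept tight so that
    refitting the same window is reproducible to ~1e-9.
    """

    C: float = 1.0
    epsilon: float | None = None
    kernel: str = "linear"
    feature_mode: str = "time_index"
    lag_order: int = 3
    window_size: int = 30
    tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.epsilon is not None and self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.feature_mode not in ("time_index", "lags"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if (self.feature_mode == "lags"
                and self.window_size < self.lag_order + 1):
            raise ValueError("window_size must be >= lag_order + 1")


@dataclass
class SVRModel:
    """A fitted one-step forecaster for a single window.

    Values are standardised by the window mean/SD before the solve
    (``y_loc``/``y_scale``) so the optimiser sees O(1) numbers
    whatever the native units; predictions are mapped back.  The
    standardisation commutes with adding a constant to the window, so
    translation equivariance is exact.
    """

    estimator: SVR
    config: SVRConfig
    first_index: int
    last_index: int
    window_values: np.ndarray
    epsilon: float  # resolved tube half-width, native units
    y_loc: float = 0.0
    y_scale: float = 1.0

    def _features_for(self, t: int) -> np.ndarray:
        w = self.config.window_size
        if self.config.feature_mode == "time_index":
            # window-local index rescaled to [0, 1]; the forecast sits
            # one step beyond, at (t - first)/(w - 1)
            return np.array([[(t - self.first_index) / (w - 1)]])
        k = self.config.lag_order
        z = (self.window_values[-k:][::-1] - self.y_loc) / self.y_scale
        return z.reshape(1, -1)

    def predict(self, t: int) -> float:
        if t != self.last_index + 1:
            raise ValueError(
                f"one-step contract: can only predict t={self.last_index + 1},"
                f" got t={t}")
        z = float(self.estimator.predict(self._features_for(t))[0])
        y = self.y_loc + self.y_scale * z
        if not math.isfinite(y):
            raise FitError("non-finite prediction")
        return y


def _resolve_epsilon(values: np.ndarray, config: SVRConfig) -> float:
    if config.epsilon is not None:
        return config.epsilon
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return 0.1 * sd


def fit_window(window, config: SVRConfig) -> SVRModel:
    """Fit the epsilon-SVR on an ordered (index, value) window.

    Indices must be consecutive; missing (NaN) values are not accepted
    here — the caller skips such windows entirely (imputing would mask
    the very sensor faults the pipeline looks for).
    """
    pairs = list(window)
    if len(pairs) < 2:
        raise FitError(f"need >= 2 points, got {len(pairs)}")
    idx = np.array([int(i) for i, _ in pairs])
    vals = np.array([float(v) for _, v in pairs])
    if not np.all(np.isfinite(vals)):
        raise FitError("window contains non-finite values")
    if not np.all(np.diff(idx) == 1):
        raise FitError("window indices must be consecutive")

    eps = _resolve_epsilon(vals, config)
    # standardise by the window so the solver works on O(1) numbers
    y_loc = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    y_scale = sd if sd > 0 else 1.0
    z = (vals - y_loc) / y_scale

    w = config.window_size
    if config.feature_mode == "time_index":
        X = ((idx - idx[0]) / (w - 1)).reshape(-1, 1)
        y = z
    else:
        k = config.lag_order
        X = np.column_stack([z[k - 1 - j:len(z) - 1 - j]
                             for j in range(k)])
        y = z[k:]

    est = SVR(kernel=config.kernel, C=config.C, epsilon=eps / y_scale,
              tol=config.tol, gamma="scale")
    est.fit(X, y)
    return SVRModel(estimator=est, config=config,
                    first_index=int(idx[0]), last_index=int(idx[-1]),
                    window_values=vals, epsilon=eps,
                    y_loc=y_loc, y_scale=y_scale)


def predict_next(model: SVRModel, t: int) -> float:
    """Forecast f(x_t) = <w, x_t> + b at the index just past the window."""
    return model.predict(t)


@dataclass
class PredictionRecord:
    parameter: str
    t: int
    predicted: float
    actual: float  # NaN when the sensed value is missing

    @property
    def residual(self) -> float:
        return abs(self.actual - self.predicted)


def rolling_predict(series: VitalSeries, parameter: str,
                    config: SVRConfig | None = None,
                    start: int | None = None,
                    stop: int | None = None) -> list[PredictionRecord]:
    """One-step forecasts over a series: for each t, fit on the
    preceding ``window_size`` samples and predict at t.

    Windows containing missing values are skipped (a gap, not an
    imputation).  Returns one record per usable t.
    """
    if config is None:
        config = SVRConfig()
    col = series.column(parameter)
    w = config.window_size
    if len(col) <= w:
        raise FitError(f"series length {len(col)} <= window size {w}")
    start = w if start is None else max(start, w)
    stop = len(col) if stop is None else min(stop, len(col))
    records: list[PredictionRecord] = []
    for t in range(start, stop):
        window_vals = col[t - w:t]
        if not np.all(np.isfinite(window_vals)):
            continue
        model = fit_window(list(zip(range(t - w, t), window_vals)), config)
        records.append(PredictionRecord(
            parameter=parameter, t=t,
            predicted=predict_next(model, t), actual=float(col[t])))
    return records


def prediction_metrics(records: list[PredictionRecord]) -> dict:
    """Average percentage error and RMSE over (actual, predicted) pairs.

    Pairs with a missing actual are dropped; pairs with actual == 0 are
    excluded from the percentage-error mean (and counted) because the
    percentage is undefined there.
    """
    pairs = [(r.actual, r.predicted) for r in records
             if math.isfinite(r.actual)]
    n = len(pairs)
    if n == 0:
        return {"n": 0, "rmse": math.nan, "pct_error": math.nan,
                "n_zero_actual": 0}
    a = np.array([p[0] for p in pairs])
    p = np.array([p[1] for p in pairs])
    rmse = float(np.sqrt(np.mean((a - p) ** 2)))
    nz = a != 0
    pct = (float(np.mean(np.abs(a[nz] - p[nz]) / np.abs(a[nz]) * 100.0))
           if nz.any() else math.nan)
    return {"n": n, "rmse": rmse, "pct_error": pct,
            "n_zero_actual": int((~nz).sum())}


def _baseline_forecaster(method: str, seed: int):
    if method == "linear_regression":
        return LinearRegression()
    if method == "gaussian_process":
        kernel = RBF(length_scale=0.3) + WhiteKernel(noise_level=1e-2)
        return GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                        random_state=seed)
    raise ValueError(f"unknown method {method!r}")


def compare_predictors(series: VitalSeries,
                       window_size: int = 30,
                       n_predictions: int = 100,
                       parameters: list[str] | None = None,
                       methods: tuple[str, ...] = (
                           "svr", "linear_regression", "gaussian_process"),
                       svr_config: SVRConfig | None = None,
                       seed: int = 0) -> pd.DataFrame:
    """Rolling one-step comparison of forecasting methods.

    For each method and parameter, performs ``n_predictions`` one-step
    forecasts (fit on the previous ``window_size`` samples, predict the
    next) and reports average percentage error |S_a - S_p|/|S_a| * 100
    and RMSE.  Returns a tidy DataFrame with columns
    (method, parameter, n, pct_error, rmse, n_zero_actual).
    """
    if parameters is None:
        parameters = list(series.parameter_names)
    if svr_config is None:
        svr_config = SVRConfig(window_size=window_size)
    w = window_size
    stop = min(len(series), w + n_predictions)
    if stop - w < n_predictions:
        raise FitError(
            f"series too short for {n_predictions} forecasts at window {w}")

    rows = []
    for method in methods:
        for param in parameters:
            if method == "svr":
                recs = rolling_predict(series, param, svr_config,
                                       start=w, stop=stop)
            else:
                recs = _rolling_baseline(series, param, method, w,
                                         stop, seed)
            m = prediction_metrics(recs)
            rows.append({"method": method, "parameter": param, **m})
    return pd.DataFrame(rows)


def _rolling_baseline(series: VitalSeries, parameter: str, method: str,
                      w: int, stop: int, seed: int):
    col = series.column(parameter)
    records = []
    for t in range(w, stop):
        vals = col[t - w:t]
        if not np.all(np.isfinite(vals)):
            continue
        X = (np.arange(w) / (w - 1)).reshape(-1, 1)
        est = _baseline_forecaster(method, seed)
        with warnings.catch_warnings():
            # GP hyperparameter bounds routinely saturate on short,
            # nearly-noiseless windows; harmless for a one-step forecast
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(X, vals)
        pred = float(est.predict(np.array([[w / (w - 1)]]))[0])
        records.append(PredictionRecord(parameter=parameter, t=t,
                                        predicted=pred,
                                        actual=float(col[t])))
    return records
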