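"""Alarm triage: dynamic thresholds, parameter flags, majority voting.

For every time instant past warm-up the pipeline, per parameter:

1. forecasts the sensed value from a sliding window of accepted
   history (``prediction`` module);
2. computes the native-unit residual |S_a - S_p| against the sensed
   value;
3. compares it with a dynamic threshold T_d = k_mult * S_d, where S_d
   is the sample standard deviation of a sliding buffer of recent
   accepted values — the threshold tracks the patient's own recent
   variability instead of a fixed population bound;
4. flags the parameter when the residual strictly exceeds T_d.

Flags are then combined by majority voting: no flags means a normal
instant; a strict majority of flagged parameters means the excursion
is corroborated across sensors and is a **true alarm** (a genuine
medical condition); a non-empty minority means an uncorroborated,
single-sensor excursion — a **false alarm** caused by a sensor fault.

The residual, not the percentage error, is compared with T_d: both are
computed, but T_d is a standard deviation in native units, so the
comparison is only dimensionally meaningful against the residual.  The
percentage error is logged on every record for reporting.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np

from .prediction import FitError, SVRConfig, fit_window, predict_next
from .series_io import VitalSeries

VERDICT_NORMAL = "normal"
VERDICT_TRUE_ALARM = "true_alarm"
VERDICT_FALSE_ALARM = "false_alarm"


def sample_sd(values) -> float:
    """Sample standard deviation (n-1 denominator); 0.0 for n < 2."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return 0.0
    return float(np.std(v, ddof=1))


@dataclass
class ThresholdState:
    """Per-parameter sliding buffer and its dynamic threshold.

    ``t_d = k_mult * s_d`` with s_d the sample SD of the buffer;
    recomputed on every update.  In ``fixed`` mode the threshold is
    frozen at its first full-buffer value (the non-updating special
    case T_f).
    """

    parameter: str
    w_t: int = 30
    k_mult: float = 1.0
    mode: str = "dynamic"  # dynamic | fixed
    buffer: deque = field(default_factory=deque)
    s_d: float = 0.0
    t_d: float = 0.0
    _frozen: bool = False

    def __post_init__(self) -> None:
        if self.w_t < 2:
            raise ValueError("threshold window must be >= 2")
        if self.k_mult <= 0:
            raise ValueError("k_mult must be positive")
        if self.mode not in ("dynamic", "fixed"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        self.buffer = deque(self.buffer, maxlen=self.w_t)
        self._recompute()

    def _recompute(self) -> None:
        self.s_d = sample_sd(self.buffer)
        self.t_d = self.k_mult * self.s_d

    def push(self, value: float) -> None:
        """FIFO update: evict the oldest when full, append, recompute."""
        if not math.isfinite(value):
            return  # non-finite values are rejected, state unchanged
        self.buffer.append(value)
        if self.mode == "fixed":
            if not self._frozen:
                self._recompute()
                if len(self.buffer) == self.w_t:
                    self._frozen = True
        else:
            self._recompute()

    @property
    def full(self) -> bool:
        return len(self.buffer) == self.w_t


def update_threshold(state: ThresholdState, new_value: float) -> ThresholdState:
    """Functional wrapper: returns the updated state (same object)."""
    state.push(new_value)
    return state


@dataclass
class ErrorRecord:
    """Per-parameter, per-instant comparison of sensed vs predicted."""

    parameter: str
    t: int
    residual: float
    percent_error: float  # NaN when the sensed value is 0
    threshold: float = math.nan
    flagged: int = 0


def compute_error(actual: float, predicted: float) -> tuple[float, float]:
    """Native-unit residual and percentage error (NaN when actual==0)."""
    if not (math.isfinite(actual) and math.isfinite(predicted)):
        raise ValueError("actual and predicted must be finite")
    residual = abs(actual - predicted)
    pct = 100.0 * residual / abs(actual) if actual != 0 else math.nan
    return residual, pct


def flag_parameter(err: ErrorRecord, state: ThresholdState) -> int:
    """v(i) = 1 iff the residual strictly exceeds T_d (ties unflagged)."""
    return 1 if err.residual > state.t_d else 0


def majority_vote(flags, n: int | None = None) -> str:
    """Combine per-parameter flags into a verdict.

    Y = sum of flags.  Y = 0 -> normal; Y > n/2 (strict majority) ->
    true alarm; otherwise a non-empty minority -> false alarm (sensor
    anomaly).  A tied even-n vote resolves to false alarm: a split
    vote is not treated as a corroborated medical emergency.
    """
    flags = list(flags)
    if n is None:
        n = len(flags)
    if n < 1 or len(flags) != n:
        raise ValueError(f"need n >= 1 flags, got {len(flags)} (n={n})")
    y = int(sum(flags))
    if y == 0:
        return VERDICT_NORMAL
    if y > n / 2:
        return VERDICT_TRUE_ALARM
    return VERDICT_FALSE_ALARM


@dataclass
class AlarmDecision:
    """Per-instant verdict with its evidence."""

    t: int
    flags: dict[str, int]
    vote_count: int
    n: int  # parameters that actually voted at t
    verdict: str
    residuals: dict[str, float] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    percent_errors: dict[str, float] = field(default_factory=dict)


@dataclass
class PipelineConfig:
    """Knobs of the detection pipeline.

    ``w_t``/``w_p`` are the threshold and prediction sliding-window
    sizes (30 samples each by default), ``w_detect`` the evaluation
    batch size (80).  ``update_policy`` controls what enters the
    sliding buffers after a decision: ``accept_all`` (default) always
    pushes the sensed value — estimates never replace measurements;
    ``accept_normal_only`` pushes the sensed value only for unflagged
    parameters and the predicted value otherwise.  The latter keeps
    anomalies out of the model of normality but is unstable under
    sustained flagging (the forecaster ends up predicting its own
    predictions, residuals compound, and flagging becomes an absorbing
    state), so it is opt-in.
    """

    w_t: int = 30
    w_p: int = 30
    w_detect: int = 80
    k_mult: float = 1.0
    # the pipeline forecasts from lagged values: the detector must track
    # the signal's autocorrelation, not just its windowed trend
    svr: SVRConfig = field(
        default_factory=lambda: SVRConfig(feature_mode="lags"))
    update_policy: str = "accept_all"
    threshold_mode: str = "dynamic"

    def __post_init__(self) -> None:
        if isinstance(self.svr, dict):
            self.svr = SVRConfig(**self.svr)
        for name in ("w_t", "w_p", "w_detect"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.k_mult <= 0:
            raise ValueError("k_mult must be positive")
        if self.update_policy not in ("accept_all", "accept_normal_only"):
            raise ValueError(f"unknown update_policy {self.update_policy!r}")
        if self.threshold_mode not in ("dynamic", "fixed"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.svr.window_size != self.w_p:
            self.svr = replace(self.svr, window_size=self.w_p)

    @property
    def warmup(self) -> int:
        """No decisions for the first max(w_p, w_t) samples."""
        return max(self.w_p, self.w_t)


class _ParamTracker:
    """Sliding prediction window + threshold state for one parameter."""

    def __init__(self, name: str, config: PipelineConfig) -> None:
        self.name = name
        self.config = config
        self.pred_buf: deque = deque(maxlen=config.w_p)  # (index, value)
        self.threshold = ThresholdState(
            parameter=name, w_t=config.w_t, k_mult=config.k_mult,
            mode=config.threshold_mode)

    def window_ready(self, t: int) -> bool:
        if len(self.pred_buf) < self.config.w_p:
            return False
        idx = [i for i, _ in self.pred_buf]
        return idx[-1] == t - 1 and idx[-1] - idx[0] == self.config.w_p - 1

    def accept(self, t: int, value: float) -> None:
        if not math.isfinite(value):
            # a gap breaks window continuity; restart the buffer
            self.pred_buf.clear()
            return
        self.pred_buf.append((t, value))
        self.threshold.push(value)


def run_pipeline(series: VitalSeries,
                 config: PipelineConfig | None = None,
                 parameters: list[str] | None = None) -> list[AlarmDecision]:
    """Run forecast -> error -> threshold -> vote over a whole series.

    Per instant t past warm-up, every parameter with a complete, gap
    free history window forecasts its value and votes; parameters with
    a missing reading or an incomplete window abstain, and n for the
    vote is the number of non-abstaining parameters.  Instants where
    every parameter abstains produce no decision.  Deterministic given
    (series, config).
    """
    if config is None:
        config = PipelineConfig()
    if parameters is None:
        parameters = list(series.parameter_names)
    if len(series) <= config.warmup:
        raise ValueError(
            f"series length {len(series)} <= warm-up {config.warmup}")

    trackers = {p: _ParamTracker(p, config) for p in parameters}
    cols = {p: series.column(p) for p in parameters}

    for t in range(config.warmup):
        for p in parameters:
            trackers[p].accept(t, float(cols[p][t]))

    decisions: list[AlarmDecision] = []
    for t in range(config.warmup, len(series)):
        flags: dict[str, int] = {}
        residuals: dict[str, float] = {}
        thresholds: dict[str, float] = {}
        pcts: dict[str, float] = {}
        updates: list[tuple[str, float]] = []
        for p in parameters:
            tr = trackers[p]
            actual = float(cols[p][t])
            if not math.isfinite(actual) or not tr.window_ready(t):
                tr.accept(t, actual)  # refill/clear; abstain from vote
                continue
            try:
                model = fit_window(list(tr.pred_buf), config.svr)
                predicted = predict_next(model, t)
            except FitError:
                tr.accept(t, actual)
                continue
            residual, pct = compute_error(actual, predicted)
            err = ErrorRecord(parameter=p, t=t, residual=residual,
                              percent_error=pct, threshold=tr.threshold.t_d)
            err.flagged = flag_parameter(err, tr.threshold)
            flags[p] = err.flagged
            residuals[p] = residual
            thresholds[p] = tr.threshold.t_d
            pcts[p] = pct
            if (config.update_policy == "accept_all") or not err.flagged:
                updates.append((p, actual))
            else:
                updates.append((p, predicted))
        if not flags:
            continue  # every parameter abstained
        n = len(flags)
        verdict = majority_vote(flags.values(), n)
        decisions.append(AlarmDecision(
            t=t, flags=dict(flags), vote_count=int(sum(flags.values())),
            n=n, verdict=verdict, residuals=residuals,
            thresholds=thresholds, percent_errors=pcts))
        for p, v in updates:
            trackers[p].accept(t, v)
    return decisions


def decisions_to_frame(decisions: list[AlarmDecision],
                       parameters: list[str]):
    """Tabulate decisions: t, verdict, vote_count, n, then per-parameter
    flag / residual / threshold columns."""
    import pandas as pd

    rows = []
    for d in decisions:
        row = {"t": d.t, "verdict": d.verdict,
               "vote_count": d.vote_count, "n": d.n}
        for p in parameters:
            row[f"{p}_flag"] = d.flags.get(p, "")
            row[f"{p}_residual"] = d.residuals.get(p, math.nan)
            row[f"{p}_threshold"] = d.thresholds.get(p, math.nan)
        rows.append(row)
    return pd.DataFrame(rows)
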