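"""Scoring alarm decisions against ground truth.

Positive class = true alarm (a genuine medical condition); negative
class = false alarm (a sensor fault).  Default scoring is event-level:
each ground-truth event contributes exactly one outcome — a medical
event counts as a true positive if any decision inside its window is a
true alarm, else a false negative; a fault event counts as a false
positive if any decision inside its window is (wrongly) a true alarm,
else a true negative.  Instant-level scoring is available for
diagnostics.

Detection Rate DR = TP / (TP + FN); False Positive Rate
FPR = FP / (FP + TN).  Undefined ratios (zero denominator) are
reported as NaN with a diagnostic, never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .detection import (VERDICT_TRUE_ALARM, AlarmDecision, PipelineConfig,
                        run_pipeline)
from .synthetic_data import (LABEL_FAULT, LABEL_MEDICAL, LabeledSeries)


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        for f in ("TP", "FP", "TN", "FN"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.TN + other.TN, self.FN + other.FN)


def detection_rate(c: ConfusionCounts) -> float:
    """DR = TP / (TP + FN); NaN when no positives were scored."""
    if c.TP + c.FN == 0:
        return math.nan
    return c.TP / (c.TP + c.FN)


def false_positive_rate(c: ConfusionCounts) -> float:
    """FPR = FP / (FP + TN); NaN when no negatives were scored."""
    if c.FP + c.TN == 0:
        return math.nan
    return c.FP / (c.FP + c.TN)


def score(decisions: list[AlarmDecision], truth: LabeledSeries,
          mode: str = "event") -> ConfusionCounts:
    """Confusion counts of decisions against ground truth.

    ``mode='event'`` (default): one outcome per ground-truth event, as
    described in the module docstring.  ``mode='instant'``: one outcome
    per decided instant, positive truth = a medical-event instant,
    positive prediction = a true-alarm verdict.
    """
    if mode not in ("event", "instant"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    n = len(truth)
    for d in decisions:
        if not (0 <= d.t < n):
            raise ValueError(f"decision at t={d.t} outside truth of length {n}")

    if mode == "instant":
        decided = {d.t: d.verdict for d in decisions}
        c = ConfusionCounts()
        for t, verdict in decided.items():
            positive_truth = truth.labels[t] == LABEL_MEDICAL
            positive_pred = verdict == VERDICT_TRUE_ALARM
            if positive_truth and positive_pred:
                c.TP += 1
            elif positive_truth:
                c.FN += 1
            elif positive_pred:
                c.FP += 1
            else:
                c.TN += 1
        return c

    alarm_instants = {d.t for d in decisions
                      if d.verdict == VERDICT_TRUE_ALARM}
    c = ConfusionCounts()
    for ev in truth.events:
        hit = any(t in alarm_instants for t in ev.window())
        if ev.kind == LABEL_MEDICAL:
            if hit:
                c.TP += 1
            else:
                c.FN += 1
        elif ev.kind == LABEL_FAULT:
            if hit:
                c.FP += 1
            else:
                c.TN += 1
    return c


@dataclass
class RocPoint:
    k: int  # number of physiological parameters voting
    DR: float
    FPR: float


def roc_sweep(truth: LabeledSeries, config: PipelineConfig | None = None,
              k_values: list[int] | None = None,
              mode: str = "event") -> list[RocPoint]:
    """Operating points obtained by varying the number of voting
    parameters k: rerun the pipeline on the first k parameters (in
    canonical order), score, and emit (k, DR, FPR).

    Fewer voting parameters weaken the majority-vote corroboration, so
    the sweep traces how DR/FPR degrade as sensors are removed.
    """
    series = truth.series
    if k_values is None:
        k_values = list(range(1, series.n + 1))
    points: list[RocPoint] = []
    for k in k_values:
        if not (1 <= k <= series.n):
            raise ValueError(f"k={k} outside 1..{series.n}")
        params = series.parameter_names[:k]
        decisions = run_pipeline(series, config, parameters=params)
        c = score(decisions, truth, mode=mode)
        points.append(RocPoint(k=k, DR=detection_rate(c),
                               FPR=false_positive_rate(c)))
    return points


def threshold_mode_comparison(truth: LabeledSeries,
                              config: PipelineConfig | None = None,
                              mode: str = "event") -> pd.DataFrame:
    """DR/FPR of the dynamic threshold vs the fixed special case.

    Runs the pipeline twice — sliding T_d vs T_f frozen at the SD of
    the initial window — and tabulates both.  On drifting data the
    frozen threshold goes stale, which is the empirical case for
    updating it.
    """
    if config is None:
        config = PipelineConfig()
    rows = []
    for tmode in ("dynamic", "fixed"):
        cfg = replace(config, threshold_mode=tmode)
        decisions = run_pipeline(truth.series, cfg)
        c = score(decisions, truth, mode=mode)
        rows.append({"threshold_mode": tmode, "TP": c.TP, "FP": c.FP,
                     "TN": c.TN, "FN": c.FN,
                     "DR": detection_rate(c),
                     "FPR": false_positive_rate(c),
                     "n_alarm_instants": sum(
                         d.verdict == VERDICT_TRUE_ALARM for d in decisions)})
    return pd.DataFrame(rows)


def roc_frame(points: list[RocPoint]) -> pd.DataFrame:
    return pd.DataFrame([{"k": p.k, "DR": p.DR, "FPR": p.FPR}
                         for p in points])
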