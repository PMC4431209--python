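"""Synthetic multivariate vital-sign streams with labeled anomalies.

Each vital (ABPmean, HR, Pulse, Respiration, SpO2) is the sum of a
slow quasi-periodic physiological drift (a mixture of incommensurate
sinusoids with seeded random phases — the minutes-scale wander that activity and
autonomic regulation impose on monitor numerics) and a mean-reverting
AR(1) noise process capturing short-term variability, with one shared
latent drift component inducing cross-parameter correlation of the
slow wander.  On top
of the anomaly-free stream two kinds of labeled anomalies are
injected:

* **medical events** — correlated multi-parameter excursions (blood
  pressure up; HR, Pulse, Respiration and SpO2 down), the signature of
  a genuine deterioration affecting a strict majority of parameters;
* **sensor faults** — a single parameter perturbed in isolation,
  multiplicatively (x -> x*(1 ± m) with m in {0.20, 0.30, 0.50}) or as
  a zero dropout, the characteristic shape of a device artifact.

Every stream carries per-instant ground-truth labels, so detection and
evaluation can be exercised end to end without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .series_io import CANONICAL_ORDER, VitalSeries

LABEL_NORMAL = "normal"
LABEL_MEDICAL = "medical_event"
LABEL_FAULT = "sensor_fault"

#: Physiologically typical resting-adult baselines (mean, innovation SD),
#: inside the standard normal ranges: HR 60-100 bpm, Respiration 12-20
#: breaths/min, SpO2 95-100 %.  Innovation SDs reflect sample-to-sample
#: variability of monitor numerics (which average over several beats).
DEFAULT_BASELINES = {
    "ABPmean": (85.0, 0.4),
    "HR": (80.0, 0.3),
    "Pulse": (80.0, 0.3),
    "Respiration": (16.0, 0.12),
    "SpO2": (97.5, 0.08),
}

#: Amplitude scale (native units) of the slow physiological wander —
#: resting vitals cycle over a few minutes with swings of several bpm
#: (HR), a few mmHg (ABPmean) and ~1 % (SpO2).
DEFAULT_DRIFT_AMPLITUDE = {
    "ABPmean": 6.0,
    "HR": 5.0,
    "Pulse": 5.0,
    "Respiration": 1.8,
    "SpO2": 1.2,
}

#: Medical-event direction signature: BP rises; the rest fall.
MEDICAL_EVENT_DIRECTIONS = {
    "ABPmean": +1,
    "HR": -1,
    "Pulse": -1,
    "Respiration": -1,
    "SpO2": -1,
}

#: Hard physical bounds applied after generation and injection.
CLIP_BOUNDS = {"SpO2": (0.0, 100.0)}

NORMAL_RANGES = {"HR": (60.0, 100.0), "Respiration": (12.0, 20.0),
                 "SpO2": (95.0, 100.0)}


class GeneratorConfigError(ValueError):
    """Invalid generator configuration."""


class EventPlacementError(ValueError):
    """Requested events cannot be placed (overlap or out of bounds)."""


@dataclass
class GeneratorConfig:
    """Parameters of the vital-sign generator.

    ``baselines`` maps parameter -> (mean, innovation SD) in native
    units.  Each parameter is x_t = mu + d_t + r_t where d_t is a slow
    multi-sinusoid drift of amplitude scale ``drift_amplitude[param]``
    and periods ~ ``drift_periods`` samples (seeded random phases and
    +-15% period jitter), and r_t is AR(1) noise: r_t = phi*r_{t-1} +
    e_t with phi = ``ar_coefficient`` and independent innovations e_t
    of SD ``noise_sd`` (falling back to the baseline SD).
    Cross-parameter correlation enters through a shared latent drift
    component with weight ``cross_correlation`` — vitals co-vary at
    the minutes scale of physiological co-regulation, not in
    device-level sample noise.  Setting ``drift_amplitude`` to zeros
    gives the pure AR(1) process.
    """

    n_samples: int = 2000
    seed: int = 0
    sample_period: float = 1.0
    baselines: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES))
    ar_coefficient: float = 0.9
    noise_sd: dict[str, float] | None = None
    cross_correlation: float = 0.3
    drift_amplitude: dict[str, float] | None = None
    drift_periods: tuple[float, ...] = (90.0, 200.0, 460.0)

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise GeneratorConfigError("n_samples must be positive")
        if not (0.0 <= self.ar_coefficient < 1.0):
            raise GeneratorConfigError("ar_coefficient must be in [0, 1)")
        if not (-1.0 <= self.cross_correlation <= 1.0):
            raise GeneratorConfigError("cross_correlation must be in [-1, 1]")
        for name, (mu, sd) in self.baselines.items():
            if not (math.isfinite(mu) and math.isfinite(sd)) or sd < 0:
                raise GeneratorConfigError(
                    f"baseline for {name!r} must be finite with SD >= 0")
            lo, hi = NORMAL_RANGES.get(name, (-math.inf, math.inf))
            if not (lo <= mu <= hi):
                raise GeneratorConfigError(
                    f"{name} baseline mean {mu} outside normal range "
                    f"[{lo}, {hi}]")
        if self.noise_sd is not None:
            for name, sd in self.noise_sd.items():
                if not math.isfinite(sd) or sd < 0:
                    raise GeneratorConfigError(
                        f"noise_sd for {name!r} must be finite and >= 0")
        if self.drift_amplitude is not None:
            for name, a in self.drift_amplitude.items():
                if not math.isfinite(a) or a < 0:
                    raise GeneratorConfigError(
                        f"drift_amplitude for {name!r} must be finite, >= 0")
        if any(p <= 0 for p in self.drift_periods):
            raise GeneratorConfigError("drift_periods must be positive")

    @property
    def parameter_names(self) -> list[str]:
        names = list(self.baselines)
        if set(CANONICAL_ORDER) <= set(names):
            return [p for p in CANONICAL_ORDER] + [
                p for p in names if p not in CANONICAL_ORDER]
        return names

    def innovation_sd(self, name: str) -> float:
        if self.noise_sd is not None and name in self.noise_sd:
            return self.noise_sd[name]
        return self.baselines[name][1]

    def stationary_sd(self, name: str) -> float:
        """Closed-form stationary SD of the AR(1) noise component:
        sigma/sqrt(1-phi^2)."""
        return self.innovation_sd(name) / math.sqrt(
            1.0 - self.ar_coefficient ** 2)

    def drift_amp(self, name: str) -> float:
        if self.drift_amplitude is not None and name in self.drift_amplitude:
            return self.drift_amplitude[name]
        if self.drift_amplitude is not None:
            return 0.0
        return DEFAULT_DRIFT_AMPLITUDE.get(name, 0.0)


@dataclass
class EventSpec:
    """One injected anomaly window.

    ``magnitude_fraction`` is the multiplicative perturbation (0.50,
    0.30 or 0.20 by default); ``direction`` maps each affected
    parameter to +1 (scale up) or -1 (scale down).  ``dropout`` marks a
    zero-reading fault (value forced to 0, magnitude ignored).
    """

    kind: str  # LABEL_MEDICAL | LABEL_FAULT
    start_index: int
    duration: int
    affected_parameters: list[str]
    magnitude_fraction: float = 0.50
    direction: dict[str, int] = field(default_factory=dict)
    dropout: bool = False

    def __post_init__(self) -> None:
        if self.kind not in (LABEL_MEDICAL, LABEL_FAULT):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.magnitude_fraction <= 0 and not self.dropout:
            raise ValueError("magnitude_fraction must be positive")
        if self.kind == LABEL_FAULT and len(self.affected_parameters) != 1:
            raise ValueError("a sensor fault affects exactly one parameter")
        if not self.affected_parameters:
            raise ValueError("event must affect at least one parameter")
        for p in self.affected_parameters:
            self.direction.setdefault(p, +1)

    @property
    def stop_index(self) -> int:
        """One past the last affected sample."""
        return self.start_index + self.duration

    def window(self) -> range:
        return range(self.start_index, self.stop_index)


@dataclass
class LabeledSeries:
    """A vital-sign stream plus per-instant ground truth."""

    series: VitalSeries
    labels: np.ndarray  # dtype object/str, length == len(series)
    events: list[EventSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != (len(self.series),):
            raise ValueError("labels length must equal series length")

    def __len__(self) -> int:
        return len(self.series)

    def copy(self) -> "LabeledSeries":
        return LabeledSeries(self.series.copy(), self.labels.copy(),
                             [replace(e) for e in self.events])


def generate_vitals(config: GeneratorConfig) -> VitalSeries:
    """Simulate an anomaly-free multivariate vital-sign stream.

    Per parameter: baseline mean + slow multi-sinusoid physiological
    drift (seeded random phases, +-15% period jitter per parameter)
    + mean-reverting AR(1) noise started at its stationary
    distribution.  A shared latent drift component with loading
    sqrt(|cross_correlation|) induces cross-parameter correlation of
    the slow wander (alternating loading signs when cross_correlation
    < 0); AR innovations are independent across parameters.
    Deterministic given the seed; SpO2 clipped to [0, 100], every vital
    clipped at 0.
    """
    rng = np.random.default_rng(config.seed)
    names = config.parameter_names
    n = len(names)
    phi = config.ar_coefficient
    c = config.cross_correlation
    load = np.sqrt(abs(c)) * np.ones(n)
    if c < 0:
        load[1::2] *= -1.0
    idio = math.sqrt(1.0 - abs(c))

    sds = np.array([config.innovation_sd(p) for p in names])
    mus = np.array([config.baselines[p][0] for p in names])
    stat_sd = sds / math.sqrt(1.0 - phi ** 2) if phi > 0 else sds

    # slow broadband wander: incommensurate sinusoids with seeded random
    # phases and period jitter (a single tone would leave long stretches
    # where the drift is flat and the stream unrealistically quiet)
    t_axis = np.arange(config.n_samples)

    def _unit_mixture() -> np.ndarray:
        out = np.zeros(config.n_samples)
        for i, base_period in enumerate(config.drift_periods):
            weight = 0.6 * 0.85 ** i
            period = base_period * (1.0 + 0.3 * (rng.random() - 0.5))
            phase = rng.random() * 2.0 * math.pi
            out += weight * np.sin(2.0 * math.pi * t_axis / period + phase)
        return out

    shared_wander = _unit_mixture()
    drift = np.zeros((config.n_samples, n))
    for j, name in enumerate(names):
        amp = config.drift_amp(name)
        drift[:, j] = amp * (idio * _unit_mixture()
                             + load[j] * shared_wander)

    values = np.empty((config.n_samples, n))
    # AR(1) noise starts at the stationary distribution: no burn-in
    r = stat_sd * rng.standard_normal(n)
    values[0] = mus + drift[0] + r
    for t in range(1, config.n_samples):
        r = phi * r + sds * rng.standard_normal(n)
        values[t] = mus + drift[t] + r

    values = np.clip(values, 0.0, None)
    for j, name in enumerate(names):
        if name in CLIP_BOUNDS:
            lo, hi = CLIP_BOUNDS[name]
            values[:, j] = np.clip(values[:, j], lo, hi)

    times = np.arange(config.n_samples, dtype=float) * config.sample_period
    return VitalSeries(parameter_names=names, values=values, times=times)


def as_labeled(series: VitalSeries) -> LabeledSeries:
    """Wrap an anomaly-free series with all-normal labels."""
    return LabeledSeries(series,
                         np.array([LABEL_NORMAL] * len(series), dtype=object))


def inject_event(labeled: LabeledSeries, event: EventSpec) -> LabeledSeries:
    """Return a copy with one anomaly injected.

    Affected values x become x*(1 + direction*magnitude) (or 0 for a
    dropout fault) over [start_index, start_index+duration); labels are
    set to the event kind.  Samples outside the window are untouched
    bit for bit.  Overlap with an existing event is rejected.
    """
    if event.start_index < 0 or event.stop_index > len(labeled):
        raise EventPlacementError(
            f"event window [{event.start_index}, {event.stop_index}) "
            f"outside series of length {len(labeled)}")
    for other in labeled.events:
        if (event.start_index < other.stop_index
                and other.start_index < event.stop_index):
            raise EventPlacementError(
                f"event at [{event.start_index}, {event.stop_index}) "
                f"overlaps existing event at "
                f"[{other.start_index}, {other.stop_index})")
    out = labeled.copy()
    sl = slice(event.start_index, event.stop_index)
    for p in event.affected_parameters:
        col = out.series.column(p)
        if event.dropout:
            col[sl] = 0.0
        else:
            d = event.direction[p]
            col[sl] = col[sl] * (1.0 + d * event.magnitude_fraction)
            lo, hi = CLIP_BOUNDS.get(p, (0.0, math.inf))
            col[sl] = np.clip(col[sl], lo, hi)
    out.labels[sl] = event.kind
    out.events.append(replace(event))
    return out


def _place_windows(rng: np.random.Generator, n_events: int, duration: int,
                   lo: int, hi: int, taken: list[tuple[int, int]],
                   gap: int) -> list[int]:
    """Draw non-overlapping start indices uniformly from [lo, hi)."""
    starts: list[int] = []
    occupied = list(taken)
    attempts = 0
    while len(starts) < n_events:
        attempts += 1
        if attempts > 10000:
            raise EventPlacementError(
                f"could not place {n_events} events of duration {duration} "
                f"in [{lo}, {hi}) without overlap")
        s = int(rng.integers(lo, hi - duration))
        win = (s - gap, s + duration + gap)
        if any(win[0] < e and b < win[1] for b, e in occupied):
            continue
        occupied.append((s, s + duration))
        starts.append(s)
    return starts


def make_benchmark(config: GeneratorConfig | None = None,
                   n_medical: int = 5,
                   n_faults: int = 10,
                   magnitudes: tuple[float, ...] = (0.50,),
                   seed: int | None = None,
                   event_duration: int = 8,
                   warmup: int = 60,
                   min_gap: int = 10) -> LabeledSeries:
    """Build a labeled benchmark stream.

    Medical events co-perturb four of the five vitals with the
    canonical deterioration signature (ABPmean up; HR, Pulse,
    Respiration, SpO2 down); sensor faults hit one parameter each,
    cycling through the parameter list and the requested magnitudes
    with alternating sign.  Placement is uniform at random outside the
    ``warmup`` prefix, with ``min_gap`` clean samples between events.
    Fully reproducible given (config, seed).
    """
    if config is None:
        config = GeneratorConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    series = generate_vitals(config)
    labeled = as_labeled(series)

    n_events = n_medical + n_faults
    if n_events == 0:
        return labeled
    span = len(series) - warmup
    if span < n_events * (event_duration + min_gap):
        raise EventPlacementError(
            f"{n_events} events of duration {event_duration} (+gap "
            f"{min_gap}) do not fit in {span} post-warmup samples")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    starts = _place_windows(rng, n_events, event_duration, warmup,
                            len(series), [], min_gap)
    names = series.parameter_names
    medical_params = [p for p in names if p in MEDICAL_EVENT_DIRECTIONS]
    if len(medical_params) <= len(names) // 2:
        raise EventPlacementError(
            "medical events must affect a strict majority of parameters")
    mags = tuple(magnitudes)

    events: list[EventSpec] = []
    for i in range(n_medical):
        events.append(EventSpec(
            kind=LABEL_MEDICAL,
            start_index=starts[i],
            duration=event_duration,
            affected_parameters=list(medical_params),
            magnitude_fraction=mags[i % len(mags)],
            direction={p: MEDICAL_EVENT_DIRECTIONS[p]
                       for p in medical_params},
        ))
    for i in range(n_faults):
        p = names[i % len(names)]
        events.append(EventSpec(
            kind=LABEL_FAULT,
            start_index=starts[n_medical + i],
            duration=event_duration,
            affected_parameters=[p],
            magnitude_fraction=mags[i % len(mags)],
            direction={p: +1 if i % 2 == 0 else -1},
        ))
    # inject in time order so diagnostics read naturally
    for ev in sorted(events, key=lambda e: e.start_index):
        labeled = inject_event(labeled, ev)
    return labeled


def write_labels(labeled: LabeledSeries, path) -> None:
    """Sidecar ground-truth CSV: columns ``index,label,event_id``."""
    event_id = np.full(len(labeled), -1, dtype=int)
    order = sorted(range(len(labeled.events)),
                   key=lambda i: labeled.events[i].start_index)
    for rank, i in enumerate(order):
        ev = labeled.events[i]
        event_id[ev.start_index:ev.stop_index] = rank
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("index,label,event_id\n")
        for i, (lab, eid) in enumerate(zip(labeled.labels, event_id)):
            fh.write(f"{i},{lab},{eid}\n")


def read_labels(path, series: VitalSeries) -> LabeledSeries:
    """Rebuild a LabeledSeries from a sidecar label CSV.

    Event windows are reconstructed from contiguous runs of equal
    event_id; affected parameters are unknown from labels alone, so the
    reconstructed EventSpecs carry the label kind and window only.
    """
    import pandas as pd

    df = pd.read_csv(path)
    labels = df["label"].to_numpy(dtype=object)
    labeled = LabeledSeries(series, labels)
    if "event_id" in df:
        eids = df["event_id"].to_numpy()
        for eid in sorted({e for e in eids if e >= 0}):
            idx = np.nonzero(eids == eid)[0]
            kind = labels[idx[0]]
            labeled.events.append(EventSpec(
                kind=str(kind), start_index=int(idx[0]),
                duration=int(idx[-1] - idx[0] + 1),
                affected_parameters=[series.parameter_names[0]]
                if kind == LABEL_FAULT else list(series.parameter_names),
                magnitude_fraction=0.5,
            ))
    return labeled
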