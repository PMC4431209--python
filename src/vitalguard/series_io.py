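"""Read, validate, and write multivariate vital-sign time series.

The on-disk dialect is a plain CSV modeled on PhysioNet "numerics"
exports: a mandatory header row ``t,<param1>,<param2>,...``, comma
separator, ``.`` decimal, UTF-8.  Non-numeric or blank cells become
explicit missing markers (NaN) — they are never silently dropped,
because a gap is itself evidence about a sensor.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Canonical column order when all five standard vitals are present.
CANONICAL_ORDER = ("ABPmean", "HR", "Pulse", "Respiration", "SpO2")

#: Native units of the standard vitals.
DEFAULT_UNITS = {
    "ABPmean": "mmHg",
    "HR": "bpm",
    "Pulse": "bpm",
    "Respiration": "breaths/min",
    "SpO2": "%",
}

#: Physical plausibility bounds used by validate_series (inclusive).
PHYSICAL_BOUNDS = {
    "ABPmean": (0.0, 300.0),
    "HR": (0.0, 300.0),
    "Pulse": (0.0, 300.0),
    "Respiration": (0.0, 120.0),
    "SpO2": (0.0, 100.0),
}


class SeriesFormatError(ValueError):
    """Raised for unparseable or structurally invalid series files."""


@dataclass
class VitalSeries:
    """Ordered multivariate samples A_t = (a_t,1 ... a_t,n).

    Attributes
    ----------
    parameter_names : list of str
        Ordered physiological parameter names (n entries).
    values : ndarray, shape (length, n)
        Sample vectors in native units; NaN marks a missing reading.
    times : ndarray, shape (length,)
        Strictly increasing sample indices or seconds.
    units : dict
        Parameter name -> unit string.
    """

    parameter_names: list[str]
    values: np.ndarray
    times: np.ndarray | None = None
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SeriesFormatError("values must be 2-D (instants x parameters)")
        if self.values.shape[1] != len(self.parameter_names):
            raise SeriesFormatError(
                f"{self.values.shape[1]} columns but "
                f"{len(self.parameter_names)} parameter names"
            )
        if len(self.parameter_names) < 1:
            raise SeriesFormatError("need at least one parameter")
        if self.times is None:
            self.times = np.arange(len(self.values), dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (len(self.values),):
                raise SeriesFormatError("times length must match values length")
        if not self.units:
            self.units = {
                p: DEFAULT_UNITS.get(p, "") for p in self.parameter_names
            }

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        """Number of physiological parameters."""
        return self.values.shape[1]

    def column(self, parameter: str) -> np.ndarray:
        """Return one parameter's samples (a view)."""
        try:
            j = self.parameter_names.index(parameter)
        except ValueError:
            raise KeyError(
                f"parameter {parameter!r} not in {self.parameter_names}"
            ) from None
        return self.values[:, j]

    def subset(self, parameters: list[str]) -> "VitalSeries":
        """Series restricted to the given parameters, order preserved."""
        idx = [self.parameter_names.index(p) for p in parameters]
        return VitalSeries(
            parameter_names=list(parameters),
            values=self.values[:, idx].copy(),
            times=self.times.copy(),
            units={p: self.units.get(p, "") for p in parameters},
        )

    def copy(self) -> "VitalSeries":
        return replace(
            self,
            parameter_names=list(self.parameter_names),
            values=self.values.copy(),
            times=self.times.copy(),
            units=dict(self.units),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.parameter_names)
        df.insert(0, "t", self.times)
        return df


def canonicalize_columns(names: list[str]) -> list[str]:
    """Reorder to (ABPmean, HR, Pulse, Respiration, SpO2) when all five
    are present; extra columns keep their relative order at the end."""
    if set(CANONICAL_ORDER) <= set(names):
        extra = [c for c in names if c not in CANONICAL_ORDER]
        return list(CANONICAL_ORDER) + extra
    return list(names)


def read_series(path, *, canonical: bool = True) -> VitalSeries:
    """Parse a vital-sign CSV into a :class:`VitalSeries`.

    A ``t`` (or ``time``) first column is used as the time axis; when
    absent the row index is the time.  Non-numeric cells become NaN.
    Ragged rows raise :class:`SeriesFormatError` with the line number.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if not text.strip():
        raise SeriesFormatError(f"{path}: empty file")
    lines = text.splitlines()
    header = [c.strip() for c in lines[0].split(",")]
    width = len(header)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) != width:
            raise SeriesFormatError(
                f"{path}:{lineno}: ragged row ({len(cells)} cells, "
                f"expected {width})"
            )
        rows.append(cells)
    df = pd.read_csv(
        io.StringIO(text), dtype=str, skip_blank_lines=True, engine="python"
    )
    df.columns = header
    # non-numeric cells -> NaN, explicitly
    df = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))

    if header[0].lower() in ("t", "time", "index"):
        times = df.iloc[:, 0].to_numpy(dtype=float)
        params = header[1:]
        data = df.iloc[:, 1:]
    else:
        times = None
        params = header
        data = df
    if canonical:
        order = canonicalize_columns(params)
        data = data[order]
        params = order
    return VitalSeries(
        parameter_names=list(params),
        values=data.to_numpy(dtype=float),
        times=times,
    )


def write_series(series: VitalSeries, path) -> None:
    """Write a series as CSV with header ``t,<param1>,...``.

    Floats carry enough digits (repr-shortest via %.10g) that a
    write -> read round trip is lossless at working precision; genuine
    zeros (e.g., a dropped-out SpO2 sensor) are preserved verbatim.
    """
    df = series.to_frame()
    df.to_csv(path, index=False, float_format="%.10g")


@dataclass
class Finding:
    kind: str  # missing_run | non_monotone_time | out_of_range
    parameter: str | None
    start: int
    end: int  # inclusive
    detail: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    def __bool__(self) -> bool:  # truthy when clean
        return not self.findings

    @property
    def is_clean(self) -> bool:
        return not self.findings

    def by_kind(self, kind: str) -> list[Finding]:
        return [f for f in self.findings if f.kind == kind]


def validate_series(series: VitalSeries) -> ValidationReport:
    """Report missing-value runs, non-monotone times and physically
    implausible values.  Pure: never mutates the series."""
    findings: list[Finding] = []

    dt = np.diff(series.times)
    for i in np.nonzero(dt <= 0)[0]:
        findings.append(
            Finding(
                "non_monotone_time", None, int(i), int(i + 1),
                f"times[{i}]={series.times[i]} >= times[{i+1}]={series.times[i+1]}",
            )
        )

    for j, name in enumerate(series.parameter_names):
        col = series.values[:, j]
        miss = np.isnan(col)
        # contiguous runs of missing values
        if miss.any():
            edges = np.diff(miss.astype(int))
            starts = list(np.nonzero(edges == 1)[0] + 1)
            ends = list(np.nonzero(edges == -1)[0])
            if miss[0]:
                starts.insert(0, 0)
            if miss[-1]:
                ends.append(len(col) - 1)
            for s, e in zip(starts, ends):
                findings.append(
                    Finding("missing_run", name, int(s), int(e),
                            f"{e - s + 1} missing value(s)")
                )
        lo, hi = PHYSICAL_BOUNDS.get(name, (0.0, math.inf))
        bad = np.nonzero((col < lo) | (col > hi))[0]
        for i in bad:
            findings.append(
                Finding("out_of_range", name, int(i), int(i),
                        f"{name}={col[i]} outside [{lo}, {hi}]")
            )
    return ValidationReport(findings)
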