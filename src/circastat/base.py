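"""Model/Results scaffolding shared by the rhythm-detection methods.

Each detection method is a model class constructed from a
:class:`~circastat.timeseries.TimeSeries` (plus its scan grids); ``fit()``
returns a :class:`RhythmResults` carrying the verdict (best period,
amplitude, acrophase, raw and adjusted p), the winning reference, and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import TimeSeries

__all__ = [
    "DEFAULT_PERIODS",
    "RhythmResult",
    "RhythmResults",
    "RhythmModel",
    "default_lag_step",
    "robust_amplitude",
    "scale_to_data",
]

#: candidate periods scanned by default: the circadian band at half-hour
#: resolution (matches the granularity of reported period estimates)
DEFAULT_PERIODS = tuple(20.0 + 0.5 * k for k in range(17))


@dataclass
class RhythmResult:
    """One method's verdict for one series or group.

    ``adj_p`` is the within-series Bonferroni-adjusted p (ADJ.P);
    ``bh_q`` the across-series Benjamini-Hochberg q (BH.Q), unset unless
    batch adjustment in BH mode was applied.
    """

    label: str
    method: str
    period: float
    amplitude: float
    acrophase: float
    p_raw: float
    adj_p: float
    bh_q: "float | None" = None

    def __post_init__(self):
        if np.isfinite(self.p_raw) and self.adj_p < self.p_raw - 1e-12:
            raise ValueError("adjusted p cannot be smaller than raw p")


class RhythmResults:
    """Results container for one fitted rhythm model.

    Exposes the :class:`RhythmResult` fields as attributes, the grid size
    used for the within-series Bonferroni correction, and a dense best-fit
    curve for plotting.
    """

    def __init__(self, model: "RhythmModel", record: RhythmResult, n_tests: int):
        self.model = model
        self.record = record
        self.n_tests = int(n_tests)

    # attribute delegation to the record ------------------------------
    @property
    def label(self):
        return self.record.label

    @property
    def method(self):
        return self.record.method

    @property
    def period(self):
        return self.record.period

    @property
    def amplitude(self):
        return self.record.amplitude

    @property
    def acrophase(self):
        return self.record.acrophase

    @property
    def p_raw(self):
        return self.record.p_raw

    @property
    def adj_p(self):
        return self.record.adj_p

    @property
    def bh_q(self):
        return self.record.bh_q

    @bh_q.setter
    def bh_q(self, q):
        self.record.bh_q = q

    @property
    def detected(self) -> bool:
        """Rhythmic at the conventional ADJ.P < 0.05 threshold."""
        return bool(np.isfinite(self.adj_p) and self.adj_p < 0.05)

    # ------------------------------------------------------------------
    def fit_curve(self, times) -> np.ndarray:
        """Best-fit waveform evaluated at arbitrary times (data units)."""
        raise NotImplementedError

    def _extra_summary_rows(self):
        return []

    def summary(self) -> str:
        r = self.record
        rows = [
            ("label", r.label),
            ("method", r.method),
            ("n obs", self.model.ts.n),
            ("PER (h)", f"{r.period:.6g}"),
            ("AMP", f"{r.amplitude:.6g}"),
            ("acrophase (h)", f"{r.acrophase:.6g}"),
            ("p (raw)", f"{r.p_raw:.4g}"),
            ("ADJ.P", f"{r.adj_p:.4g}"),
            ("BH.Q", "-" if r.bh_q is None else f"{r.bh_q:.4g}"),
            ("tests in scan", self.n_tests),
        ]
        rows += self._extra_summary_rows()
        width = max(len(k) for k, _ in rows)
        title = f"Rhythm scan results: {r.method}"
        bar = "=" * max(len(title), width + 24)
        body = "\n".join(f"{k:<{width}}  {v}" for k, v in rows)
        return f"{bar}\n{title}\n{bar}\n{body}\n{bar}"

    def plot(self, path, **kwargs):
        from .viz import plot_fit

        return plot_fit(self.model.ts, self, self.fit_curve, path, **kwargs)

    def __repr__(self):
        r = self.record
        return (
            f"<{type(self).__name__} {r.method} label={r.label!r} "
            f"PER={r.period:.3g} ADJ.P={r.adj_p:.3g}>"
        )


class RhythmModel:
    """Base class: a detection method bound to one time series."""

    method = "abstract"

    def __init__(self, ts: TimeSeries, periods=None):
        if not isinstance(ts, TimeSeries):
            raise TypeError("ts must be a TimeSeries")
        self.ts = ts
        self.periods = tuple(float(p) for p in (periods or DEFAULT_PERIODS))
        if not self.periods or any(p <= 0 for p in self.periods):
            raise ValueError("periods must be positive and non-empty")

    @classmethod
    def from_dataframe(cls, df, column, time_column="Time", label=None, **kwargs):
        """Build a model from a tidy DataFrame with a time column."""
        ts = TimeSeries(
            np.asarray(df[time_column], dtype=float),
            np.asarray(df[column], dtype=float),
            label=label or str(column),
        )
        return cls(ts, **kwargs)

    def fit(self) -> RhythmResults:
        raise NotImplementedError


def default_lag_step(ts: TimeSeries, floor: float = 1.0) -> float:
    """Default lag-grid resolution: the (median) sampling interval, >= 1 h."""
    return max(floor, ts.median_interval)


def robust_amplitude(values) -> float:
    """Rank-method amplitude proxy: half the spread between the mean of the
    top and bottom deciles of the data."""
    v = np.sort(np.asarray(values, dtype=float))
    k = max(1, int(round(0.1 * v.size)))
    return float((v[-k:].mean() - v[:k].mean()) / 2.0)


def scale_to_data(template: np.ndarray, values: np.ndarray) -> "tuple[float, float]":
    """Least-squares scale and offset mapping a reference template into data
    units: argmin over (k, b) of sum (y - k*template - b)^2."""
    X = np.column_stack([np.asarray(template, float), np.ones(len(values))])
    (k, b), *_ = np.linalg.lstsq(X, np.asarray(values, float), rcond=None)
    return float(k), float(b)
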