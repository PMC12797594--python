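"""Cosine-Kendall: nonparametric cosine concordance.

The data are ranked and compared against phase-shifted cosine references on
a period x lag grid; concordance is scored with Kendall's tau, which makes
the verdict invariant to any strictly monotone transform of the data and
robust to outliers.  The minimum raw p over the grid wins and is
Bonferroni-adjusted by the total number of (period, lag) tests.
"""

from __future__ import annotations

import numpy as np

from .base import DEFAULT_PERIODS, RhythmModel, default_lag_step
from .rankscan import RankScanResults, run_rank_scan
from .templates import TemplateSpec, cosine_reference
from .timeseries import TimeSeries

__all__ = ["CosineKendall", "scan_cosine_kendall", "cosine_reference"]


def _lag_grid(period: float, lag_step: float) -> np.ndarray:
    return np.arange(0.0, period, lag_step)


class CosineKendall(RhythmModel):
    """Cosine concordance test scanned over periods and peak-time lags.

    Parameters
    ----------
    ts : TimeSeries
    periods : iterable of float, optional
        Candidate periods in hours (default 20-28 h).
    lag_step : float, optional
        Lag-grid resolution in hours; defaults to the series' (median)
        sampling interval, floored at 1 h.
    """

    method = "cosine-kendall"

    def __init__(self, ts: TimeSeries, periods=None, lag_step=None):
        super().__init__(ts, periods=periods)
        self.lag_step = float(lag_step) if lag_step else default_lag_step(ts)
        if self.lag_step <= 0:
            raise ValueError("lag_step must be positive")

    def template_grid(self) -> "list[TemplateSpec]":
        return [
            TemplateSpec(shape="cosine", period=p, lag=float(lag))
            for p in self.periods
            for lag in _lag_grid(p, self.lag_step)
        ]

    def fit(self) -> RankScanResults:
        specs = self.template_grid()
        # ties on p: prefer larger (signed) tau, then smaller period, smaller lag
        return run_rank_scan(
            self, specs, lambda i, tau: (-tau, specs[i].period, specs[i].lag)
        )


def scan_cosine_kendall(
    ts: TimeSeries, periods=DEFAULT_PERIODS, lag_step=None
) -> RankScanResults:
    """Functional form of :class:`CosineKendall`."""
    return CosineKendall(ts, periods=periods, lag_step=lag_step).fit()
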