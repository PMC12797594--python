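"""Python-style JTK: rank concordance against triangle templates.

A reimplementation of the JTK_CYCLE idea that replaces the
Jonckheere-Terpstra statistic with Kendall's tau for both similarity and
significance.  The data are compared against a library of symmetric and
asymmetric triangle templates over a period x lag x asymmetry grid; because
templates are evaluated pointwise, regular and irregular sampling are
supported alike.  The test is two-sided on |tau| (a trough-aligned template
is as informative as a peak-aligned one), the minimum-p winner is
Bonferroni-adjusted by the grid size, and across many series the
Benjamini-Hochberg procedure can replace Bonferroni (BH.Q vs ADJ.P).
"""

from __future__ import annotations

import numpy as np

from .base import DEFAULT_PERIODS, RhythmModel, default_lag_step
from .rankscan import RankScanResults, run_rank_scan
from .stats import bh_adjust
from .templates import TemplateSpec, build_template
from .timeseries import TimeSeries

__all__ = [
    "DEFAULT_ASYMMETRIES",
    "LARGE_BATCH_CUTOFF",
    "PythonJTK",
    "scan_jtk",
    "batch_adjust",
    "TemplateSpec",
    "build_template",
]

#: default rise-fraction grid: symmetric tent plus moderate/strong asymmetry
DEFAULT_ASYMMETRIES = (0.2, 0.35, 0.5, 0.65, 0.8)

#: series count at or above which auto batch adjustment switches to BH
LARGE_BATCH_CUTOFF = 20


class PythonJTK(RhythmModel):
    """Triangle-template rank test scanned over period, lag and asymmetry.

    Parameters
    ----------
    ts : TimeSeries
    periods : iterable of float, optional
        Candidate periods, hours (default 20-28).
    lag_step : float, optional
        Lag-grid resolution in hours; defaults to the sampling interval,
        floored at 1 h.
    asymmetries : iterable of float, optional
        Rise fractions in (0, 1); 0.5 is the symmetric tent.
    """

    method = "jtk"

    def __init__(self, ts: TimeSeries, periods=None, lag_step=None, asymmetries=None):
        super().__init__(ts, periods=periods)
        self.lag_step = float(lag_step) if lag_step else default_lag_step(ts)
        if self.lag_step <= 0:
            raise ValueError("lag_step must be positive")
        self.asymmetries = tuple(float(a) for a in (asymmetries or DEFAULT_ASYMMETRIES))
        if not self.asymmetries or any(not 0 < a < 1 for a in self.asymmetries):
            raise ValueError("asymmetries must lie strictly inside (0, 1)")

    def template_grid(self) -> "list[TemplateSpec]":
        return [
            TemplateSpec(shape="triangle", period=p, lag=float(lag), asymmetry=a)
            for p in self.periods
            for lag in np.arange(0.0, p, self.lag_step)
            for a in self.asymmetries
        ]

    def fit(self, ts: "TimeSeries | None" = None) -> RankScanResults:
        specs = self.template_grid()
        # two-sided on |tau|; ties prefer larger |tau|, smaller period,
        # smaller lag, then asymmetry closest to symmetric
        return run_rank_scan(
            self,
            specs,
            lambda i, tau: (
                -abs(tau),
                specs[i].period,
                specs[i].lag,
                abs(specs[i].asymmetry - 0.5),
            ),
            ts=ts,
        )


def scan_jtk(
    ts: TimeSeries,
    periods=DEFAULT_PERIODS,
    lag_step=None,
    asymmetries=DEFAULT_ASYMMETRIES,
) -> RankScanResults:
    """Functional form of :class:`PythonJTK`."""
    return PythonJTK(
        ts, periods=periods, lag_step=lag_step, asymmetries=asymmetries
    ).fit()


def batch_adjust(results, mode: str = "auto", large_cutoff: int = LARGE_BATCH_CUTOFF):
    """Across-series multiple-testing control for a batch of scan results.

    ``bh`` sets BH.Q by Benjamini-Hochberg over the series' minimum raw
    p-values; ``bonferroni`` keeps only the within-series ADJ.P (BH.Q left
    unset); ``auto`` picks BH for large batches (>= ``large_cutoff`` series)
    and Bonferroni otherwise.  All results must come from the same method.
    Adjustment is applied in place; the list is returned for convenience.
    """
    results = list(results)
    if not results:
        return results
    methods = {r.method for r in results}
    if len(methods) > 1:
        raise ValueError(f"mixed methods in one batch: {sorted(methods)}")
    if mode not in ("auto", "bonferroni", "bh"):
        raise ValueError(f"unknown adjustment mode {mode!r}")
    if mode == "auto":
        mode = "bh" if len(results) >= large_cutoff else "bonferroni"
    if mode == "bh":
        qs = bh_adjust([r.p_raw for r in results])
        for r, q in zip(results, qs):
            r.bh_q = float(q)
    else:
        for r in results:
            r.bh_q = None
    return results
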