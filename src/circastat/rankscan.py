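"""Generic template-scan driver shared by the rank-based methods.

A scan evaluates Kendall's tau between the data and every template in a
grid, picks the minimum-p winner under a method-specific tie-break, and
Bonferroni-adjusts the winning p by the grid size.
"""

from __future__ import annotations

import numpy as np

from .base import RhythmModel, RhythmResult, RhythmResults, robust_amplitude, scale_to_data
from .stats import KendallScanner, TemplateBank, bonferroni_adjust
from .templates import TemplateSpec, build_template
from .timeseries import TimeSeries

__all__ = ["RankScanResults", "run_rank_scan", "template_peak_time"]

# banks of evaluated templates are expensive to build and shared by every
# series scanned on the same time grid with the same template grid
_BANK_CACHE: "dict[tuple, TemplateBank]" = {}
_BANK_CACHE_MAX = 8


def _bank_for(specs: "tuple[TemplateSpec, ...]", times: np.ndarray) -> TemplateBank:
    key = (specs, times.tobytes())
    bank = _BANK_CACHE.get(key)
    if bank is None:
        bank = TemplateBank(np.vstack([build_template(s, times) for s in specs]))
        if len(_BANK_CACHE) >= _BANK_CACHE_MAX:
            _BANK_CACHE.pop(next(iter(_BANK_CACHE)))
        _BANK_CACHE[key] = bank
    return bank


class RankScanResults(RhythmResults):
    """Results of a Kendall-tau template scan.

    ``winner`` is the best-scoring :class:`TemplateSpec` (None for a
    degenerate, constant input), ``tau`` its rank correlation.  The best-fit
    curve for plotting is the winning template least-squares-scaled into
    data units.
    """

    def __init__(self, model, record, n_tests, winner, tau, analyzed_ts=None):
        super().__init__(model, record, n_tests)
        self.winner: "TemplateSpec | None" = winner
        self.tau = float(tau)
        #: series the scan actually ran on (differs from model.ts after pre-whitening)
        self.analyzed_ts: TimeSeries = analyzed_ts or model.ts
        self._scale = None

    def template_values(self, times) -> np.ndarray:
        if self.winner is None:
            raise ValueError("degenerate result has no winning template")
        return build_template(self.winner, times)

    @property
    def scale(self) -> "tuple[float, float]":
        """(k, b) minimizing sum (y - k*template - b)^2 on the analyzed series."""
        if self._scale is None:
            k, b = scale_to_data(
                self.template_values(self.analyzed_ts.times), self.analyzed_ts.values
            )
            self._scale = (k, b)
        return self._scale

    def fit_curve(self, times) -> np.ndarray:
        k, b = self.scale
        return k * self.template_values(times) + b

    def _extra_summary_rows(self):
        rows = [("tau", f"{self.tau:.4g}")]
        if self.winner is not None:
            rows.append(("winning template", _spec_text(self.winner)))
        return rows


def _spec_text(spec: TemplateSpec) -> str:
    txt = f"{spec.shape} P={spec.period:g} lag={spec.lag:g}"
    if spec.shape == "triangle":
        txt += f" a={spec.asymmetry:g}"
    if spec.shape == "harmonic":
        txt += f" gamma={spec.harmonic_weight:g} lag2={spec.harmonic_lag:g}"
    return txt


def template_peak_time(spec: TemplateSpec, sign: float = 1.0, resolution: float = 0.01) -> float:
    """Peak time (hours in [0, period)) of the possibly sign-flipped template.

    For concordant (sign >= 0) cosine and triangle templates this is the lag
    itself; for discordant winners (negative tau, i.e. a trough-aligned
    template) the fitted waveform is the negated template and its peak sits
    elsewhere in the cycle, located here on a dense grid.
    """
    if sign >= 0 and spec.shape in ("cosine", "triangle"):
        return spec.lag
    grid = np.arange(0.0, spec.period, resolution)
    vals = build_template(spec, grid)
    if sign < 0:
        vals = -vals
    return float(grid[int(np.argmax(vals))])


def _degenerate_record(ts: TimeSeries, method: str) -> RhythmResult:
    return RhythmResult(
        label=ts.label,
        method=method,
        period=float("nan"),
        amplitude=0.0,
        acrophase=float("nan"),
        p_raw=1.0,
        adj_p=1.0,
    )


def run_rank_scan(
    model: RhythmModel,
    specs: "list[TemplateSpec]",
    tie_key,
    ts: "TimeSeries | None" = None,
) -> RankScanResults:
    """Score every template spec against the series and build results.

    ``tie_key(i, tau)`` returns the tie-break tuple appended after the raw p
    when ranking grid point ``i``; lower sorts first.  ``ts`` overrides the
    model's series (used by the AR-corrected path to scan a filtered copy).
    """
    ts = ts or model.ts
    if not specs:
        raise ValueError("empty template grid")
    scanner = KendallScanner(ts.values)
    if scanner.degenerate:
        rec = _degenerate_record(ts, model.method)
        return RankScanResults(model, rec, len(specs), None, 0.0, analyzed_ts=ts)
    taus, ps = scanner.scan(_bank_for(tuple(specs), ts.times))
    order = sorted(range(len(specs)), key=lambda i: (ps[i],) + tie_key(i, taus[i]))
    best = order[0]
    win = specs[best]
    m = len(specs)
    rec = RhythmResult(
        label=ts.label,
        method=model.method,
        period=win.period,
        amplitude=robust_amplitude(ts.values),
        acrophase=template_peak_time(win, sign=taus[best]),
        p_raw=float(ps[best]),
        adj_p=bonferroni_adjust(float(ps[best]), m),
    )
    return RankScanResults(model, rec, m, win, taus[best], analyzed_ts=ts)
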