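"""Single-component cosinor regression.

The cosinor model linearizes a cosine of known period P (angular frequency
w = 2*pi/P)::

    y = M + beta1*cos(w*t) + beta2*sin(w*t) + eps

and is fitted by ordinary least squares.  Rhythmicity is the F-test of
beta1 = beta2 = 0 with (2, n-3) degrees of freedom; amplitude is
sqrt(beta1^2 + beta2^2) and the acrophase is the peak time of the fitted
cosine within one period.  A scan over candidate periods picks the smallest
raw p and Bonferroni-adjusts it by the number of periods tried.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .base import (
    DEFAULT_PERIODS,
    RhythmModel,
    RhythmResult,
    RhythmResults,
)
from .errors import ScanError, SingularFitError
from .stats import bonferroni_adjust
from .timeseries import TimeSeries

__all__ = ["CosinorFit", "Cosinor", "CosinorResults", "fit_cosinor", "scan_cosinor"]


@dataclass
class CosinorFit:
    """OLS cosinor fit at one fixed period."""

    mesor: float
    beta_cos: float
    beta_sin: float
    period: float
    amplitude: float
    acrophase: float
    F_stat: float
    df: "tuple[int, int]"
    p_raw: float
    fitted: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)

    def curve(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        w = 2.0 * np.pi / self.period
        return self.mesor + self.beta_cos * np.cos(w * t) + self.beta_sin * np.sin(w * t)


def fit_cosinor(ts: TimeSeries, period: float) -> CosinorFit:
    """Fit the cosinor model at a single candidate period.

    Raises :class:`SingularFitError` when the design matrix
    ``[1, cos(wt), sin(wt)]`` is rank deficient (period aliases the
    sampling grid).
    """
    if period <= 0:
        raise ValueError("period must be positive")
    t, y = ts.times, ts.values
    n = ts.n
    w = 2.0 * np.pi / period
    X = np.column_stack([np.ones(n), np.cos(w * t), np.sin(w * t)])
    if np.linalg.matrix_rank(X) < 3:
        raise SingularFitError(
            f"cosinor design singular at period {period} h for series {ts.label!r}"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    df = (2, n - 3)
    scale = max(tss, 1.0)
    if rss <= scale * 1e-14:  # (near-)perfect fit, or constant input
        ess = max(tss - rss, 0.0)
        F = np.inf if ess > scale * 1e-14 else 0.0
    else:
        F = max(0.0, (tss - rss) / 2.0 / (rss / df[1]))
    p = 0.0 if np.isinf(F) else float(sps.f.sf(F, *df))
    amp = float(np.hypot(beta[1], beta[2]))
    acro = float(np.arctan2(beta[2], beta[1]) * period / (2.0 * np.pi)) % period
    if period - acro < 1e-9:  # keep acrophase in [0, period)
        acro = 0.0
    return CosinorFit(
        mesor=float(beta[0]),
        beta_cos=float(beta[1]),
        beta_sin=float(beta[2]),
        period=float(period),
        amplitude=amp,
        acrophase=acro,
        F_stat=float(F),
        df=df,
        p_raw=p,
        fitted=fitted,
        residuals=resid,
    )


class CosinorResults(RhythmResults):
    """Cosinor scan results; ``best_fit`` is the winning :class:`CosinorFit`."""

    def __init__(self, model, record, n_tests, best_fit: CosinorFit, period_fits):
        super().__init__(model, record, n_tests)
        self.best_fit = best_fit
        self.period_fits = period_fits  # period -> CosinorFit

    def fit_curve(self, times) -> np.ndarray:
        return self.best_fit.curve(times)

    def _extra_summary_rows(self):
        f = self.best_fit
        return [
            ("MESOR", f"{f.mesor:.6g}"),
            ("F", f"{f.F_stat:.4g}"),
            ("df", f"{f.df}"),
        ]


class Cosinor(RhythmModel):
    """Cosinor regression scanned over candidate periods.

    Parameters
    ----------
    ts : TimeSeries
    periods : iterable of float, optional
        Candidate periods in hours (default: 20-28 h, 1-h step).
    """

    method = "cosinor"

    def fit(self) -> CosinorResults:
        fits: "dict[float, CosinorFit]" = {}
        errors = []
        for p in sorted(self.periods):
            try:
                fits[p] = fit_cosinor(self.ts, p)
            except SingularFitError as exc:  # propagate per-period, fail if all do
                errors.append(exc)
        if not fits:
            raise ScanError(
                f"every candidate period failed for series {self.ts.label!r}: {errors}"
            )
        # argmin raw p; ties resolved to the smallest period (ascending order)
        best_p = min(fits, key=lambda p: (fits[p].p_raw, p))
        best = fits[best_p]
        m = len(self.periods)
        record = RhythmResult(
            label=self.ts.label,
            method=self.method,
            period=best.period,
            amplitude=best.amplitude,
            acrophase=best.acrophase,
            p_raw=best.p_raw,
            adj_p=bonferroni_adjust(best.p_raw, m),
        )
        return CosinorResults(self, record, m, best, fits)


def scan_cosinor(ts: TimeSeries, periods=DEFAULT_PERIODS) -> CosinorResults:
    """Functional form of :class:`Cosinor`: fit every candidate period and
    report the minimum-p winner with Bonferroni-adjusted p."""
    return Cosinor(ts, periods=periods).fit()
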