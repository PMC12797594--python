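"""Harmonic-Cosinor: bimodal rhythm detection with two-component references.

Animal behavior under 12:12 light/dark cycles (e.g. Drosophila locomotion)
is often bimodal within one circadian cycle; a single cosine cannot express
two peaks.  This module scores the data against composite references
combining a fundamental and a gamma-weighted second harmonic,
``cos(2*pi*(t - lag1)/P) + gamma*cos(4*pi*(t - lag2)/P)``, using Kendall's
tau exactly as in the cosine-Kendall and JTK scans.  A two-component OLS
fit (multiple-component cosinor) is provided for visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .base import DEFAULT_PERIODS, RhythmModel, default_lag_step
from .errors import SingularFitError
from .rankscan import RankScanResults, run_rank_scan
from .templates import TemplateSpec, harmonic_reference
from .timeseries import TimeSeries

__all__ = [
    "DEFAULT_GAMMAS",
    "HarmonicCosinor",
    "scan_harmonic",
    "harmonic_reference",
    "HarmonicFit",
    "fit_harmonic_ols",
]

#: default second-harmonic weights: unimodal, moderately and strongly bimodal
DEFAULT_GAMMAS = (0.0, 0.5, 1.0)

#: default second-harmonic lag offsets, as fractions of the period
DEFAULT_LAG2_FRACTIONS = (0.0, 1.0 / 8.0, 1.0 / 4.0)


class HarmonicCosinor(RhythmModel):
    """Two-component composite-reference scan.

    The grid covers period x lag1 x gamma x lag2 where lag2 runs over
    ``lag1 + {0, P/8, P/4}``; gamma = 0 collapses to a plain cosine and is
    included once per (period, lag1) so the unimodal case is always in the
    library without duplicated tests.
    """

    method = "harmonic"

    def __init__(
        self,
        ts: TimeSeries,
        periods=None,
        lag_step=None,
        gammas=None,
        lag2_fractions=None,
    ):
        super().__init__(ts, periods=periods)
        self.lag_step = float(lag_step) if lag_step else default_lag_step(ts)
        if self.lag_step <= 0:
            raise ValueError("lag_step must be positive")
        self.gammas = tuple(float(g) for g in (gammas or DEFAULT_GAMMAS))
        if any(g < 0 for g in self.gammas):
            raise ValueError("gamma weights must be non-negative")
        self.lag2_fractions = tuple(
            float(f) for f in (lag2_fractions or DEFAULT_LAG2_FRACTIONS)
        )

    def template_grid(self) -> "list[TemplateSpec]":
        specs = []
        for p in self.periods:
            for lag1 in np.arange(0.0, p, self.lag_step):
                for g in self.gammas:
                    offsets = self.lag2_fractions if g > 0 else (0.0,)
                    for frac in offsets:
                        specs.append(
                            TemplateSpec(
                                shape="harmonic",
                                period=p,
                                lag=float(lag1),
                                harmonic_weight=g,
                                harmonic_lag=float((lag1 + frac * p) % p),
                            )
                        )
        return specs

    def fit(self) -> RankScanResults:
        specs = self.template_grid()
        return run_rank_scan(
            self,
            specs,
            lambda i, tau: (
                -abs(tau),
                specs[i].period,
                specs[i].lag,
                specs[i].harmonic_weight,
                specs[i].harmonic_lag,
            ),
        )


def scan_harmonic(
    ts: TimeSeries,
    periods=DEFAULT_PERIODS,
    lag_step=None,
    gammas=DEFAULT_GAMMAS,
) -> RankScanResults:
    """Functional form of :class:`HarmonicCosinor`."""
    return HarmonicCosinor(ts, periods=periods, lag_step=lag_step, gammas=gammas).fit()


# ---------------------------------------------------------------------------
# two-component OLS fit (multiple-component cosinor) for overlays
# ---------------------------------------------------------------------------

@dataclass
class HarmonicFit:
    """OLS fit of mesor + fundamental + second harmonic at one period."""

    mesor: float
    beta_cos: float
    beta_sin: float
    beta_cos2: float
    beta_sin2: float
    period: float
    F_stat: float
    df: "tuple[int, int]"
    p_raw: float
    fitted: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)

    def curve(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        w = 2.0 * np.pi / self.period
        return (
            self.mesor
            + self.beta_cos * np.cos(w * t)
            + self.beta_sin * np.sin(w * t)
            + self.beta_cos2 * np.cos(2 * w * t)
            + self.beta_sin2 * np.sin(2 * w * t)
        )


def fit_harmonic_ols(ts: TimeSeries, period: float) -> HarmonicFit:
    """Two-component cosinor by OLS on [1, cos, sin, cos2, sin2].

    Requires n >= 6 (five parameters plus one residual df); the overall
    F-test of all four trigonometric coefficients has df (4, n-5).
    """
    if ts.n < 6:
        raise ValueError("two-component cosinor needs at least 6 points")
    if period <= 0:
        raise ValueError("period must be positive")
    t, y = ts.times, ts.values
    n = ts.n
    w = 2.0 * np.pi / period
    X = np.column_stack(
        [np.ones(n), np.cos(w * t), np.sin(w * t), np.cos(2 * w * t), np.sin(2 * w * t)]
    )
    if np.linalg.matrix_rank(X) < 5:
        raise SingularFitError(
            f"harmonic design singular at period {period} h for {ts.label!r}"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    df = (4, n - 5)
    scale = max(tss, 1.0)
    if rss <= scale * 1e-14:
        F = np.inf if tss - rss > scale * 1e-14 else 0.0
    else:
        F = max(0.0, (tss - rss) / df[0] / (rss / df[1]))
    p = 0.0 if np.isinf(F) else float(sps.f.sf(F, *df))
    return HarmonicFit(
        mesor=float(beta[0]),
        beta_cos=float(beta[1]),
        beta_sin=float(beta[2]),
        beta_cos2=float(beta[3]),
        beta_sin2=float(beta[4]),
        period=float(period),
        F_stat=float(F),
        df=df,
        p_raw=p,
        fitted=fitted,
        residuals=resid,
    )
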