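"""Chronobiology figures: grouped previews, double-plotted actograms,
best-fit overlays.

All functions write a figure file whose format follows the extension
(PNG/SVG/PDF) and leave the input data untouched.  SVG output is
deterministic for identical inputs (fixed hash salt, no timestamps).
"""

from __future__ import annotations

import warnings

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .timeseries import GroupedStudy, TimeSeries

__all__ = ["plot_preview", "plot_actogram", "plot_fit", "actogram_rows"]

plt.rcParams["svg.hashsalt"] = "circastat"


def _save(fig, path):
    path = str(path)
    if path.lower().endswith(".svg"):
        fig.savefig(path, metadata={"Date": None})
    else:
        fig.savefig(path)
    plt.close(fig)
    return path


def plot_preview(study: GroupedStudy, spans=(), path="preview.png", slot: int = 1):
    """Grouped time-series preview with optional shaded background spans.

    ``spans`` is a list of (start, end, color) tuples, typically marking
    light/dark periods.  Groups with several members plot the member mean
    with a +/- SD band when their time grids agree, individual curves
    otherwise.
    """
    if not study.groups:
        raise ValueError("empty study")
    fig, ax = plt.subplots(figsize=(8, 4))
    tmin = min(ts.times[0] for ts in study.all_series())
    tmax = max(ts.times[-1] for ts in study.all_series())
    for start, end, color in spans:
        if end < tmin or start > tmax:
            warnings.warn(f"span ({start}, {end}) outside data range; clipped")
        ax.axvspan(max(start, tmin), min(end, tmax), color=color, alpha=0.3, zorder=0)
    for label in study.labels:
        members = study.members(label, slot)
        if not members:
            continue
        color = study.colors.get(label)
        t0 = members[0].times
        same_grid = all(
            m.n == members[0].n and np.allclose(m.times, t0) for m in members
        )
        if len(members) > 1 and same_grid:
            stack = np.vstack([m.values for m in members])
            mean, sd = stack.mean(axis=0), stack.std(axis=0, ddof=1)
            ax.plot(t0, mean, color=color, label=label)
            ax.fill_between(t0, mean - sd, mean + sd, color=color, alpha=0.2)
        else:
            for i, m in enumerate(members):
                ax.plot(m.times, m.values, color=color, label=label if i == 0 else None)
    ax.set_xlabel("Time (h)")
    ax.set_ylabel("Value")
    ax.legend()
    fig.tight_layout()
    return _save(fig, path)


def actogram_rows(
    ts: TimeSeries, day_length: float = 24.0
) -> "list[tuple[np.ndarray, np.ndarray]]":
    """Split a series into per-day (time-of-day, value) segments.

    Day d covers [d*day_length, (d+1)*day_length) from the series start;
    times are reduced to hours within the day.  This is the binning used by
    :func:`plot_actogram`, exposed for testing and reuse.
    """
    t = ts.times - ts.times[0]
    n_days = int(np.ceil((t[-1] + 1e-9) / day_length))
    n_days = max(n_days, 1)
    rows = []
    for d in range(n_days):
        mask = (t >= d * day_length) & (t < (d + 1) * day_length)
        rows.append((t[mask] - d * day_length, ts.values[mask]))
    return rows


def plot_actogram(
    ts: TimeSeries,
    path="actogram.png",
    day_length: float = 24.0,
    double_plot: bool = True,
):
    """Double-plotted actogram: one row per day, each showing day d followed
    by day d+1, bars normalized to the global maximum."""
    if ts.duration < day_length:
        warnings.warn(
            f"series spans {ts.duration:g} h < one day ({day_length:g} h); "
            "single-row actogram"
        )
    days = actogram_rows(ts, day_length)
    n_rows = len(days)
    vmin = float(ts.values.min())
    vrange = float(np.ptp(ts.values))
    bar_w = 0.8 * ts.median_interval

    def norm(v):
        return np.ones_like(v) if vrange == 0 else (v - vmin) / vrange

    fig, axes = plt.subplots(
        n_rows, 1, figsize=(8, max(1.5, 0.9 * n_rows)), sharex=True, squeeze=False
    )
    width = 2 * day_length if double_plot else day_length
    for r in range(n_rows):
        ax = axes[r, 0]
        x, v = days[r]
        ax.bar(x, norm(v), width=bar_w, align="center", color="black")
        if double_plot and r + 1 < n_rows:
            x2, v2 = days[r + 1]
            ax.bar(x2 + day_length, norm(v2), width=bar_w, align="center", color="black")
        ax.set_xlim(0, width)
        ax.set_ylim(0, 1.05)
        ax.set_yticks([])
        ax.set_ylabel(f"d{r + 1}", rotation=0, ha="right", va="center")
    axes[-1, 0].set_xlabel("Time of day (h)")
    fig.suptitle(ts.label or "actogram")
    return _save(fig, path)


def plot_fit(ts: TimeSeries, result, fit_curve, path="fit.png", n_dense: int = 400):
    """Raw points plus the dense best-fit curve of a rhythm-scan result,
    annotated with PER, AMP and ADJ.P."""
    analyzed = getattr(result, "analyzed_ts", ts) or ts
    grid = np.linspace(analyzed.times[0], analyzed.times[-1], n_dense)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(analyzed.times, analyzed.values, "o", ms=4, color="#555555", label="data")
    ax.plot(grid, fit_curve(grid), color="#d62728", label=f"{result.method} fit")
    ax.set_xlabel("Time (h)")
    ax.set_ylabel("Value")
    ax.set_title(ts.label)
    ax.legend(loc="upper right")
    note = (
        f"PER={result.period:.3g} h  AMP={result.amplitude:.3g}  "
        f"ADJ.P={result.adj_p:.3g}"
    )
    ax.annotate(
        note, xy=(0.02, 0.02), xycoords="axes fraction", fontsize=9,
        bbox={"boxstyle": "round", "fc": "white", "alpha": 0.8},
    )
    fig.tight_layout()
    return _save(fig, path)
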