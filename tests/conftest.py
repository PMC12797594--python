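import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from circastat import TimeSeries

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def hours48():
    """48 hourly time points spanning two days."""
    return np.arange(48.0)


@pytest.fixture
def make_cosine(hours48):
    """Factory for cosine series y = mesor + A*cos(2*pi*(t - phase)/P) + noise."""

    def _make(period=24.0, amplitude=2.0, mesor=3.0, phase=0.0, noise_sd=0.0,
              seed=0, label="sample", times=None):
        t = hours48 if times is None else np.asarray(times, dtype=float)
        y = mesor + amplitude * np.cos(2.0 * np.pi * (t - phase) / period)
        if noise_sd:
            y = y + np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
        return TimeSeries(t, y, label=label)

    return _make


@pytest.fixture
def write_csv(tmp_path):
    """Write CSV text to a temp file and return its path."""

    def _write(text, name="data.csv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write


@pytest.fixture
def grouped_csv_text():
    """A small grouped CSV: two 'A' replicates and one 'B' over 48 h."""
    t = np.arange(48.0)
    rng = np.random.default_rng(7)
    a1 = 3 + 2 * np.cos(2 * np.pi * t / 24) + rng.normal(0, 0.2, t.size)
    a2 = 3 + 2 * np.cos(2 * np.pi * t / 24) + rng.normal(0, 0.2, t.size)
    b = rng.uniform(0, 1, t.size)
    lines = ["Time,A,A,B"]
    for i in range(t.size):
        lines.append(f"{t[i]:g},{a1[i]:.6f},{a2[i]:.6f},{b[i]:.6f}")
    return "\n".join(lines) + "\n"
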