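"""Name-based dispatch to the detection methods (CLI and benchmark use it)."""

from __future__ import annotations

from .ar_noise import ARCorrectedJTK
from .cosine_kendall import CosineKendall
from .cosinor import Cosinor
from .harmonic import HarmonicCosinor
from .jtk import PythonJTK
from .timeseries import TimeSeries

__all__ = ["METHODS", "analyze"]

METHODS = {
    "cosinor": Cosinor,
    "cosine-kendall": CosineKendall,
    "jtk": PythonJTK,
    "ar-jtk": ARCorrectedJTK,
    "harmonic": HarmonicCosinor,
}


def analyze(ts: TimeSeries, method: str, **options):
    """Run one named detection method on one series; returns its results."""
    try:
        cls = METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; choose from {sorted(METHODS)}"
        ) from None
    return cls(ts, **options).fit()
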