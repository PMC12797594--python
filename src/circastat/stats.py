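"""Rank-correlation machinery and multiple-testing control.

Kendall's tau-b is the score shared by all rank-based rhythm tests in this
package.  For small untied samples the null distribution of the concordance
statistic S = C - D is computed exactly by the inversion-count recursion
(Mahonian numbers); otherwise a normal approximation with tie-corrected
variance and a continuity correction is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TauTest",
    "kendall_tau_test",
    "KendallScanner",
    "TemplateBank",
    "bonferroni_adjust",
    "bh_adjust",
    "EXACT_CUTOFF",
]

#: largest untied sample size for which the exact permutation null is used
EXACT_CUTOFF = 12


@dataclass(frozen=True)
class TauTest:
    """Kendall rank-correlation test result.

    ``method`` is ``"exact"`` (inversion-count null), ``"normal"``
    (tie-corrected Gaussian approximation with continuity correction) or
    ``"degenerate"`` (a constant input; tau is 0 and p is 1 by convention).
    """

    tau: float
    n: int
    p_raw: float
    method: str

    def __post_init__(self):
        if not (-1.0 - 1e-12 <= self.tau <= 1.0 + 1e-12):
            raise ValueError("tau outside [-1, 1]")
        if not (0.0 <= self.p_raw <= 1.0):
            raise ValueError("p outside [0, 1]")


# ---------------------------------------------------------------------------
# exact null: permutation counts by number of inversions
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _inversion_counts(n: int) -> tuple:
    """Mahonian numbers: counts[k] = permutations of n items with k inversions."""
    counts = [1]
    for m in range(2, n + 1):
        out = [0] * (len(counts) + m - 1)
        for k, c in enumerate(counts):
            for j in range(m):
                out[k + j] += c
        counts = out
    return tuple(counts)


def _exact_two_sided_p(s_obs: int, n: int) -> float:
    """P(|S| >= |s_obs|) under a uniformly random untied permutation."""
    counts = _inversion_counts(n)
    n_pairs = n * (n - 1) // 2
    hits = sum(c for k, c in enumerate(counts) if abs(n_pairs - 2 * k) >= abs(s_obs))
    return min(1.0, hits / math.factorial(n))


# ---------------------------------------------------------------------------
# tau-b pieces
# ---------------------------------------------------------------------------

def _tie_sizes(x: np.ndarray) -> np.ndarray:
    _, counts = np.unique(x, return_counts=True)
    return counts[counts > 1].astype(float)


def _pair_sign(x: np.ndarray) -> np.ndarray:
    return np.sign(x[:, None] - x[None, :])


def _s_statistic(sign_a: np.ndarray, sign_b: np.ndarray) -> float:
    # each unordered pair counted twice in the full matrices
    return float((sign_a * sign_b).sum()) / 2.0


def _null_var(n: int, ties_a: np.ndarray, ties_b: np.ndarray) -> float:
    """Variance of S under the null with ties (standard tau-b formula)."""
    def v0(t):
        return float((t * (t - 1) * (2 * t + 5)).sum())

    var = (n * (n - 1) * (2 * n + 5) - v0(ties_a) - v0(ties_b)) / 18.0
    var += (
        float((ties_a * (ties_a - 1)).sum())
        * float((ties_b * (ties_b - 1)).sum())
        / (2.0 * n * (n - 1))
    )
    if n > 2:
        var += (
            float((ties_a * (ties_a - 1) * (ties_a - 2)).sum())
            * float((ties_b * (ties_b - 1) * (ties_b - 2)).sum())
            / (9.0 * n * (n - 1) * (n - 2))
        )
    return var


def _normal_two_sided_p(s: float, var: float) -> float:
    if var <= 0:
        return 1.0
    z = max(0.0, (abs(s) - 1.0)) / math.sqrt(var)  # continuity correction
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


def kendall_tau_test(a, b, exact_cutoff: int = EXACT_CUTOFF) -> TauTest:
    """Tie-corrected Kendall tau (tau-b) with a two-sided significance test.

    The exact inversion-count null is used when ``n <= exact_cutoff`` and
    neither sequence contains ties; otherwise the normal approximation with
    tie-corrected variance and continuity correction.  A constant input is
    degenerate: tau 0, p 1, flagged via ``method``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-d sequences of equal length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return TauTest(tau=0.0, n=n, p_raw=1.0, method="degenerate")

    ties_a, ties_b = _tie_sizes(a), _tie_sizes(b)
    s = _s_statistic(_pair_sign(a), _pair_sign(b))
    n_pairs = n * (n - 1) / 2.0
    n1 = float((ties_a * (ties_a - 1) / 2).sum())
    n2 = float((ties_b * (ties_b - 1) / 2).sum())
    tau = s / math.sqrt((n_pairs - n1) * (n_pairs - n2))
    tau = float(np.clip(tau, -1.0, 1.0))

    if n <= exact_cutoff and ties_a.size == 0 and ties_b.size == 0:
        return TauTest(tau=tau, n=n, p_raw=_exact_two_sided_p(round(s), n), method="exact")
    p = _normal_two_sided_p(s, _null_var(n, ties_a, ties_b))
    return TauTest(tau=tau, n=n, p_raw=p, method="normal")


class TemplateBank:
    """Precomputed pairwise structure of a stack of reference templates.

    Holds the (m, n, n) pairwise sign tensor and the per-template tie
    statistics entering the tau-b denominator and null variance, so scanning
    many data series against one fixed grid costs a single tensor
    contraction per series.
    """

    def __init__(self, templates):
        T = np.atleast_2d(np.asarray(templates, dtype=float))
        self.templates = T
        m, n = T.shape
        self.n = n
        self.sign = np.sign(T[:, :, None] - T[:, None, :]).astype(np.int8)
        n2 = np.zeros(m)
        vt = np.zeros(m)
        t2 = np.zeros(m)
        t3 = np.zeros(m)
        untied = np.zeros(m, dtype=bool)
        constant = np.zeros(m, dtype=bool)
        for i in range(m):
            ties = _tie_sizes(T[i])
            n2[i] = float((ties * (ties - 1) / 2).sum())
            vt[i] = float((ties * (ties - 1) * (2 * ties + 5)).sum())
            t2[i] = float((ties * (ties - 1)).sum())
            t3[i] = float((ties * (ties - 1) * (ties - 2)).sum())
            untied[i] = ties.size == 0
            constant[i] = n2[i] == n * (n - 1) / 2.0
        self.n2, self.vt, self.t2, self.t3 = n2, vt, t2, t3
        self.untied, self.constant = untied, constant

    def __len__(self):
        return self.templates.shape[0]


class KendallScanner:
    """Tau tests of one data vector against many reference templates.

    Precomputes the data's pairwise sign matrix and tie structure once, so a
    period/lag/asymmetry template scan costs one tensor contraction per grid.
    Identical results to :func:`kendall_tau_test` applied template by
    template (including the exact small-n path).
    """

    def __init__(self, values, exact_cutoff: int = EXACT_CUTOFF):
        v = np.asarray(values, dtype=float)
        if v.ndim != 1 or v.size < 3:
            raise ValueError("need a 1-d data vector with n >= 3")
        self.values = v
        self.n = v.size
        self.exact_cutoff = exact_cutoff
        self.degenerate = np.ptp(v) == 0
        self._sign = _pair_sign(v).astype(np.int8)
        ties = _tie_sizes(v)
        self._ties = ties
        self._n1 = float((ties * (ties - 1) / 2).sum())
        self._vt = float((ties * (ties - 1) * (2 * ties + 5)).sum())
        self._t2 = float((ties * (ties - 1)).sum())
        self._t3 = float((ties * (ties - 1) * (ties - 2)).sum())

    def scan(self, templates) -> "tuple[np.ndarray, np.ndarray]":
        """Return (tau, p) arrays for an (m, n) template stack or a
        prebuilt :class:`TemplateBank`."""
        bank = templates if isinstance(templates, TemplateBank) else TemplateBank(templates)
        n = self.n
        if bank.n != n:
            raise ValueError("template length mismatch")
        m = len(bank)
        taus = np.zeros(m)
        ps = np.ones(m)
        if self.degenerate:
            return taus, ps
        s = np.tensordot(
            bank.sign.reshape(m, -1).astype(np.float64),
            self._sign.reshape(-1).astype(np.float64),
            axes=1,
        ) / 2.0
        n_pairs = n * (n - 1) / 2.0
        ok = ~bank.constant
        denom = np.sqrt((n_pairs - self._n1) * (n_pairs - bank.n2[ok]))
        taus[ok] = np.clip(s[ok] / denom, -1.0, 1.0)
        # null variance of S with ties, vectorized over templates
        var = (n * (n - 1) * (2 * n + 5) - self._vt - bank.vt[ok]) / 18.0
        var = var + self._t2 * bank.t2[ok] / (2.0 * n * (n - 1))
        if n > 2:
            var = var + self._t3 * bank.t3[ok] / (9.0 * n * (n - 1) * (n - 2))
        z = np.maximum(np.abs(s[ok]) - 1.0, 0.0) / np.sqrt(np.maximum(var, 1e-300))
        p_ok = np.where(var > 0, np.minimum(1.0, 2.0 * sps.norm.sf(z)), 1.0)
        if n <= self.exact_cutoff and self._ties.size == 0:
            idx = np.flatnonzero(ok)
            for j, i in enumerate(idx):
                if bank.untied[i]:
                    p_ok[j] = _exact_two_sided_p(round(s[i]), n)
        ps[ok] = p_ok
        return taus, ps


# ---------------------------------------------------------------------------
# multiple-testing control
# ---------------------------------------------------------------------------

def bonferroni_adjust(p: float, m: int) -> float:
    """Bonferroni family-wise adjustment: min(1, m * p)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be a positive integer")
    return min(1.0, m * p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in the input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
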