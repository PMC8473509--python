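"""Statistical engines for the parameter-sweep analysis.

Pearson product-moment correlation, ordinary least-squares regression and
the paired two-sided t-test, as used to relate recovery coefficients to
swept acquisition/reconstruction parameters, plus a windowed plateau
detector for "converged at iteration n" statements.  The numerics are
delegated to scipy.stats behind this surface; tests cross-check them
against independent closed-form implementations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class StatResult:
    """Correlation + regression (+ optional paired test) for one sphere/parameter."""

    pearson_r: float
    r_pvalue: float
    slope: float  # the "regression coefficient"
    intercept: float
    ttest_t: float | None = None
    ttest_df: int | None = None
    ttest_p: float | None = None


def _as_vec(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite values in input")
    return a


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment r and its two-sided p (t with n-2 df)."""
    x, y = _as_vec(x), _as_vec(y)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def spearman_correlation(x, y) -> tuple[float, float]:
    """Rank correlation alternative (not used by the default protocol)."""
    x, y = _as_vec(x), _as_vec(y)
    r, p = sps.spearmanr(x, y)
    return float(r), float(p)


def linear_regression(x, y) -> tuple[float, float]:
    """Least-squares slope and intercept."""
    x, y = _as_vec(x), _as_vec(y)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.ptp(x) == 0:
        raise ValueError("regression undefined for constant x")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept)


def paired_t_test(a, b) -> tuple[float, int, float]:
    """Two-sided paired t-test: (t, df, p) with df = n - 1."""
    a, b = _as_vec(a), _as_vec(b)
    if a.size != b.size or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = a - b
    if np.ptp(d) == 0:
        raise ValueError("degenerate paired test: differences have zero variance")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), int(a.size - 1), float(res.pvalue)


def convergence_iteration(
    rc_curve, window: int = 10, tol: float = 1.0
) -> int | None:
    """Smallest iteration n whose next ``window`` iterations gain < ``tol``.

    ``rc_curve[i]`` is the RC after iteration i+1.  Returns the 1-based
    iteration index n such that max(RC[n..n+window]) - RC[n] < tol, or None
    if the curve never plateaus within its length.
    """
    rc = _as_vec(rc_curve)
    if rc.size < window + 1:
        raise ValueError("curve shorter than the convergence window")
    for i in range(rc.size - window):
        if np.max(rc[i : i + window + 1]) - rc[i] < tol:
            return i + 1
    return None


def correlate_and_fit(x, y, a=None, b=None) -> StatResult:
    r, p = pearson_correlation(x, y)
    slope, intercept = linear_regression(x, y)
    t = df = tp = None
    if a is not None and b is not None:
        t, df, tp = paired_t_test(a, b)
    return StatResult(r, p, slope, intercept, t, df, tp)
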