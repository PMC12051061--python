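"""Statistical primitives for segment-wise feature-taste correlation.

The correlation engine tests hundreds of thousands of short (5-9 point)
fraction windows, so every primitive here has a vectorized batch form
operating on a ``(m, n)`` array of windows of common length ``n``, plus a
scalar convenience wrapper.

Implemented here rather than delegated:

* Shapiro-Wilk via Royston's AS R94 coefficient approximation (the
  normality gate choosing Kendall vs Pearson),
* Kendall tau-b with an exact two-sided permutation p-value for tie-free
  samples of n <= 9 (the segment regime) from the inversion-count null
  distribution, and the tie-corrected normal approximation otherwise,
* Pearson's r with the t-distribution p-value,
* Benjamini-Hochberg step-up adjustment.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import NamedTuple

import numpy as np
from scipy.special import ndtri, stdtr

__all__ = [
    "ShapiroResult",
    "CorrResult",
    "shapiro_wilk",
    "shapiro_wilk_batch",
    "kendall_tau",
    "kendall_tau_batch",
    "pearson_r",
    "pearson_r_batch",
    "adjust_bh",
    "EXACT_KENDALL_MAX_N",
]

EXACT_KENDALL_MAX_N = 9


class ShapiroResult(NamedTuple):
    statistic: float
    pvalue: float
    degenerate: bool


class CorrResult(NamedTuple):
    coefficient: float
    pvalue: float
    undefined: bool


# ---------------------------------------------------------------------------
# Shapiro-Wilk (Royston 1995, AS R94)
# ---------------------------------------------------------------------------

_SW_C1 = (-2.706056, 4.434685, -2.071190, -0.147981, 0.221157, 0.0)
_SW_C2 = (-3.582633, 5.682633, -1.752461, -0.293762, 0.042981, 0.0)


@lru_cache(maxsize=None)
def _sw_coefficients(n: int) -> np.ndarray:
    """Royston's approximate optimal weights a_1..a_n (ascending order)."""
    if n < 3:
        raise ValueError("Shapiro-Wilk requires n >= 3")
    if n == 3:
        r = math.sqrt(0.5)
        return np.array([-r, 0.0, r])
    i = np.arange(1, n + 1)
    m = ndtri((i - 0.375) / (n + 0.25))
    ssq = float(np.dot(m, m))
    u = 1.0 / math.sqrt(n)
    a = np.empty(n)
    cn = m[-1] / math.sqrt(ssq)
    an = np.polyval(_SW_C1, u) + cn
    if n > 5:
        cn1 = m[-2] / math.sqrt(ssq)
        an1 = np.polyval(_SW_C2, u) + cn1
        phi = (ssq - 2.0 * m[-1] ** 2 - 2.0 * m[-2] ** 2) / (
            1.0 - 2.0 * an**2 - 2.0 * an1**2
        )
        a[2:-2] = m[2:-2] / math.sqrt(phi)
        a[-2], a[1] = an1, -an1
    else:
        phi = (ssq - 2.0 * m[-1] ** 2) / (1.0 - 2.0 * an**2)
        a[1:-1] = m[1:-1] / math.sqrt(phi)
    a[-1], a[0] = an, -an
    return a


def _sw_pvalue(w: np.ndarray, n: int) -> np.ndarray:
    """Royston's normalizing transformation of W to a p-value."""
    w = np.clip(w, 1e-12, 1.0 - 1e-15)
    if n == 3:
        # exact for n = 3
        p = (6.0 / math.pi) * (np.arcsin(np.sqrt(w)) - math.asin(math.sqrt(0.75)))
        return np.clip(p, 0.0, 1.0)
    lw = np.log1p(-w)
    if n <= 11:
        g = -2.273 + 0.459 * n
        mu = 0.5440 - 0.39978 * n + 0.025054 * n**2 - 0.0006714 * n**3
        sigma = math.exp(1.3822 - 0.77857 * n + 0.062767 * n**2 - 0.0020322 * n**3)
        arg = np.maximum(g - lw, 1e-300)
        z = (-np.log(arg) - mu) / sigma
    else:
        ln = math.log(n)
        mu = -1.5861 - 0.31082 * ln - 0.083751 * ln**2 + 0.0038915 * ln**3
        sigma = math.exp(-0.4803 - 0.082676 * ln + 0.0030302 * ln**2)
        z = (lw - mu) / sigma
    # upper-tail normal probability
    return 0.5 * np.vectorize(math.erfc)(z / math.sqrt(2.0))


def shapiro_wilk_batch(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shapiro-Wilk over each row of ``x``.

    Returns ``(W, p, degenerate)`` arrays; degenerate (constant) rows get
    ``W = nan``, ``p = nan`` and are to be treated as non-normal downstream.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    n = x.shape[1]
    a = _sw_coefficients(n)
    xs = np.sort(x, axis=1)
    degenerate = xs[:, -1] == xs[:, 0]
    num = (xs @ a) ** 2
    den = np.sum((x - x.mean(axis=1, keepdims=True)) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(degenerate, np.nan, num / np.where(den > 0, den, np.nan))
    p = np.full(x.shape[0], np.nan)
    ok = ~degenerate
    if ok.any():
        p[ok] = _sw_pvalue(w[ok], n)
    return w, p, degenerate


def shapiro_wilk(x) -> ShapiroResult:
    """Shapiro-Wilk normality test for a single sample (3 <= n <= 50 typical).

    W is location/scale invariant and lies in (0, 1]; a constant sample is
    flagged degenerate rather than raising.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D sample")
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires n >= 3")
    w, p, deg = shapiro_wilk_batch(x[None, :])
    return ShapiroResult(float(w[0]), float(p[0]), bool(deg[0]))


# ---------------------------------------------------------------------------
# Kendall tau-b
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _mahonian(n: int) -> np.ndarray:
    """Counts of permutations of n items by inversion number (0..n(n-1)/2)."""
    counts = np.array([1], dtype=object)
    for k in range(2, n + 1):
        # convolve with the uniform kernel of length k
        new = np.zeros(len(counts) + k - 1, dtype=object)
        for shift in range(k):
            new[shift : shift + len(counts)] += counts
        counts = new
    return counts


@lru_cache(maxsize=None)
def _kendall_exact_table(n: int) -> np.ndarray:
    """p_two[s] = P(|S| >= s) under the tie-free permutation null, s = |S|."""
    n0 = n * (n - 1) // 2
    counts = _mahonian(n)  # index k (inversions) -> S = n0 - 2k
    total = math.factorial(n)
    p = np.zeros(n0 + 1)
    for s in range(n0 + 1):
        c = sum(int(counts[k]) for k in range(n0 + 1) if abs(n0 - 2 * k) >= s)
        p[s] = c / total
    return p


def _pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def kendall_tau_batch(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tie-corrected Kendall tau-b for paired rows of ``x`` and ``y``.

    Two-sided p-values are exact (permutation null) for tie-free rows with
    n <= 9 and use the tie-corrected normal approximation otherwise.
    Returns ``(tau, p, undefined)``; rows where either variable is constant
    are flagged undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have identical shapes")
    if x.ndim == 1:
        x, y = x[None, :], y[None, :]
    m, n = x.shape
    iu, ju = _pair_index(n)
    dx = x[:, ju] - x[:, iu]
    dy = y[:, ju] - y[:, iu]
    sx, sy = np.sign(dx), np.sign(dy)
    s = np.sum(sx * sy, axis=1)
    n0 = n * (n - 1) // 2
    tx = np.sum(sx == 0, axis=1)  # tied x pairs
    ty = np.sum(sy == 0, axis=1)
    undefined = (tx == n0) | (ty == n0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = s / np.sqrt((n0 - tx) * (n0 - ty))
    tau = np.where(undefined, np.nan, np.clip(tau, -1.0, 1.0))

    p = np.full(m, np.nan)
    tie_free = (tx == 0) & (ty == 0)
    if n <= EXACT_KENDALL_MAX_N and tie_free.any():
        table = _kendall_exact_table(n)
        p[tie_free] = table[np.abs(s[tie_free]).astype(int)]
    approx = ~tie_free & ~undefined if n <= EXACT_KENDALL_MAX_N else ~undefined
    if approx.any():
        p[approx] = _kendall_normal_p(x[approx], y[approx], s[approx])
    return tau, p, undefined


def _tie_group_sums(v: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row sums over tie groups of t(t-1), t(t-1)(2t+5), t(t-1)(t-2)."""
    # c_i = (group size containing i) - 1, computed from the equality matrix
    c = np.sum(v[:, :, None] == v[:, None, :], axis=2) - 1.0
    s1 = np.sum(c, axis=1)  # sum t(t-1)
    s2 = np.sum(c * (2.0 * (c + 1.0) + 5.0), axis=1)  # sum t(t-1)(2t+5)
    s3 = np.sum(c * (c - 1.0), axis=1)  # sum t(t-1)(t-2)
    return s1, s2, s3


def _kendall_normal_p(x: np.ndarray, y: np.ndarray, s: np.ndarray) -> np.ndarray:
    n = x.shape[1]
    x1, x2, x3 = _tie_group_sums(x)
    y1, y2, y3 = _tie_group_sums(y)
    v0 = n * (n - 1) * (2 * n + 5)
    var = (v0 - x2 - y2) / 18.0 + x1 * y1 / (2.0 * n * (n - 1))
    if n > 2:
        var = var + x3 * y3 / (9.0 * n * (n - 1) * (n - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(s) / np.sqrt(var)
    return np.vectorize(math.erfc)(z / math.sqrt(2.0))


def kendall_tau(x, y) -> CorrResult:
    """Kendall's tau-b with a two-sided p-value for one pair of samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("Kendall tau requires n >= 3")
    tau, p, und = kendall_tau_batch(x[None, :], y[None, :])
    return CorrResult(float(tau[0]), float(p[0]), bool(und[0]))


# ---------------------------------------------------------------------------
# Pearson
# ---------------------------------------------------------------------------


def pearson_r_batch(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Product-moment correlation per row; p from t on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim == 1:
        x, y = x[None, :], y[None, :]
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = np.sum(xc * xc, axis=1)
    syy = np.sum(yc * yc, axis=1)
    undefined = (sxx == 0) | (syy == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sum(xc * yc, axis=1) / np.sqrt(sxx * syy)
    r = np.where(undefined, np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = r * r * (n - 2) / (1.0 - r * r)
    t = np.sqrt(np.where(np.isfinite(t2), t2, np.inf))
    # two-sided p from Student's t with n-2 df; |r| = 1 gives p = 0
    p = np.where(
        np.isfinite(t2),
        2.0 * stdtr(n - 2, -t),
        np.where(undefined, np.nan, 0.0),
    )
    return r, p, undefined


def pearson_r(x, y) -> CorrResult:
    """Pearson's r with a two-sided p-value for one pair of samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("Pearson correlation requires n >= 3")
    r, p, und = pearson_r_batch(x[None, :], y[None, :])
    return CorrResult(float(r[0]), float(p[0]), bool(und[0]))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} m p_(j) / j, clipped at 1, in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out
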