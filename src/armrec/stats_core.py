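"""Self-contained inferential statistics: one-way ANOVA and Spearman rank correlation.

Both procedures are implemented from first principles so that the analysis
pipeline has no opaque statistical dependency: the F and t tail areas come
from a regularized incomplete beta function evaluated with a Lentz-type
continued fraction, and small-sample Spearman p-values are exact, obtained by
enumerating all ``n!`` rank permutations (feasible up to n = 9, which covers
the clade-level correlations this package runs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "AnovaResult",
    "SpearmanResult",
    "average_ranks",
    "betainc_reg",
    "f_sf",
    "one_way_anova",
    "spearman",
    "t_sf_two_sided",
]

#: largest n for which the exact permutation null is enumerated (9! = 362 880)
EXACT_PERMUTATION_MAX_N = 9

_BETA_TOL = 1e-14
_BETA_MAXIT = 300


@dataclass(frozen=True)
class AnovaResult:
    """Result of a one-way fixed-effects analysis of variance."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    ss_between: float
    ss_within: float


@dataclass(frozen=True)
class SpearmanResult:
    """Spearman rank correlation with its p-value provenance.

    ``method`` records whether ``p_value`` came from full permutation
    enumeration (exact for n <= 9) or from the Student-t approximation
    ``t = rho * sqrt((n - 2) / (1 - rho**2))``.
    """

    rho: float
    n: int
    p_value: float
    method: Literal["exact_permutation", "t_approximation"]


# ---------------------------------------------------------------------------
# incomplete beta / distribution tails
# ---------------------------------------------------------------------------

def _betacf(a: float, b: float, x: float) -> float:
    """Continued fraction for the incomplete beta function (modified Lentz)."""
    fpmin = 1e-300
    qab, qap, qam = a + b, a + 1.0, a - 1.0
    c = 1.0
    d = 1.0 - qab * x / qap
    if abs(d) < fpmin:
        d = fpmin
    d = 1.0 / d
    h = d
    for m in range(1, _BETA_MAXIT + 1):
        m2 = 2 * m
        aa = m * (b - m) * x / ((qam + m2) * (a + m2))
        d = 1.0 + aa * d
        if abs(d) < fpmin:
            d = fpmin
        c = 1.0 + aa / c
        if abs(c) < fpmin:
            c = fpmin
        d = 1.0 / d
        h *= d * c
        aa = -(a + m) * (qab + m) * x / ((a + m2) * (qap + m2))
        d = 1.0 + aa * d
        if abs(d) < fpmin:
            d = fpmin
        c = 1.0 + aa / c
        if abs(c) < fpmin:
            c = fpmin
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < _BETA_TOL:
            return h
    raise RuntimeError("incomplete beta continued fraction did not converge")


def betainc_reg(a: float, b: float, x: float) -> float:
    """Regularized incomplete beta function I_x(a, b)."""
    if a <= 0 or b <= 0:
        raise ValueError("beta parameters must be positive")
    if x <= 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    ln_front = (
        math.lgamma(a + b)
        - math.lgamma(a)
        - math.lgamma(b)
        + a * math.log(x)
        + b * math.log1p(-x)
    )
    front = math.exp(ln_front)
    # the continued fraction converges fast only on one side of the mean
    if x < (a + 1.0) / (a + b + 2.0):
        return front * _betacf(a, b, x) / a
    return 1.0 - front * _betacf(b, a, 1.0 - x) / b


def f_sf(f: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F(df1, df2) distribution."""
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degrees of freedom must be positive")
    if f <= 0.0:
        return 1.0
    x = df2 / (df2 + df1 * f)
    return betainc_reg(df2 / 2.0, df1 / 2.0, x)


def t_sf_two_sided(t: float, df: float) -> float:
    """Two-sided tail probability P(|T| >= |t|) for Student's t."""
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    if not math.isfinite(t):
        return 0.0
    x = df / (df + t * t)
    return betainc_reg(df / 2.0, 0.5, x)


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------

def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA over two or more groups of observations.

    F is the ratio of the between-group to the within-group mean square;
    the p-value is the upper tail of F(k - 1, N - k).

    Raises
    ------
    ValueError
        If fewer than two groups are given, any group has fewer than two
        observations, or the pooled within-group variance is zero (the F
        ratio is then undefined/degenerate).
    """
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, a in enumerate(arrays):
        if a.ndim != 1 or a.size < 2:
            raise ValueError(f"group {i} must hold at least two observations")
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    grand_mean = sum(a.sum() for a in arrays) / n_total
    ss_between = sum(a.size * (a.mean() - grand_mean) ** 2 for a in arrays)
    ss_within = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    df_between = k - 1
    df_within = n_total - k
    if ss_within <= 0.0:
        raise ValueError(
            "pooled within-group variance is zero; F ratio undefined on degenerate data"
        )
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    f = ms_between / ms_within
    return AnovaResult(
        f_statistic=float(f),
        df_between=df_between,
        df_within=df_within,
        p_value=f_sf(float(f), df_between, df_within),
        ss_between=float(ss_between),
        ss_within=float(ss_within),
    )


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def average_ranks(values: Sequence[float]) -> np.ndarray:
    """Ranks starting at 1, ties sharing the average of their positions."""
    a = np.asarray(values, dtype=float)
    if a.ndim != 1:
        raise ValueError("values must be one-dimensional")
    order = np.argsort(a, kind="mergesort")
    ranks = np.empty(a.size, dtype=float)
    i = 0
    while i < a.size:
        j = i
        while j + 1 < a.size and a[order[j + 1]] == a[order[i]]:
            j += 1
        # positions i..j (0-based) share rank mean of (i+1 .. j+1)
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float((xc * xc).sum()) * float((yc * yc).sum()))
    if denom == 0.0:
        raise ValueError("constant input: correlation undefined")
    return float((xc * yc).sum()) / denom


# permutation matrices and tie-free |rho| null distributions, cached per n
_perm_cache: dict[int, np.ndarray] = {}
_tie_free_null_cache: dict[int, np.ndarray] = {}


def _perm_matrix(n: int) -> np.ndarray:
    if n not in _perm_cache:
        _perm_cache[n] = np.array(
            list(permutations(range(n))), dtype=np.int8
        )
    return _perm_cache[n]


def _tie_free_abs_null(n: int) -> np.ndarray:
    """Sorted |rho| over all permutations of tie-free ranks 1..n."""
    if n not in _tie_free_null_cache:
        perms = _perm_matrix(n)
        r = np.arange(1.0, n + 1.0)
        s = (perms + 1.0) @ r  # sum_i rank_x(i) * rank_y(perm(i))
        mean_sq = n * ((n + 1.0) / 2.0) ** 2
        denom = n * (n * n - 1.0) / 12.0
        rho_all = (s - mean_sq) / denom
        _tie_free_null_cache[n] = np.sort(np.abs(rho_all))
    return _tie_free_null_cache[n]


def _exact_p_two_sided(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    n = rx.size
    tol = 1e-12
    tie_free = np.allclose(np.sort(rx), np.arange(1, n + 1)) and np.allclose(
        np.sort(ry), np.arange(1, n + 1)
    )
    if tie_free:
        null = _tie_free_abs_null(n)
        idx = np.searchsorted(null, abs(rho_obs) - tol, side="left")
        return float(null.size - idx) / null.size
    perms = _perm_matrix(n)
    ry_perm = ry[perms]  # (n!, n)
    xc = rx - rx.mean()
    yc_sq = float(((ry - ry.mean()) ** 2).sum())
    denom = math.sqrt(float((xc * xc).sum()) * yc_sq)
    rho_all = (ry_perm @ xc) / denom
    return float(np.count_nonzero(np.abs(rho_all) >= abs(rho_obs) - tol)) / len(rho_all)


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    *,
    alternative: Literal["two-sided", "greater", "less"] = "two-sided",
    method: Literal["auto", "exact", "t_approximation"] = "auto",
) -> SpearmanResult:
    """Spearman rank correlation between paired samples.

    Ties receive average ranks and rho is the Pearson correlation of the
    rank vectors (the tie-corrected form; it reduces to the classical
    ``1 - 6*sum(d^2)/(n*(n^2-1))`` shortcut when there are no ties).

    For ``n <= 9`` (or ``method="exact"``) the p-value enumerates all n!
    permutations of one rank vector; otherwise the t approximation with
    ``n - 2`` degrees of freedom is used. One-sided alternatives are only
    supported by the t approximation.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be one-dimensional and the same length")
    n = xa.size
    if n < 3:
        raise ValueError("Spearman correlation requires at least 3 pairs")
    rx = average_ranks(xa)
    ry = average_ranks(ya)
    rho = _pearson(rx, ry)

    use_exact = method == "exact" or (method == "auto" and n <= EXACT_PERMUTATION_MAX_N)
    if use_exact and n > EXACT_PERMUTATION_MAX_N:
        raise ValueError(
            f"exact permutation p only feasible for n <= {EXACT_PERMUTATION_MAX_N}"
        )
    if use_exact:
        if alternative != "two-sided":
            raise ValueError("exact method implements the two-sided alternative only")
        p = _exact_p_two_sided(rx, ry, rho)
        return SpearmanResult(rho=rho, n=n, p_value=p, method="exact_permutation")

    if abs(rho) >= 1.0:
        p_two = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p_two = t_sf_two_sided(t, n - 2)
    if alternative == "two-sided":
        p = p_two
    elif alternative == "greater":
        p = p_two / 2.0 if rho >= 0 else 1.0 - p_two / 2.0
    else:
        p = p_two / 2.0 if rho <= 0 else 1.0 - p_two / 2.0
    return SpearmanResult(rho=rho, n=n, p_value=p, method="t_approximation")
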