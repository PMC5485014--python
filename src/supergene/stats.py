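"""Small-sample statistical tests used throughout the supergene analysis.

Each test is implemented from its defining formula (or by exact enumeration
for small samples) rather than delegating to a library routine, so that the
exact conventions — Yates continuity correction for 2x2 chi-square, the
probability-mass rule for two-sided Fisher tests, exact rank-sum enumeration
without ties — are explicit and unit-testable against independent oracles.
Only distribution functions (t, chi-square, normal, hypergeometric mass)
come from scipy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy import stats as _sps

__all__ = [
    "ContingencyResult",
    "WelchResult",
    "welch_t",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "chi2_2x2",
    "fisher_exact_2x2",
    "mk_test",
    "density_enrichment_chi2",
    "bonferroni",
]


@dataclass(frozen=True)
class ContingencyResult:
    """Outcome of a contingency-table test.

    Attributes
    ----------
    statistic : float
        The test statistic (always >= 0).
    df : int
        Degrees of freedom.
    p_value : float
        Two-sided p-value.
    corrected : bool
        Whether a continuity correction was applied.
    extra : dict
        Test-specific extras (e.g. the neutrality index for the MK test).
    """

    statistic: float
    df: int
    p_value: float
    corrected: bool = False
    extra: dict | None = None


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_two_sided: float
    p_one_sided: float
    degenerate: bool = False


def welch_t(x, y) -> WelchResult:
    """Welch's unequal-variance t test.

    Uses the Welch–Satterthwaite degrees of freedom. Degenerate inputs
    (zero variance in both samples) are flagged: equal means give p = 1,
    unequal means give p = 0. The one-sided p is for the alternative
    mean(x) < mean(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t requires at least two observations per sample")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    sx, sy = vx / x.size, vy / y.size
    if sx + sy == 0.0:
        if mx == my:
            return WelchResult(0.0, float("nan"), 1.0, 1.0, degenerate=True)
        t = -math.inf if mx < my else math.inf
        return WelchResult(t, float("nan"), 0.0, 0.0 if mx < my else 1.0, degenerate=True)
    t = (mx - my) / math.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (sx**2 / (x.size - 1) + sy**2 / (y.size - 1))
    p_two = 2.0 * _sps.t.sf(abs(t), df)
    p_one = _sps.t.cdf(t, df)  # alternative: mean(x) < mean(y)
    return WelchResult(float(t), float(df), float(min(p_two, 1.0)), float(p_one))


def _rank_sum_exact_p(x, y, side):
    """Exact rank-sum p by enumeration of group assignments (no ties)."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = _sps.rankdata(pooled)
    w_obs = ranks[:n].sum()
    idx = range(n + m)
    total = math.comb(n + m, n)
    count_le = 0
    count_ge = 0
    for comb in itertools.combinations(idx, n):
        w = ranks[list(comb)].sum()
        if w <= w_obs + 1e-9:
            count_le += 1
        if w >= w_obs - 1e-9:
            count_ge += 1
    p_less = count_le / total  # alternative: x tends smaller
    p_greater = count_ge / total
    if side == "less":
        return p_less
    if side == "greater":
        return p_greater
    return min(1.0, 2.0 * min(p_less, p_greater))


def wilcoxon_rank_sum(x, y, side: str = "two-sided"):
    """Wilcoxon rank-sum (Mann–Whitney) test.

    Exact enumeration when min(n, m) <= 10 and there are no ties; otherwise
    the normal approximation with tie correction. Returns ``(W, p)`` where W
    is the rank sum of ``x``.

    ``side`` is one of ``"less"`` (x tends smaller), ``"greater"``,
    ``"two-sided"``.
    """
    if side not in ("less", "greater", "two-sided"):
        raise ValueError(f"unknown side {side!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _sps.rankdata(pooled)
    w = float(ranks[:n].sum())
    has_ties = np.unique(pooled).size < pooled.size
    if min(n, m) <= 10 and not has_ties:
        return w, _rank_sum_exact_p(x, y, side)
    # normal approximation with tie correction
    N = n + m
    mu = n * (N + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var == 0:
        return w, 1.0
    # continuity-corrected z
    if side == "less":
        z = (w - mu + 0.5) / math.sqrt(var)
        p = _sps.norm.cdf(z)
    elif side == "greater":
        z = (w - mu - 0.5) / math.sqrt(var)
        p = _sps.norm.sf(z)
    else:
        z = (abs(w - mu) - 0.5) / math.sqrt(var)
        p = 2.0 * _sps.norm.sf(max(z, 0.0))
    return w, float(min(p, 1.0))


def wilcoxon_signed_rank(values, center: float, side: str = "two-sided"):
    """One-sample Wilcoxon signed-rank test of ``values`` against ``center``.

    Exact null distribution for n < 25 without ties in |differences|, normal
    approximation otherwise. Zero differences are dropped (Wilcoxon's rule).
    Returns ``(V, p)`` with V the positive-rank sum.
    """
    if side not in ("less", "greater", "two-sided"):
        raise ValueError(f"unknown side {side!r}")
    d = np.asarray(values, dtype=float) - center
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    absd = np.abs(d)
    ranks = _sps.rankdata(absd)
    v = float(ranks[d > 0].sum())
    has_ties = np.unique(absd).size < n
    if n < 25 and not has_ties:
        # exact: enumerate sign patterns via DP over the rank distribution
        max_v = int(n * (n + 1) // 2)
        counts = np.zeros(max_v + 1, dtype=float)
        counts[0] = 1.0
        for r in range(1, n + 1):
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[:-r] if r > 0 else counts
            counts = counts + shifted
        total = counts.sum()
        cdf_le = counts[: int(round(v)) + 1].sum() / total
        cdf_ge = counts[int(round(v)):].sum() / total
        p_less, p_greater = cdf_le, cdf_ge
    else:
        mu = n * (n + 1) / 4.0
        _, tc = np.unique(absd, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tc**3 - tc).sum()) / 48.0
        z_less = (v - mu + 0.5) / math.sqrt(var)
        z_greater = (v - mu - 0.5) / math.sqrt(var)
        p_less = float(_sps.norm.cdf(z_less))
        p_greater = float(_sps.norm.sf(z_greater))
    if side == "less":
        return v, min(1.0, p_less)
    if side == "greater":
        return v, min(1.0, p_greater)
    return v, min(1.0, 2.0 * min(p_less, p_greater))


def chi2_2x2(table, continuity: bool = True) -> ContingencyResult:
    """Pearson chi-square test on a 2x2 table, df = 1.

    ``continuity=True`` (default) applies the Yates correction
    max(|O - E| - 0.5, 0).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("chi2_2x2 expects a 2x2 table")
    if (t < 0).any():
        raise ValueError("negative cell count")
    n = t.sum()
    if n == 0:
        raise ValueError("empty table")
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    expected = row @ col / n
    if (expected == 0).any():
        return ContingencyResult(0.0, 1, 1.0, continuity)
    dev = np.abs(t - expected)
    if continuity:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev**2 / expected).sum())
    p = float(_sps.chi2.sf(stat, 1))
    return ContingencyResult(stat, 1, p, continuity)


def _hypergeom_pmf(a, r1, r2, c1):
    """P(top-left cell = a) given margins, via log binomials."""
    n = r1 + r2
    return math.exp(
        _log_comb(r1, a) + _log_comb(r2, c1 - a) - _log_comb(n, c1)
    )


def _log_comb(n, k):
    if k < 0 or k > n:
        return -math.inf
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


def fisher_exact_2x2(table, side: str = "two-sided") -> float:
    """Fisher's exact test on a 2x2 table by hypergeometric enumeration.

    The two-sided p sums the probabilities of all tables (with the observed
    margins) whose probability is <= that of the observed table, the standard
    probability-mass rule. One-sided alternatives refer to the top-left cell:
    ``"less"`` sums tables with a smaller-or-equal top-left cell.
    """
    if side not in ("less", "greater", "two-sided"):
        raise ValueError(f"unknown side {side!r}")
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("fisher_exact_2x2 expects a nonnegative 2x2 table")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2, c1 = a + b, c + d, a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = range(lo, hi + 1)
    pmf = {k: _hypergeom_pmf(k, r1, r2, c1) for k in support}
    p_obs = pmf[a]
    if side == "less":
        return min(1.0, sum(pmf[k] for k in support if k <= a))
    if side == "greater":
        return min(1.0, sum(pmf[k] for k in support if k >= a))
    eps = 1e-12
    return min(1.0, sum(p for p in pmf.values() if p <= p_obs * (1 + eps)))


def mk_test(fixed_n: int, fixed_s: int, poly_n: int, poly_s: int) -> ContingencyResult:
    """McDonald–Kreitman test.

    Contrasts the nonsynonymous:synonymous ratio of fixed differences between
    the two haplotype groups against the same ratio among polymorphisms,
    as a Yates-corrected 2x2 chi-square on::

        [[fixed_n, fixed_s],
         [poly_n,  poly_s ]]

    The neutrality index NI = (poly_n/poly_s) / (fixed_n/fixed_s) is reported
    in ``extra`` (NaN when undefined). NI > 1 indicates an excess of
    nonsynonymous polymorphism; NI < 1 an excess of nonsynonymous divergence,
    the signature of relaxed purifying selection on the diverged haplotype.
    """
    res = chi2_2x2([[fixed_n, fixed_s], [poly_n, poly_s]], continuity=True)
    if poly_s > 0 and fixed_s > 0 and fixed_n > 0:
        ni = (poly_n / poly_s) / (fixed_n / fixed_s)
    else:
        ni = float("nan")
    return ContingencyResult(res.statistic, res.df, res.p_value, res.corrected, {"neutrality_index": ni})


def density_enrichment_chi2(count_in: int, count_out: int, size_in: float, size_out: float) -> ContingencyResult:
    """Goodness-of-fit of observed counts against size-proportional expectation.

    Tests whether ``count_in`` of ``count_in + count_out`` events falling in a
    region covering ``size_in`` of ``size_in + size_out`` bp is compatible
    with a uniform density. df = 1, no continuity correction (counts are
    typically large when this is used).
    """
    if size_in <= 0 or size_out <= 0:
        raise ValueError("region sizes must be positive")
    total = count_in + count_out
    if total == 0:
        return ContingencyResult(0.0, 1, 1.0)
    frac = size_in / (size_in + size_out)
    expected = np.array([total * frac, total * (1 - frac)])
    observed = np.array([count_in, count_out], dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    return ContingencyResult(stat, 1, float(_sps.chi2.sf(stat, 1)))


def bonferroni(p_values, alpha: float = 0.05):
    """Bonferroni correction: returns (adjusted p-values, reject flags)."""
    p = np.asarray(p_values, dtype=float)
    adj = np.minimum(p * p.size, 1.0)
    return adj, adj < alpha
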