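"""Statistical primitives.

The tests used throughout the pipeline — two-sample permutation test,
Wilcoxon signed-rank, Benjamini–Hochberg FDR, Fisher exact 2x2, Pearson
chi-square, Kruskal–Wallis, and one-way MANOVA (Wilks' lambda) — are
implemented here from first principles, with exact enumeration whenever
the null support is small enough to enumerate.  Only distribution tail
functions (normal, chi-square, F) and midrank computation are taken from
scipy.

Conventions shared by every test:

* p-values are two-sided unless inherently one-sided (chi-square, KW);
* degenerate inputs with a zero-variance null (all-constant data, zero
  differences, zero events) return p = 1 rather than raising;
* Monte-Carlo estimates use the add-one estimator
  ``p = (1 + #{T* >= T}) / (n_perm + 1)`` so that p is never exactly 0;
* every stochastic operation takes an explicit seed and records it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist
from scipy.stats import f as f_dist
from scipy.stats import norm as norm_dist
from scipy.stats import rankdata

_EPS = 1e-12


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_used: tuple[int, ...]
    exact: bool = False
    seed: int | None = None
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# two-sample permutation test

def permutation_test(
    x, y, n_perm: int = 10000, seed: int | None = 0
) -> TestResult:
    """Two-sided permutation test on the difference of group means.

    If the number of distinct label assignments C(n, nx) does not exceed
    ``n_perm`` the full null support is enumerated and the p-value is
    exact; otherwise ``n_perm`` random reassignments are drawn and the
    add-one estimator is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    n, nx = pooled.size, x.size
    t_obs = x.mean() - y.mean()
    if np.ptp(pooled) == 0:
        return TestResult(0.0, 1.0, "permutation", (nx, y.size), exact=True)

    n_total = math.comb(n, nx)
    if n_total <= n_perm:
        hits = 0
        for idx in itertools.combinations(range(n), nx):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            t = pooled[mask].mean() - pooled[~mask].mean()
            if abs(t) >= abs(t_obs) - _EPS:
                hits += 1
        return TestResult(float(t_obs), hits / n_total, "permutation",
                          (nx, y.size), exact=True)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        t = perm[:nx].mean() - perm[nx:].mean()
        if abs(t) >= abs(t_obs) - _EPS:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return TestResult(float(t_obs), p, "permutation", (nx, y.size),
                      exact=False, seed=seed)


def permutation_test_matrix(
    a: np.ndarray, b: np.ndarray, n_perm: int = 10000, seed: int | None = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided permutation tests sharing one permutation set.

    ``a`` (features x n1) and ``b`` (features x n2) hold the two groups.
    One set of ``n_perm`` random column reassignments is applied to every
    feature simultaneously (a single matrix product per batch), which is
    the standard vectorization for genome-scale scans.  Returns
    ``(t_obs, p)`` arrays of length ``features`` with add-one p-values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.hstack([a, b])               # features x n
    n = n1 + n2
    t_obs = a.mean(axis=1) - b.mean(axis=1)
    rng = np.random.default_rng(seed)

    hits = np.zeros(pooled.shape[0], dtype=np.int64)
    batch = max(1, min(n_perm, int(2e8 // max(1, pooled.shape[0] * 8))))
    done = 0
    col_sum = pooled.sum(axis=1)
    while done < n_perm:
        m = min(batch, n_perm - done)
        # boolean selection matrix: m permutations x n samples
        sel = np.zeros((m, n), dtype=float)
        for i in range(m):
            sel[i, rng.choice(n, size=n1, replace=False)] = 1.0
        sum_a = sel @ pooled.T               # m x features
        t_star = sum_a / n1 - (col_sum[None, :] - sum_a) / n2
        hits += (np.abs(t_star) >= np.abs(t_obs)[None, :] - _EPS).sum(axis=0)
        done += m
    p = (1 + hits) / (n_perm + 1)
    constant = np.ptp(pooled, axis=1) == 0
    p[constant] = 1.0
    t_obs = np.where(constant, 0.0, t_obs)
    return t_obs, p


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank

def wilcoxon_signed_rank(diffs, exact_max_n: int = 15) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking (Wilcoxon's original
    treatment).  With ``n <= exact_max_n`` non-zero differences the
    two-sided p-value is computed by enumerating all 2^n sign
    assignments of the observed midranks (exact even under ties);
    otherwise the normal approximation with tie and continuity
    correction is used.  All differences zero gives p = 1.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, "wilcoxon-signed-rank", (0,), exact=True)
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    mu = total / 2.0
    dev = abs(w - mu)

    if n <= exact_max_n:
        # enumerate all sign vectors; W* = sum of ranks given '+' signs
        hits = 0
        for signs in itertools.product((0, 1), repeat=n):
            w_star = float(np.dot(signs, ranks))
            if abs(w_star - mu) >= dev - _EPS:
                hits += 1
        return TestResult(w, hits / 2 ** n, "wilcoxon-signed-rank", (n,),
                          exact=True)

    var = float(np.sum(ranks ** 2)) / 4.0  # = n(n+1)(2n+1)/24 - tie term
    if var == 0:
        return TestResult(w, 1.0, "wilcoxon-signed-rank", (n,), exact=False)
    z = max(dev - 0.5, 0.0) / math.sqrt(var)
    p = min(1.0, 2.0 * float(norm_dist.sf(z)))
    return TestResult(w, p, "wilcoxon-signed-rank", (n,), exact=False)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg

def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving.

    ``q_i = min over j with p_(j) >= p_(i) of m * p_(j) / rank(j)``,
    clipped to 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Fisher exact (2x2) and chi-square

def _hypergeom_logpmf(k: int, n1: int, n2: int, c1: int) -> float:
    return (
        gammaln(n1 + 1) - gammaln(k + 1) - gammaln(n1 - k + 1)
        + gammaln(n2 + 1) - gammaln(c1 - k + 1) - gammaln(n2 - (c1 - k) + 1)
        - (gammaln(n1 + n2 + 1) - gammaln(c1 + 1) - gammaln(n1 + n2 - c1 + 1))
    )


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test by full hypergeometric enumeration.

    Two-sidedness by the point-probability rule: sum the probabilities
    of all tables (with the observed margins) no more probable than the
    observed one.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    a = int(t[0, 0])
    n1, n2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    if n1 == 0 or n2 == 0 or c1 == 0 or c1 == n1 + n2:
        return TestResult(float(a), 1.0, "fisher-exact", (n1, n2), exact=True)
    lo, hi = max(0, c1 - n2), min(n1, c1)
    logp = np.array([_hypergeom_logpmf(k, n1, n2, c1) for k in range(lo, hi + 1)])
    p_obs = logp[a - lo]
    mask = logp <= p_obs + 1e-9
    p = float(np.exp(logp[mask]).sum())
    return TestResult(float(a), min(p, 1.0), "fisher-exact", (n1, n2), exact=True)


def chi_square_independence(table) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("table must be a 2-D non-negative count grid")
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    total = t.sum()
    if total == 0:
        raise ValueError("empty table")
    expected = row @ col / total
    if (expected == 0).any():
        raise ValueError(
            "zero expected cell count; use fisher_exact_2x2 for sparse tables")
    x2 = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    if df == 0:
        return TestResult(x2, 1.0, "chi-square", tuple(int(r) for r in row.ravel()))
    p = float(chi2_dist.sf(x2, df))
    return TestResult(x2, p, "chi-square", tuple(int(r) for r in row.ravel()),
                      details={"df": df})


# ---------------------------------------------------------------------------
# Kruskal-Wallis

def kruskal_wallis(groups) -> TestResult:
    """Kruskal–Wallis H test with tie correction."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    if tie == 0:  # all values identical
        return TestResult(0.0, 1.0, "kruskal-wallis",
                          tuple(g.size for g in groups))
    h /= tie
    df = len(groups) - 1
    p = float(chi2_dist.sf(h, df))
    return TestResult(float(h), p, "kruskal-wallis",
                      tuple(g.size for g in groups), details={"df": df})


# ---------------------------------------------------------------------------
# one-way MANOVA, Wilks' lambda

@dataclass(frozen=True)
class ManovaResult:
    wilks_lambda: float
    f_statistic: float
    df1: float
    df2: float
    p_value: float
    per_response_f: np.ndarray
    per_response_p: np.ndarray
    n_used: tuple[int, ...]


def manova_wilks(responses, group_labels) -> ManovaResult:
    """One-way MANOVA via Wilks' lambda with Rao's F approximation.

    ``responses`` is an n x p grid (rows = observations); rows with any
    missing value are dropped (complete-case).  Also returns the
    univariate one-way ANOVA F and p per response column, so single
    clinical factors can be reported individually.  With p = 1 the
    multivariate F reduces exactly to the one-way ANOVA F.
    """
    y = np.atleast_2d(np.asarray(responses, dtype=float))
    if y.shape[0] == 1 and len(group_labels) != 1:
        y = y.T
    labels = np.asarray(group_labels)
    keep = ~np.isnan(y).any(axis=1)
    y, labels = y[keep], labels[keep]
    n, p = y.shape
    uniq = np.unique(labels)
    k = uniq.size
    if k < 2:
        raise ValueError("need >= 2 groups")
    if n <= p + k:
        raise ValueError(f"n = {n} too small for p = {p} responses, k = {k} groups")

    grand = y.mean(axis=0)
    w = np.zeros((p, p))
    b = np.zeros((p, p))
    sizes = []
    for g in uniq:
        yg = y[labels == g]
        sizes.append(yg.shape[0])
        dev = yg - yg.mean(axis=0)
        w += dev.T @ dev
        diff = (yg.mean(axis=0) - grand)[:, None]
        b += yg.shape[0] * (diff @ diff.T)

    sign, logdet_w = np.linalg.slogdet(w)
    if sign <= 0:
        diag = np.diag(w)
        bad = [int(i) for i in np.where(diag <= 1e-12)[0]]
        raise ValueError(
            f"singular within-group scatter (collinear/constant columns {bad})")
    _, logdet_t = np.linalg.slogdet(w + b)
    lam = float(np.exp(logdet_w - logdet_t))

    # Rao's F approximation
    df1 = p * (k - 1)
    denom = p ** 2 + (k - 1) ** 2 - 5
    t = math.sqrt((p ** 2 * (k - 1) ** 2 - 4) / denom) if denom > 0 else 1.0
    m = n - 1 - (p + k) / 2.0
    df2 = m * t - (df1 - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    if lam_t <= 0:
        f_stat, p_val = math.inf, 0.0
    elif df2 <= 0:
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat = (1 - lam_t) / lam_t * df2 / df1
        p_val = float(f_dist.sf(f_stat, df1, df2))

    # univariate one-way ANOVA per response
    f_uni = np.empty(p)
    p_uni = np.empty(p)
    for j in range(p):
        ssb, ssw = b[j, j], w[j, j]
        if ssw <= 0:
            f_uni[j] = math.inf if ssb > 0 else 0.0
            p_uni[j] = 0.0 if ssb > 0 else 1.0
        else:
            f_uni[j] = (ssb / (k - 1)) / (ssw / (n - k))
            p_uni[j] = float(f_dist.sf(f_uni[j], k - 1, n - k))

    return ManovaResult(lam, float(f_stat), float(df1), float(df2),
                        float(min(p_val, 1.0)), f_uni, p_uni, tuple(sizes))
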