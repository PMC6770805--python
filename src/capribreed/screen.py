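"""Pre-model statistical battery for fixed-effect screening.

Milk recording data routinely violate normality and homoscedasticity, so
before any mixed-model fit the candidate fixed effects are screened with a
rank-based battery: Kruskal-Wallis H per factor with an F conversion and a
partial eta-squared effect size, Dunn's pairwise post-hoc tests under a
Bonferroni family correction, the Shapiro-Francia normality test, Levene's
(median-centred) homoscedasticity test, an independent-samples median test,
Spearman correlations and adjusted sample moments.

The F and effect-size conversions are F = H / dfn and
eta_p^2 = F*dfn / (F*dfn + dfd) with dfn = levels - 1, dfd = n - levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FactorTestResult:
    factor: str
    trait: str
    H: float
    p_value: float
    dfn: int
    dfd: int
    F: float
    eta_p2: float


def _group_arrays(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    return [values[groups == g] for g in labels], labels


def kruskal_wallis(values, groups):
    """Tie-corrected Kruskal-Wallis H with chi-square p-value.

    Returns (H, p, dfn, dfd).  H is defined as 0 when all values are tied.
    """
    arrays, labels = _group_arrays(values, groups)
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    n = sum(len(a) for a in arrays)
    if np.ptp(np.concatenate(arrays)) == 0:
        return 0.0, 1.0, len(arrays) - 1, n - len(arrays)
    H, p = stats.kruskal(*arrays)
    return float(H), float(p), len(arrays) - 1, n - len(arrays)


def h_to_f(H: float, dfn: int) -> float:
    """Convert a Kruskal-Wallis H statistic to its F-scale equivalent H/dfn."""
    if dfn < 1:
        raise ValueError("dfn must be >= 1")
    return H / dfn


def partial_eta_squared(F: float, dfn: int, dfd: int) -> float:
    """Partial eta squared from an F statistic: F*dfn / (F*dfn + dfd)."""
    if dfn < 1 or dfd < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return F * dfn / (F * dfn + dfd)


def factor_screen(values, groups, factor: str = "", trait: str = "") -> FactorTestResult:
    """Full Kruskal-Wallis row: H, p, df, F conversion and eta_p^2."""
    H, p, dfn, dfd = kruskal_wallis(values, groups)
    F = h_to_f(H, dfn)
    return FactorTestResult(factor, trait, H, p, dfn, dfd, F, partial_eta_squared(F, dfn, dfd))


def screen_dataset(records: pd.DataFrame, traits, factors) -> pd.DataFrame:
    """One Kruskal-Wallis row per trait x factor, mirroring the screening table."""
    rows = []
    for fac in factors:
        for t in traits:
            r = factor_screen(records[t], records[fac], factor=fac, trait=t)
            rows.append(vars(r))
    return pd.DataFrame(rows)


def dunn_bonferroni(values, groups) -> pd.DataFrame:
    """Dunn's rank-based pairwise post-hoc z tests with Bonferroni adjustment.

    The z statistic for groups i, j uses the tie-corrected variance
    (N(N+1)/12 - sum(t^3 - t)/(12(N-1))) (1/n_i + 1/n_j) on mean ranks; the
    Bonferroni family is all k(k-1)/2 level pairs of the factor.
    """
    arrays, labels = _group_arrays(values, groups)
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) < 1 for a in arrays):
        raise ValueError("empty group")
    all_vals = np.concatenate(arrays)
    N = len(all_vals)
    ranks = stats.rankdata(all_vals)
    mean_ranks = []
    pos = 0
    for a in arrays:
        mean_ranks.append(ranks[pos : pos + len(a)].mean())
        pos += len(a)
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    base_var = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1)) if N > 1 else 0.0
    k = len(arrays)
    family = k * (k - 1) // 2
    rows = []
    for (i, j) in combinations(range(k), 2):
        se = np.sqrt(base_var * (1.0 / len(arrays[i]) + 1.0 / len(arrays[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "z": z,
                "p_raw": p_raw,
                "p_adjusted": min(1.0, family * p_raw),
            }
        )
    return pd.DataFrame(rows)


def shapiro_francia(values):
    """Shapiro-Francia W' normality test for 5 <= n <= 5000.

    W' is the squared correlation between the order statistics and Blom
    normal scores; the p-value uses Royston's normal approximation for
    log(1 - W').
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 5 or n > 5000:
        raise ValueError("Shapiro-Francia requires 5 <= n <= 5000")
    m = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    w = np.corrcoef(x, m)[0, 1] ** 2
    u, v = np.log(n), np.log(np.log(n))
    mu = -1.2725 + 1.0521 * (v - u)
    sigma = 1.0308 - 0.26758 * (v + 2.0 / u)
    z = (np.log(1.0 - w) - mu) / sigma
    return float(w), float(stats.norm.sf(z))


def levene_median(values, groups):
    """Levene's homoscedasticity test with group-median centring
    (Brown-Forsythe variant)."""
    arrays, _ = _group_arrays(values, groups)
    stat, p = stats.levene(*arrays, center="median")
    return float(stat), float(p)


def median_test(values, groups):
    """Independent-samples median test (grand-median chi-square)."""
    arrays, _ = _group_arrays(values, groups)
    stat, p, _, _ = stats.median_test(*arrays)
    return float(stat), float(p)


def spearman_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho correlation matrix over the columns of `df`."""
    rho = stats.spearmanr(df.to_numpy()).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    return pd.DataFrame(rho, index=df.columns, columns=df.columns)


def sample_moments(values):
    """Adjusted (bias-corrected) sample skewness and excess kurtosis."""
    x = np.asarray(values, dtype=float)
    return (
        float(stats.skew(x, bias=False)),
        float(stats.kurtosis(x, bias=False)),
    )


def supporting_tests(values, groups) -> dict:
    """Levene (median-centred), median test, and adjusted moments in one call."""
    lev_stat, lev_p = levene_median(values, groups)
    med_stat, med_p = median_test(values, groups)
    skew, kurt = sample_moments(values)
    return {
        "levene_stat": lev_stat,
        "levene_p": lev_p,
        "median_stat": med_stat,
        "median_p": med_p,
        "skewness": skew,
        "kurtosis": kurt,
    }
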