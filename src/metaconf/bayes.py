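"""Frequentist t-tests, JZS Bayes-factor t-tests, and a 2x2 chi-square.

The Bayes factor follows the Jeffreys-Zellner-Siow two-sample formulation:
a Cauchy prior with scale ``r_scale`` on the standardized effect size,
integrated numerically over the prior's inverse-gamma mixing variable.
BF10 > 1 favors a group difference, BF10 < 1 favors the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    variant: str


@dataclass(frozen=True)
class BFResult:
    bf10: float
    t: float
    n1: int
    n2: int
    r_scale: float
    integration_error: float


def two_sample_t(
    x=None,
    y=None,
    *,
    mean1=None,
    sd1=None,
    n1=None,
    mean2=None,
    sd2=None,
    n2=None,
    variant: str = "welch",
) -> TTestResult:
    """Two-sided two-sample t-test from raw vectors or summary statistics.

    ``variant`` selects Welch (unequal variances, Welch-Satterthwaite df)
    or pooled-variance Student formulas.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    if x is not None:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        mean1, sd1, n1 = x.mean(), x.std(ddof=1), len(x)
        mean2, sd2, n2 = y.mean(), y.std(ddof=1), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValueError("sds must be >= 0 and not both 0")
    res = stats.ttest_ind_from_stats(
        mean2, sd2, n2, mean1, sd1, n1, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = n1 + n2 - 2
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TTestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue), variant=variant)


def jzs_bf(t: float, n1: int, n2: int, r_scale: float = 0.7) -> BFResult:
    """Two-sided JZS Bayes factor for a two-sample t statistic.

    Effective sample size n1*n2/(n1+n2), df n1+n2-2.  The marginal
    likelihood under H1 integrates over g ~ InverseGamma(1/2, r^2/2)
    (the Cauchy prior's mixing variable) with the substitution
    g = u/(1-u) mapping the integral onto the unit interval.
    Symmetric in the sign of t; monotone increasing in |t|.
    """
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if r_scale <= 0:
        raise ValueError("r_scale must be > 0")
    neff = n1 * n2 / (n1 + n2)
    nu = n1 + n2 - 2
    t2 = t * t

    def log_h1_integrand(g):
        return (
            -0.5 * np.log1p(neff * g)
            - 0.5 * (nu + 1) * np.log1p(t2 / ((1 + neff * g) * nu))
            + 0.5 * np.log(r_scale**2 / (2 * np.pi))
            - 1.5 * np.log(g)
            - r_scale**2 / (2 * g)
        )

    def integrand(u):
        g = u / (1.0 - u)
        return np.exp(log_h1_integrand(g)) / (1.0 - u) ** 2

    num, err = integrate.quad(integrand, 0.0, 1.0, epsabs=1e-10, epsrel=1e-8, limit=200)
    if not np.isfinite(num) or num <= 0:
        raise ArithmeticError(f"JZS quadrature failed (value {num}, error {err})")
    log_null = -0.5 * (nu + 1) * np.log1p(t2 / nu)
    bf10 = num / np.exp(log_null)
    return BFResult(
        bf10=float(bf10),
        t=float(t),
        n1=int(n1),
        n2=int(n2),
        r_scale=float(r_scale),
        integration_error=float(err / np.exp(log_null)),
    )


def chi_square_2x2(counts) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) for a 2x2 table."""
    table = np.asarray(counts)
    if table.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)
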