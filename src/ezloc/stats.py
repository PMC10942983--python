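"""Bayes-factor t-tests with JZS (Cauchy) priors, and Pearson correlation.

Inference on AUC distributions and feature-contribution vectors uses
Bayes factors rather than p-values, so evidence for the *null* (e.g.
at-chance classification) is expressible.  BF10 is the marginal
likelihood ratio of an alternative with a Cauchy effect-size prior
(scale r, default sqrt(2)/2) against the point null, computed by the
standard one-dimensional integral over the Zellner-Siow g-prior
representation (Cauchy = scale mixture of normals with inverse-gamma
mixing), evaluated by adaptive quadrature.

Evidence bins follow the usual rules of thumb: BF10 >= 10 or <= 1/10 is
significant evidence (for H1 / H0), 3..10 and 1/10..1/3 plain evidence,
and anything in (1/3, 3) insufficient either way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy import stats as sp_stats

DEFAULT_PRIOR_SCALE = math.sqrt(2) / 2

EVIDENCE_BINS = (
    "significant_H1",
    "evidence_H1",
    "insufficient",
    "evidence_H0",
    "significant_H0",
)


@dataclass
class BayesFactorResult:
    bf10: float
    t: float
    n: int
    n2: int | None
    test: str  # paired | unpaired | one-sample
    prior_scale: float
    evidence_bin: str


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


# ---------------------------------------------------------------------------
# JZS Bayes factor
# ---------------------------------------------------------------------------


def jzs_bf10_from_t(
    t: float, n: float, df: float, prior_scale: float = DEFAULT_PRIOR_SCALE
) -> float:
    """BF10 from a t statistic.

    ``n`` is the effective sample size (n for one-sample/paired,
    n1*n2/(n1+n2) for two-sample) and ``df`` the degrees of freedom.
    The alternative's marginal likelihood integrates over g with the
    inverse-gamma(1/2, r^2/2) mixing density of the Cauchy prior::

        BF10 = int_0^inf (1+ng)^(-1/2) * (1 + t^2/((1+ng) df))^(-(df+1)/2)
               * r/sqrt(2 pi) * g^(-3/2) * exp(-r^2/(2g)) dg
               / (1 + t^2/df)^(-(df+1)/2)
    """
    if df <= 0 or n <= 0:
        raise ValueError("need positive effective n and degrees of freedom")
    r = prior_scale
    t2 = t * t

    # Work in log space inside the integrand for numerical range.
    def integrand(g: float) -> float:
        log_term = (
            -0.5 * math.log1p(n * g)
            - (df + 1) / 2 * math.log1p(t2 / ((1 + n * g) * df))
            + math.log(r) - 0.5 * math.log(2 * math.pi)
            - 1.5 * math.log(g) - r * r / (2 * g)
        )
        return math.exp(log_term)

    # Substitute g = u/(1-u) to map (0, inf) -> (0, 1); quad handles the
    # remaining integrable endpoint behaviour.
    def integrand_u(u: float) -> float:
        g = u / (1 - u)
        return integrand(g) / (1 - u) ** 2

    alt, err = integrate.quad(
        integrand_u, 0.0, 1.0, epsabs=0.0, epsrel=1e-9, limit=200
    )
    if not np.isfinite(alt) or alt <= 0:
        raise ArithmeticError(
            f"JZS integral did not converge (value={alt}, abserr={err}, t={t}, n={n})"
        )
    if err > 1e-6 * alt:
        raise ArithmeticError(
            f"JZS integral relative error {err / alt:.2e} exceeds tolerance"
        )
    null = (1 + t2 / df) ** (-(df + 1) / 2)
    return float(alt / null)


def interpret_bf(bf10: float) -> str:
    """Map a Bayes factor to its evidence bin.

    Boundary values go to the stronger-evidence bin (BF10 = 3 counts as
    evidence for H1, BF10 = 1/3 as evidence for H0, and likewise at
    10 / 1/10).
    """
    if bf10 <= 0:
        raise ValueError("BF10 must be positive")
    if bf10 >= 10:
        return "significant_H1"
    if bf10 >= 3:
        return "evidence_H1"
    if bf10 <= 1 / 10:
        return "significant_H0"
    if bf10 <= 1 / 3:
        return "evidence_H0"
    return "insufficient"


def bf_ttest(
    sample_a,
    sample_b=None,
    null_mean: float = 0.0,
    paired: bool = False,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> BayesFactorResult:
    """JZS Bayes-factor t-test.

    One-sample against ``null_mean`` when ``sample_b`` is None; paired
    reduces to a one-sample test on the differences; unpaired uses the
    pooled-variance two-sample t statistic.
    """
    a = np.asarray(sample_a, dtype=float)
    if not np.isfinite(a).all():
        raise ValueError("sample_a contains non-finite values")
    if sample_b is not None and paired:
        b = np.asarray(sample_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired samples must have equal length")
        a = a - b
        sample_b = None
        test = "paired"
    elif sample_b is None:
        test = "one-sample"

    if sample_b is None:
        n = a.size
        if n < 3:
            raise ValueError("need n >= 3")
        sd = a.std(ddof=1)
        if sd == 0:
            raise ValueError("zero-variance sample")
        t = (a.mean() - null_mean) / (sd / math.sqrt(n))
        bf = jzs_bf10_from_t(t, n, n - 1, prior_scale)
        return BayesFactorResult(bf, float(t), n, None, test, prior_scale,
                                 interpret_bf(bf))

    b = np.asarray(sample_b, dtype=float)
    if not np.isfinite(b).all():
        raise ValueError("sample_b contains non-finite values")
    n1, n2 = a.size, b.size
    if n1 < 3 or n2 < 3:
        raise ValueError("need n >= 3 per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("zero-variance samples")
    t, _ = sp_stats.ttest_ind(a, b, equal_var=True)
    n_eff = n1 * n2 / (n1 + n2)
    bf = jzs_bf10_from_t(float(t), n_eff, n1 + n2 - 2, prior_scale)
    return BayesFactorResult(bf, float(t), n1, n2, "unpaired", prior_scale,
                             interpret_bf(bf))


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with the two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs contain non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    res = sp_stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), x.size)


__all__ = [
    "DEFAULT_PRIOR_SCALE",
    "EVIDENCE_BINS",
    "BayesFactorResult",
    "CorrelationResult",
    "jzs_bf10_from_t",
    "interpret_bf",
    "bf_ttest",
    "pearson",
]
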