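"""Lognormal distribution primitives for tolerance-distribution dose-response.

The model treats both the radiation dose received by an individual and that
individual's critical (threshold) dose as independent lognormal random
variables.  An adverse outcome occurs when the dose exceeds the individual
threshold, so the population response rate is an exceedance probability.
Because log-dose and log-threshold are both normal, the exceedance
probability has the closed form

    P(X1 > X2) = Phi((mu1 - mu2) / sqrt(sigma1^2 + sigma2^2)),

and the response rate plotted against the *mean* dose exp(mu1 + sigma1^2/2)
traces a cumulative lognormal with location mu2 + sigma1^2/2 and spread
sqrt(sigma1^2 + sigma2^2).  These closed forms are the analytic oracles for
the Monte Carlo simulator and the curve fitters in the rest of the package.

Dose units are carried as labels only (mSv for doses, Bq/kg for body
burdens); "log" is the natural logarithm throughout, so mu is the log of
the distribution median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = [
    "LognormalParams",
    "ResponseCurve",
    "lognormal_pdf",
    "lognormal_cdf",
    "exceedance_probability",
    "derived_response_curve",
    "expected_mean_dose",
    "lognormal_quantile",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class LognormalParams:
    """Parameters (mu, sigma) of a lognormal dose or threshold distribution.

    mu is the natural log of the median; sigma is the log-scale standard
    deviation.  sigma = 0 is the degenerate "discrete dose" case: a point
    mass at exp(mu), supported by the cdf and the simulator but not by the
    density.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu}")
        if not (self.sigma >= 0.0):
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def median(self) -> float:
        return math.exp(self.mu)

    @property
    def is_degenerate(self) -> bool:
        return self.sigma == 0.0


@dataclass(frozen=True)
class ResponseCurve:
    """Cumulative-lognormal dose-response curve with location mu and spread sigma.

    ``response(x)`` is strictly increasing for x > 0 with limits 0 at 0+ and
    1 at infinity.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0.0):
            raise ValueError(f"response-curve sigma must be > 0, got {self.sigma}")

    def response(self, x):
        """Response probability at dose ``x`` (scalar or array, x > 0)."""
        return lognormal_cdf(x, LognormalParams(self.mu, self.sigma))


def lognormal_pdf(x, params: LognormalParams):
    """Lognormal density 1/(x sigma sqrt(2 pi)) exp(-(log x - mu)^2 / (2 sigma^2)).

    Requires x > 0 and params.sigma > 0 (the degenerate point mass has no
    density).  Accepts scalars or arrays.
    """
    if params.sigma <= 0.0:
        raise ValueError("pdf undefined for sigma <= 0 (point mass)")
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0):
        raise ValueError("lognormal pdf requires x > 0")
    z = (np.log(x) - params.mu) / params.sigma
    out = np.exp(-0.5 * z * z) / (x * params.sigma * _SQRT_2PI)
    return out if out.ndim else float(out)


def lognormal_cdf(x, params: LognormalParams):
    """P(X <= x) for X lognormal(mu, sigma); unit step at exp(mu) when sigma = 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0):
        raise ValueError("lognormal cdf requires x > 0")
    if params.is_degenerate:
        out = (x >= params.median).astype(float)
    else:
        out = ndtr((np.log(x) - params.mu) / params.sigma)
    return out if out.ndim else float(out)


def exceedance_probability(dose: LognormalParams, threshold: LognormalParams) -> float:
    """P(dose draw > threshold draw) for independent lognormal variables.

    Equals Phi((mu1 - mu2)/sqrt(sigma1^2 + sigma2^2)).  With both sigmas
    zero the comparison is deterministic (1 if exp(mu1) > exp(mu2), else 0;
    a tie counts as no exceedance since the comparison is strict).
    """
    s2 = dose.sigma**2 + threshold.sigma**2
    if s2 == 0.0:
        return 1.0 if dose.mu > threshold.mu else 0.0
    return float(ndtr((dose.mu - threshold.mu) / math.sqrt(s2)))


def derived_response_curve(sigma1: float, threshold: LognormalParams) -> ResponseCurve:
    """Dose-response curve implied by dose dispersion sigma1 and a threshold distribution.

    Location mu = mu2 + sigma1^2/2 and spread sigma = sqrt(sigma1^2 + sigma2^2):
    evaluating this cumulative lognormal at the mean dose exp(mu1 + sigma1^2/2)
    reproduces the exceedance probability for every mu1 (an algebraic
    identity).  sigma1 = 0 returns the no-dispersion curve (mu2, sigma2).
    """
    if sigma1 < 0.0:
        raise ValueError(f"sigma1 must be >= 0, got {sigma1}")
    if threshold.sigma <= 0.0:
        raise ValueError("threshold.sigma must be > 0 for a response curve")
    return ResponseCurve(
        mu=threshold.mu + 0.5 * sigma1**2,
        sigma=math.sqrt(sigma1**2 + threshold.sigma**2),
    )


def expected_mean_dose(dose: LognormalParams) -> float:
    """First moment exp(mu + sigma^2/2) of the dose distribution (>= the median)."""
    return math.exp(dose.mu + 0.5 * dose.sigma**2)


def lognormal_quantile(p: float, params: LognormalParams) -> float:
    """Inverse cdf exp(mu + sigma * Phi^-1(p)) for 0 < p < 1 (sigma > 0)."""
    if not 0.0 < p < 1.0:
        raise ValueError("quantile requires 0 < p < 1")
    if params.is_degenerate:
        return params.median
    return math.exp(params.mu + params.sigma * float(ndtri(p)))
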