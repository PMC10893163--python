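"""CLT-based study power for detecting a difference between two populations.

An endpoint (Cmax or AUC) is assumed normal in each population:
x ~ N(mu1, sigma1^2) and y ~ N(mu2, sigma2^2), so the sample means follow
x_bar ~ N(mu1, sigma1^2/n1) and y_bar ~ N(mu2, sigma2^2/n2).  The critical
region is built from Population 1's sampling distribution at significance
level alpha (two-sided by default):

    reject when |x_bar - mu1| > z_{1-alpha/2} * sigma1 / sqrt(n1)

and the power is the probability that the Population 2 sample mean falls in
that region.  In the null case (mu2 = mu1, sigma2 = sigma1, n2 = n1) the
power equals alpha exactly by construction.

Population summaries are normally estimated from endpoint samples produced
by the simulation pipeline itself; a log-scale option is provided since PK
endpoints are typically closer to log-normal than normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError, DataError

__all__ = ["PowerInput", "PowerCurve", "study_power", "power_curve",
           "summaries_from_samples"]


@dataclass(frozen=True)
class PowerInput:
    """Normal-population summaries and sample sizes for one endpoint."""

    mu1: float
    sigma1_sq: float
    mu2: float
    sigma2_sq: float
    n1: int
    n2: int
    alpha: float = 0.05
    endpoint: str = ""

    def __post_init__(self):
        if not (self.sigma1_sq > 0 and self.sigma2_sq > 0):
            raise DataError("variances must be > 0")
        if self.n1 < 2 or self.n2 < 2:
            raise DataError("sample sizes must be >= 2")
        if not (0.0 < self.alpha < 1.0):
            raise DataError(f"alpha must be in (0, 1), got {self.alpha}")


def study_power(inp: PowerInput, *, two_sided: bool = True) -> float:
    """Probability of detecting the population difference.

    Two-sided by default; the one-sided variant uses the upper critical
    value mu1 + z_{1-alpha} * sigma1/sqrt(n1) only.
    """
    se1 = math.sqrt(inp.sigma1_sq / inp.n1)
    se2 = math.sqrt(inp.sigma2_sq / inp.n2)
    if two_sided:
        crit = norm.ppf(1.0 - inp.alpha / 2.0) * se1
        lower = norm.cdf((inp.mu1 - crit - inp.mu2) / se2)
        upper = norm.sf((inp.mu1 + crit - inp.mu2) / se2)
        power = lower + upper
    else:
        crit = norm.ppf(1.0 - inp.alpha) * se1
        power = norm.sf((inp.mu1 + crit - inp.mu2) / se2)
    return float(min(max(power, 0.0), 1.0))


def summaries_from_samples(samples1, samples2, *, log_scale: bool = False):
    """(mu, sigma^2) per population from endpoint samples (ddof=1)."""
    x = np.asarray(samples1, dtype=float)
    y = np.asarray(samples2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DataError("need >= 2 samples per population")
    if log_scale:
        if np.any(x <= 0) or np.any(y <= 0):
            raise DataError("log-scale summaries require positive endpoint values")
        x, y = np.log(x), np.log(y)
    return (float(x.mean()), float(x.var(ddof=1)),
            float(y.mean()), float(y.var(ddof=1)))


@dataclass(frozen=True)
class PowerCurve:
    """Power tabulated over per-arm sample sizes for one endpoint."""

    endpoint: str
    n_values: tuple
    powers: tuple
    alpha: float = 0.05

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "endpoint": self.endpoint, "n": self.n_values, "power": self.powers,
        })

    def smallest_n(self, target: float) -> int | None:
        """Smallest per-arm n reaching ``target`` power; None if not reached."""
        for n, p in zip(self.n_values, self.powers):
            if p >= target:
                return int(n)
        return None


def power_curve(
    samples1,
    samples2,
    *,
    n_min: int = 8,
    n_max: int = 200,
    alpha: float = 0.05,
    endpoint: str = "",
    two_sided: bool = True,
    log_scale: bool = False,
) -> PowerCurve:
    """Sweep study power over equal per-population sample sizes n_min..n_max.

    Population means and variances are estimated once from the supplied
    endpoint samples; the sweep varies only the hypothetical trial size.
    """
    if n_min < 2 or n_max < n_min:
        raise ConfigError("need 2 <= n_min <= n_max")
    mu1, s1, mu2, s2 = summaries_from_samples(samples1, samples2,
                                              log_scale=log_scale)
    ns = tuple(range(n_min, n_max + 1))
    powers = tuple(
        study_power(
            PowerInput(mu1=mu1, sigma1_sq=s1, mu2=mu2, sigma2_sq=s2,
                       n1=n, n2=n, alpha=alpha, endpoint=endpoint),
            two_sided=two_sided,
        )
        for n in ns
    )
    return PowerCurve(endpoint=endpoint, n_values=ns, powers=powers, alpha=alpha)
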