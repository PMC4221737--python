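"""Gamma-distribution velocimetry statistics and group comparison.

Pooled velocity samples are modelled by the two-parameter gamma density

    f(x; k, theta) = x^(k-1) e^(-x/theta) / (Gamma(k) theta^k),   x >= 0,

with shape ``k > 0`` and scale ``theta > 0``; the mean velocity reported
per cell is ``k * theta``.  Both maximum-likelihood and method-of-moments
fits pin the fitted mean to the sample mean exactly (for the MLE this is a
property of the gamma likelihood; for moments it is algebraic), so ``kθ``
always equals the sample mean to machine precision.

Replicate means are compared with the two-sample Student's t-test
(equal-variance, two-sided; Welch by flag) and labelled with the
significance tiers ***  (p < 0.001), **  (p < 0.01), n.s. otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats as sps

from .geometry import VelocitySampleSet
from .imaging import ConfigurationError

logger = logging.getLogger("actinflow.stats")

__all__ = [
    "GammaFit",
    "GroupComparison",
    "DegenerateFitError",
    "gamma_pdf",
    "fit_gamma",
    "mean_velocity",
    "compare_groups",
    "significance_tier",
    "histogram_distribution",
]

MIN_SAMPLES = 50


class DegenerateFitError(ValueError):
    """Samples carry no usable spread (all zero or all equal)."""


@dataclass
class GammaFit:
    """Fitted gamma parameters with diagnostics.

    ``mean`` is ``k * theta`` by construction; ``gof`` is the
    Kolmogorov–Smirnov statistic against the fitted distribution
    (diagnostic only, no p-value is attached)."""

    k: float
    theta: float
    mean: float
    n_samples: int
    method: str  # mle | moments
    gof: float
    n_zeros_dropped: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k) and self.k > 0):
            raise DegenerateFitError(f"shape k must be finite positive, got {self.k}")
        if not (np.isfinite(self.theta) and self.theta > 0):
            raise DegenerateFitError(f"scale theta must be finite positive, got {self.theta}")


@dataclass
class GroupComparison:
    """Two-group comparison of per-replicate mean velocities."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float
    tier: str
    equal_var: bool = True


# ---------------------------------------------------------------------------
# the gamma density
# ---------------------------------------------------------------------------

def gamma_pdf(x, k: float, theta: float):
    """Gamma density evaluated in log space for stability.

    Accepts scalars or arrays; raises on x < 0 or non-positive parameters.
    At x = 0 the density is 0 for k > 1, 1/theta for k = 1 and diverges
    (returns inf) for k < 1.
    """
    if not (k > 0 and theta > 0):
        raise ConfigurationError("k and theta must be > 0")
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ConfigurationError("gamma density is defined on x >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        logpdf = (
            (k - 1.0) * np.log(x_arr)
            - x_arr / theta
            - special.gammaln(k)
            - k * np.log(theta)
        )
        out = np.exp(logpdf)
    if np.any(x_arr == 0):
        at0 = np.inf if k < 1 else (1.0 / theta if k == 1 else 0.0)
        out = np.where(x_arr == 0, at0, out)
    return float(out) if np.isscalar(x) else out


def _gamma_cdf(x: np.ndarray, k: float, theta: float) -> np.ndarray:
    return special.gammainc(k, np.asarray(x, dtype=float) / theta)


def _ks_statistic(samples: np.ndarray, k: float, theta: float) -> float:
    s = np.sort(samples)
    n = s.size
    cdf = _gamma_cdf(s, k, theta)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(max(np.max(ecdf_hi - cdf), np.max(cdf - ecdf_lo)))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _solve_mle_shape(s: float) -> float:
    """Solve log(k) - digamma(k) = s for k > 0 by bracketed root finding."""
    # Minka's closed-form starter, then brentq on the monotone residual
    k0 = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    f = lambda k: np.log(k) - special.digamma(k) - s
    lo, hi = k0 / 8.0, k0 * 8.0
    while f(lo) < 0:  # log k - psi(k) decreases in k; widen until bracketed
        lo /= 8.0
    while f(hi) > 0:
        hi *= 8.0
    return float(optimize.brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16))


def fit_gamma(
    samples: VelocitySampleSet | np.ndarray | Sequence[float],
    method: str = "mle",
) -> GammaFit:
    """Fit the gamma distribution to pooled velocity samples.

    MLE (default): the shape solves ``log k - psi(k) = log(mean) -
    mean(log)`` and ``theta = mean / k``, so the fitted mean ``k*theta``
    equals the sample mean exactly.  Moments: ``k = mean^2/var``,
    ``theta = var/mean`` (same identity).  Exact zeros are dropped with a
    logged count; fewer than 50 remaining samples, or samples without
    spread, are refused.
    """
    if method not in ("mle", "moments"):
        raise ConfigurationError("method must be 'mle' or 'moments'")
    values = samples.values if isinstance(samples, VelocitySampleSet) else np.asarray(
        samples, dtype=float
    )
    if values.ndim != 1:
        raise ConfigurationError("samples must be 1-D")
    if np.any(values < 0):
        raise ConfigurationError("velocity samples must be nonnegative")
    n_zeros = int((values == 0).sum())
    if n_zeros:
        logger.info("dropping %d exact-zero sample(s) before the gamma fit", n_zeros)
    x = values[values > 0]
    if x.size < MIN_SAMPLES:
        raise ConfigurationError(
            f"need at least {MIN_SAMPLES} positive samples to fit (got {x.size}); "
            "pool more frame pairs or enlarge the region"
        )
    if np.ptp(x) == 0:
        raise DegenerateFitError("all samples equal: gamma fit is degenerate")

    m = float(x.mean())
    if method == "moments":
        v = float(x.var(ddof=1))
        if v == 0:
            raise DegenerateFitError("zero variance: gamma fit is degenerate")
        k = m * m / v
        theta = v / m
    else:
        s = float(np.log(m) - np.mean(np.log(x)))
        if not s > 0:
            raise DegenerateFitError("non-positive log-moment gap: degenerate samples")
        k = _solve_mle_shape(s)
        theta = m / k

    return GammaFit(
        k=k, theta=theta, mean=k * theta,
        n_samples=int(x.size), method=method,
        gof=_ks_statistic(x, k, theta), n_zeros_dropped=n_zeros,
    )


def mean_velocity(fit: GammaFit) -> float:
    """Mean of the fitted distribution, k * theta, in the sample units."""
    return fit.k * fit.theta


def shape_mle_standard_errors(k: float, n: int) -> tuple[float, float]:
    """Asymptotic standard errors of (k_hat, theta_hat/theta) from the
    Fisher information of the gamma likelihood."""
    trig = special.polygamma(1, k)
    denom = n * (k * trig - 1.0)
    se_k = np.sqrt(k / denom)
    se_theta_rel = np.sqrt(trig / denom)  # multiply by theta for absolute SE
    return float(se_k), float(se_theta_rel)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def significance_tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return "n.s."


def compare_groups(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sided two-sample Student's t-test on per-replicate mean velocities.

    Reports both SD and SEM per group alongside t, p and the significance
    tier.  ``equal_var=False`` switches to Welch's correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("each group needs at least two replicates")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
        sem_a=float(a.std(ddof=1) / np.sqrt(a.size)),
        sem_b=float(b.std(ddof=1) / np.sqrt(b.size)),
        n_a=int(a.size), n_b=int(b.size),
        t_statistic=float(t), p_value=float(p),
        tier=significance_tier(float(p)), equal_var=equal_var,
    )


# ---------------------------------------------------------------------------
# histogram distributions for the distribution plots
# ---------------------------------------------------------------------------

def histogram_distribution(
    samples: VelocitySampleSet | np.ndarray | Sequence[float],
    bin_width: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized probability distribution: (bin_edges, probabilities).

    Probabilities sum to exactly 1 (counts / n, not a density)."""
    values = samples.values if isinstance(samples, VelocitySampleSet) else np.asarray(
        samples, dtype=float
    )
    if values.size == 0:
        raise ConfigurationError("need at least one sample")
    if not bin_width > 0:
        raise ConfigurationError("bin_width must be > 0")
    lo = 0.0 if values.min() >= 0 else np.floor(values.min() / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((values.max() - lo) / bin_width + 1e-12)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    if edges[-1] <= values.max():
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return edges, counts / values.size
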