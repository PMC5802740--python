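"""Classical P-intervals and conjugate-normal Bayes prediction intervals.

For a normally distributed test statistic Z ~ N(mu, 1) with a conjugate
prior mu ~ N(m0, sigma0^2), sigma0^2 = N*s0^2, the posterior for mu given
an observed z_obt is normal with

    theta = z_obt * sigma0^2/(1 + sigma0^2) + m0/(1 + sigma0^2)
    s^2   = sigma0^2/(1 + sigma0^2)

and the predictive distribution for an independent replication statistic is
N(theta, 1 + s^2).  The classical P-interval, z_obt +/- q*sqrt(2), is the
sigma0^2 -> infinity limit: it implicitly assumes a flat prior on the
standardized effect, which is why it misbehaves under P-value selection
when realistic (small) prior variances apply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .transforms import (
    NORMAL_SPEC,
    Sidedness,
    TestSpec,
    p_to_stat,
    stat_to_p,
)

__all__ = [
    "ConjugateNormalPrior",
    "ConjugatePosterior",
    "PredictionInterval",
    "classical_p_interval",
    "conjugate_posterior",
    "conjugate_prediction_interval",
    "posterior_null_probability",
]


@dataclass(frozen=True)
class ConjugateNormalPrior:
    """Zero-or-nonzero-mean normal prior on the standardized effect size.

    Parameters
    ----------
    m0 : float
        Prior mean on the statistic scale (default 0; effects are equally
        likely in either direction a priori).
    s0_sq : float, optional
        Prior variance of the standardized effect delta.  Scaled onto the
        statistic scale as ``sigma0_sq = effective_n * s0_sq``.
    sigma0_sq : float, optional
        Prior variance on the statistic scale, supplied directly.  Exactly
        one of ``s0_sq``/``sigma0_sq`` is required unless both are
        consistent.
    effective_n : float
        Effective sample size used for the scaling (default 1).
    """

    m0: float = 0.0
    s0_sq: float | None = None
    sigma0_sq: float | None = None
    effective_n: float = 1.0

    def __post_init__(self) -> None:
        if self.effective_n <= 0:
            raise ValueError("effective_n must be positive")
        if self.sigma0_sq is None:
            if self.s0_sq is None:
                raise ValueError("supply s0_sq or sigma0_sq")
            object.__setattr__(self, "sigma0_sq", self.effective_n * self.s0_sq)
        elif self.s0_sq is None:
            object.__setattr__(self, "s0_sq", self.sigma0_sq / self.effective_n)
        elif not math.isclose(
            self.sigma0_sq, self.effective_n * self.s0_sq, rel_tol=1e-9, abs_tol=1e-15
        ):
            raise ValueError("s0_sq and sigma0_sq are inconsistent")
        if self.sigma0_sq < 0:
            raise ValueError("prior variance must be nonnegative")

    @property
    def vartheta(self) -> float:
        """Prior standard deviation of the standardized effect, sqrt(s0_sq)."""
        return math.sqrt(self.s0_sq)


@dataclass(frozen=True)
class ConjugatePosterior:
    """Normal posterior N(theta, s_sq) for the mean of the Z statistic."""

    theta: float
    s_sq: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.s_sq < 1.0:
            raise ValueError("posterior variance must lie in [0, 1)")

    def predictive(self):
        """Frozen predictive distribution N(theta, 1 + s_sq) for Z_rep."""
        return stats.norm(self.theta, math.sqrt(1.0 + self.s_sq))


@dataclass(frozen=True)
class PredictionInterval:
    """Equal-tailed prediction interval on both statistic and P scales.

    ``p_lower``/``p_upper`` are the ascending images of the statistic
    endpoints under the replication P-value map (one-sided upper by
    default, so ``p_lower`` corresponds to ``stat_upper``).
    """

    level: float
    stat_lower: float
    stat_upper: float
    p_lower: float
    p_upper: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0, 1)")
        if self.stat_lower > self.stat_upper or self.p_lower > self.p_upper:
            raise ValueError("interval endpoints out of order")

    @property
    def p_width(self) -> float:
        return self.p_upper - self.p_lower

    @property
    def neglog10_bounds(self) -> tuple[float, float]:
        """(-log10 p_upper, -log10 p_lower): ascending on the -log10 scale."""
        return (-math.log10(self.p_upper), -math.log10(self.p_lower))


def interval_from_stat_bounds(
    lo: float,
    hi: float,
    level: float,
    method: str,
    spec: TestSpec = NORMAL_SPEC,
    rep_conv: Sidedness = Sidedness.ONE_SIDED_UPPER,
) -> PredictionInterval:
    """Package statistic-scale endpoints with their P-scale images.

    The replication P map is the upper tail of the family's central
    distribution, so it is decreasing in the statistic and the P endpoints
    are swapped before being reported in ascending order.
    """
    lo_eff = max(lo, spec.support_lower)
    ps = sorted(
        (stat_to_p(lo_eff, spec, rep_conv), stat_to_p(hi, spec, rep_conv))
    )
    return PredictionInterval(
        level=level,
        stat_lower=lo,
        stat_upper=hi,
        p_lower=ps[0],
        p_upper=ps[1],
        method=method,
    )


def _check_level(level: float) -> float:
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    return level


def classical_p_interval(
    p_obt: float,
    level: float = 0.95,
    conv: Sidedness = Sidedness.ONE_SIDED_UPPER,
) -> PredictionInterval:
    """Cumming's frequentist P-interval for a replication P-value.

    On the statistic scale the interval is ``z_obt +/- q*sqrt(2)`` with
    ``q`` the (1+level)/2 standard-normal quantile; its width is the same
    whatever the observed P-value.  ``conv`` states how ``p_obt`` maps to
    ``z_obt``; the endpoints are reported as one-sided upper replication
    P-values.
    """
    _check_level(level)
    z_obt = p_to_stat(p_obt, NORMAL_SPEC, conv)
    half = stats.norm.ppf((1.0 + level) / 2.0) * math.sqrt(2.0)
    return interval_from_stat_bounds(
        z_obt - half, z_obt + half, level, "p_interval"
    )


def conjugate_posterior(
    z_obt: float, prior: ConjugateNormalPrior
) -> ConjugatePosterior:
    """Posterior N(theta, s_sq) for the statistic's mean given ``z_obt``.

    ``theta`` is the shrinkage combination of ``z_obt`` and the prior mean
    with weights sigma0^2/(1+sigma0^2) and 1/(1+sigma0^2).
    """
    if not math.isfinite(z_obt):
        raise ValueError("z_obt must be finite")
    v = prior.sigma0_sq
    w = v / (1.0 + v)
    return ConjugatePosterior(
        theta=z_obt * w + prior.m0 / (1.0 + v), s_sq=w
    )


def conjugate_prediction_interval(
    z_obt: float | None = None,
    prior: ConjugateNormalPrior | None = None,
    level: float = 0.95,
    conv: Sidedness = Sidedness.ONE_SIDED_UPPER,
    p_obt: float | None = None,
) -> PredictionInterval:
    """Equal-tailed conjugate Bayes prediction interval for Z_rep.

    The predictive distribution is N(theta, 1 + s^2), giving endpoints
    ``theta +/- q*sqrt(1 + s^2)``.  As sigma0^2 -> infinity this recovers
    the classical P-interval; as sigma0^2 -> 0 it collapses to the pure
    null predictive around ``m0``.
    """
    if prior is None:
        raise ValueError("a ConjugateNormalPrior is required")
    _check_level(level)
    if z_obt is None:
        if p_obt is None:
            raise ValueError("supply z_obt or p_obt")
        z_obt = p_to_stat(p_obt, NORMAL_SPEC, conv)
    post = conjugate_posterior(z_obt, prior)
    half = stats.norm.ppf((1.0 + level) / 2.0) * math.sqrt(1.0 + post.s_sq)
    return interval_from_stat_bounds(
        post.theta - half, post.theta + half, level, "conjugate"
    )


def posterior_null_probability(
    z: float, effective_n: float, vartheta_sq: float
) -> float:
    """Posterior probability of the directional null given a Z value.

    With a zero-centered normal prior of variance ``vartheta_sq`` on the
    standardized mean, Pr(H0 | data) = 1 - Phi(z / sqrt(1 + 1/(N*vartheta^2))).
    As N grows this approaches the one-sided P-value 1 - Phi(z).
    """
    if effective_n <= 0 or vartheta_sq <= 0:
        raise ValueError("effective_n and vartheta_sq must be positive")
    shrink = math.sqrt(1.0 + 1.0 / (effective_n * vartheta_sq))
    return float(stats.norm.sf(z / shrink))
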