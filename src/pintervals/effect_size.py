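"""Standardized effect-size algebra for odds ratios.

For a 2x2 case/control design with outcome frequencies p1, p2 and case
proportion v, the standardized effect size of a log odds ratio is

    delta = log(OR) / sqrt(1/(v p1 (1-p1)) + 1/((1-v) p2 (1-p2)))

(with the pooled approximation delta ~= log(OR) * sqrt(ptilde(1-ptilde) v(1-v))).
Over all consistent designs, |delta| for a given OR cannot exceed the
closed-form bound

    delta_max(OR) = ln(OR) / (2 * sqrt(2 + (1 + OR)/sqrt(OR)))

whose global maximum over all odds ratios is the Laplace Limit constant
0.662743..., attained near OR = 121.35.  This boundedness is what makes
the flat prior implicit in classical P-intervals unrealistic: a normal
prior on delta must place essentially all its mass inside (-0.663, 0.663),
pinning its variance to small values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import optimize, stats

__all__ = [
    "ORContext",
    "EffectSizeTable",
    "delta_from_or",
    "delta_max",
    "global_delta_max",
    "prior_variance_from_or_tail",
    "estimate_prior_variance_from_counts",
    "popoviciu_bound",
    "context_from_pooled",
]

#: Default odds ratio attributed to non-associated loci (and its inverse
#: for the negative half of the log-OR distribution).
DEFAULT_NULL_OR = 1.005


@dataclass(frozen=True)
class ORContext:
    """Frequency context of a 2x2 design.

    p1, p2 are the outcome (e.g. risk-allele) frequencies in cases and
    controls, ``v`` the proportion of cases, ``pooled_p`` the pooled
    frequency v*p1 + (1-v)*p2.
    """

    p1: float
    p2: float
    v: float = 0.5
    pooled_p: float | None = None

    def __post_init__(self) -> None:
        for name, val in (("p1", self.p1), ("p2", self.p2), ("v", self.v)):
            if not 0.0 < val < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1)")
        if self.pooled_p is None:
            object.__setattr__(
                self, "pooled_p", self.v * self.p1 + (1.0 - self.v) * self.p2
            )
        lo, hi = min(self.p1, self.p2), max(self.p1, self.p2)
        if not lo - 1e-12 <= self.pooled_p <= hi + 1e-12:
            raise ValueError("pooled_p must lie between p1 and p2")

    @property
    def r(self) -> float:
        """Point-biserial correlation implied by the context."""
        pt = self.pooled_p
        return (
            (self.p1 - self.p2)
            * math.sqrt(self.v * (1.0 - self.v))
            / math.sqrt(pt * (1.0 - pt))
        )


#: Balanced design at 50% pooled frequency; used when no context is given.
SYMMETRIC_CONTEXT = ORContext(p1=0.5, p2=0.5, v=0.5)


def context_from_pooled(or_value: float, pooled_p: float, v: float) -> ORContext:
    """Solve the 2x2 frequencies consistent with an OR, pooled freq and v."""
    if or_value <= 0:
        raise ValueError("odds ratio must be positive")
    if or_value == 1.0:
        return ORContext(p1=pooled_p, p2=pooled_p, v=v)

    def pooled_gap(p2: float) -> float:
        odds2 = p2 / (1.0 - p2)
        p1 = or_value * odds2 / (1.0 + or_value * odds2)
        return v * p1 + (1.0 - v) * p2 - pooled_p

    eps = 1e-12
    p2 = optimize.brentq(pooled_gap, eps, 1.0 - eps, xtol=1e-14)
    odds2 = p2 / (1.0 - p2)
    p1 = or_value * odds2 / (1.0 + or_value * odds2)
    return ORContext(p1=p1, p2=p2, v=v)


@dataclass(frozen=True)
class EffectSizeTable:
    """Tabulated distribution of odds ratios over tested loci.

    ``rows`` lists (OR_i, L_i) pairs: L_i loci carry odds ratio OR_i out of
    ``total_tests`` tests in all.  Mass not covered by the rows belongs to
    non-associated loci at ``null_or`` (split evenly with its inverse for
    the negative half of the log-OR distribution).
    """

    rows: tuple[tuple[float, int], ...]
    total_tests: int
    null_or: float = DEFAULT_NULL_OR

    def __post_init__(self) -> None:
        rows = tuple((float(o), int(c)) for o, c in self.rows)
        object.__setattr__(self, "rows", rows)
        if self.total_tests <= 0:
            raise ValueError("total_tests must be positive")
        if self.null_or <= 0:
            raise ValueError("null_or must be positive")
        for or_value, count in rows:
            if or_value <= 0:
                raise ValueError("odds ratios must be positive")
            if count < 0:
                raise ValueError("locus counts must be nonnegative")
        if self.listed_count > self.total_tests:
            raise ValueError(
                "listed locus counts exceed the total number of tests"
            )

    @property
    def listed_count(self) -> int:
        return sum(c for _, c in self.rows)

    def weighted_or_values(self) -> list[tuple[float, float]]:
        """(OR, weight) pairs including the split null component."""
        m = float(self.total_tests)
        out = [(o, c / m) for o, c in self.rows if c > 0]
        residual = (self.total_tests - self.listed_count) / m
        if residual > 0:
            out.append((self.null_or, residual / 2.0))
            out.append((1.0 / self.null_or, residual / 2.0))
        return out


def delta_from_or(
    or_value: float,
    ctx: ORContext = SYMMETRIC_CONTEXT,
    pooled_approximation: bool = False,
) -> float:
    """Standardized effect size of a log odds ratio in a given context.

    The exact form divides log(OR) by the standard deviation of the log-OR
    estimate per subject; the pooled approximation replaces the per-group
    variances with the pooled frequency.
    """
    if or_value <= 0:
        raise ValueError("odds ratio must be positive")
    log_or = math.log(or_value)
    if pooled_approximation:
        pt = ctx.pooled_p
        return log_or * math.sqrt(pt * (1.0 - pt) * ctx.v * (1.0 - ctx.v))
    denom = math.sqrt(
        1.0 / (ctx.v * ctx.p1 * (1.0 - ctx.p1))
        + 1.0 / ((1.0 - ctx.v) * ctx.p2 * (1.0 - ctx.p2))
    )
    return log_or / denom


def delta_max(or_value: float) -> float:
    """Largest standardized effect size attainable for a given odds ratio.

    Closed-form maximum of :func:`delta_from_or` over all consistent
    frequency contexts; antisymmetric under OR -> 1/OR.
    """
    if or_value <= 0:
        raise ValueError("odds ratio must be positive")
    return math.log(or_value) / (
        2.0 * math.sqrt(2.0 + (1.0 + or_value) / math.sqrt(or_value))
    )


def global_delta_max() -> tuple[float, float]:
    """Maximize delta_max over all odds ratios.

    Returns (or_at_max, delta_at_max); the maximum equals the Laplace
    Limit constant ~0.662743 near OR ~ 121.35.
    """
    res = optimize.minimize_scalar(
        lambda log_or: -delta_max(math.exp(log_or)),
        bounds=(1e-6, math.log(1e6)),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return (math.exp(res.x), -res.fun)


def prior_variance_from_or_tail(or_value: float, beta: float) -> float:
    """Largest conjugate prior variance with Pr(OR >= or_value) = beta.

    Under a zero-mean normal prior on delta, the tail condition pins the
    prior standard deviation through the bound delta_max(or_value):
    s0^2 = (delta_max(OR) / Phi^{-1}(1 - beta))^2.
    """
    if not 0.0 < beta < 0.5:
        raise ValueError("beta must lie in (0, 0.5)")
    if or_value < 1.0:
        raise ValueError("or_value must be >= 1")
    if or_value == 1.0:
        return 0.0
    q = stats.norm.ppf(1.0 - beta)
    return (delta_max(or_value) / q) ** 2


def estimate_prior_variance_from_counts(
    table: EffectSizeTable,
    effective_n: float,
    ctx: ORContext = SYMMETRIC_CONTEXT,
    pooled_approximation: bool = True,
) -> float:
    """Weighted-variance estimate of s0^2 from a tabulated OR distribution.

    With weights w_i = L_i/M and m_w = sum w_i * gamma_i/sqrt(2N), the
    estimate is s0^2 = sum w_i * (gamma_i/sqrt(2N) - m_w)^2.  Under the
    two-group convention for the per-test noncentrality,
    gamma_i = sqrt(2N)*delta_i, the scaled terms gamma_i/sqrt(2N) are the
    standardized effects delta_i themselves, so the estimator is the
    weighted variance of the delta values and is free of N.  Residual mass
    goes to the null OR and its inverse, split evenly.
    """
    if effective_n <= 0:
        raise ValueError("effective_n must be positive")
    pairs = [
        (w, delta_from_or(o, ctx, pooled_approximation))
        for o, w in table.weighted_or_values()
    ]
    total = sum(w for w, _ in pairs)
    m_w = sum(w * g for w, g in pairs) / total
    return sum(w * (g - m_w) ** 2 for w, g in pairs) / total


def popoviciu_bound(lower: float, upper: float) -> float:
    """Popoviciu's variance bound (U - L)^2 / 4 for support [L, U]."""
    if lower > upper:
        raise ValueError("lower must not exceed upper")
    return (upper - lower) ** 2 / 4.0
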