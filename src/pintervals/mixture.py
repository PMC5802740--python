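"""Mixture Bayes prediction intervals over discretized effect-size priors.

Any prior on the standardized effect size delta can be expressed as a
finite grid of values with probabilities.  Each grid value maps to a
noncentrality gamma_i (sqrt(N)*delta_i for normal/t statistics,
N*delta_i^2 for chi-square/F), and the observed statistic updates the grid
probabilities through the noncentral density:

    Pr(delta_j | t_obt)  proportional to  Pr(delta_j) * f(t_obt | gamma_j)

The predictive CDF of a replication statistic is then the posterior-
weighted average of noncentral CDFs,

    F_p(x) = sum_j Pr(delta_j | t_obt) * F(x | gamma_j),

and equal-tailed prediction intervals are read off its quantiles.  Unlike
the conjugate construction this needs no conjugacy, so it extends to
chi-square and F statistics and to arbitrary tabulated priors such as
empirical odds-ratio distributions.

Weight arithmetic is done in log space: at genome-wide-significant
P-values the component densities are of order 1e-80 and plain
normalization would underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp, ndtr

from .conjugate import PredictionInterval, interval_from_stat_bounds
from .effect_size import (
    SYMMETRIC_CONTEXT,
    EffectSizeTable,
    ORContext,
    delta_from_or,
)
from .transforms import Family, NORMAL_SPEC, Sidedness, TestSpec, p_to_stat

__all__ = [
    "TabulatedEffectPrior",
    "MixturePosterior",
    "discretize_prior",
    "tabulated_prior_from_or_table",
    "posterior_weights",
    "predictive_cdf",
    "predictive_quantile",
    "mixture_prediction_interval",
]

_OMNIBUS = frozenset({Family.CHI_SQUARE, Family.F})
#: Noncentralities below this are treated as central to avoid numerical
#: trouble in scipy's noncentral chi-square/F at nc == 0.
_NC_EPS = 1e-12


@dataclass(frozen=True)
class TabulatedEffectPrior:
    """Discrete prior over standardized effect sizes.

    ``values`` are delta_i (``scale='delta'``) or delta_i^2
    (``scale='delta_squared'``, required nonnegative), strictly increasing;
    ``probs`` are their prior probabilities, summing to one.
    """

    values: np.ndarray
    probs: np.ndarray
    scale: str = "delta"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "probs", probs)
        if values.ndim != 1 or values.shape != probs.shape:
            raise ValueError("values and probs must be 1-d and equal length")
        if values.size == 0:
            raise ValueError("prior must have at least one component")
        if np.any(np.diff(values) <= 0):
            raise ValueError("values must be strictly increasing")
        if np.any(probs < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1 within 1e-12")
        if self.scale not in ("delta", "delta_squared"):
            raise ValueError("scale must be 'delta' or 'delta_squared'")
        if self.scale == "delta_squared" and np.any(values < 0):
            raise ValueError("delta_squared values must be nonnegative")

    @property
    def B(self) -> int:
        """Number of mixture components."""
        return int(self.values.size)

    def folded_to_delta_squared(self) -> "TabulatedEffectPrior":
        """Fold a delta-scale prior to delta^2 by pooling +/-delta pairs."""
        if self.scale == "delta_squared":
            return self
        sq = np.round(self.values**2, 15)
        uniq, inv = np.unique(sq, return_inverse=True)
        probs = np.zeros_like(uniq)
        np.add.at(probs, inv, self.probs)
        return TabulatedEffectPrior(uniq, probs, scale="delta_squared")


@dataclass(frozen=True)
class MixturePosterior:
    """Posterior probabilities over the prior grid given an observation."""

    values: np.ndarray
    gammas: np.ndarray
    post_probs: np.ndarray
    posterior_mean: float

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.post_probs)) - 1.0) > 1e-10:
            raise ValueError("posterior probabilities must sum to 1")


def discretize_prior(
    m0: float,
    s0_sq: float,
    effective_n: float = 1.0,
    step_fraction: float = 1.0 / 8.0,
    tail_quantile: float = 1e-6,
) -> TabulatedEffectPrior:
    """Discretize a conjugate normal prior into a finite mixture.

    The normal prior N(m0, sigma0^2) on the statistic scale
    (sigma0^2 = N*s0_sq) is truncated at its ``tail_quantile`` and
    ``1 - tail_quantile`` quantiles and cut into contiguous bins of width
    ``sigma0 * step_fraction``; only full-width bins are counted, with the
    last bin stretched to the upper truncation point.  Each component sits
    at its bin midpoint and carries the prior mass of its bin, renormalized
    over the truncated range.  At the defaults (width sigma0/8, tails at
    1e-6) this yields B = 76 components for every sigma0 > 0.

    A nonpositive ``s0_sq`` degenerates to a single point mass at ``m0``.
    """
    if effective_n <= 0:
        raise ValueError("effective_n must be positive")
    if step_fraction <= 0:
        raise ValueError("step_fraction must be positive")
    if not 0.0 < tail_quantile < 0.5:
        raise ValueError("tail_quantile must lie in (0, 0.5)")
    root_n = math.sqrt(effective_n)
    if s0_sq <= 0:
        return TabulatedEffectPrior(
            np.array([m0 / root_n]), np.array([1.0]), scale="delta"
        )
    sigma0 = math.sqrt(effective_n * s0_sq)
    lo = m0 + sigma0 * stats.norm.ppf(tail_quantile)
    hi = m0 + sigma0 * stats.norm.ppf(1.0 - tail_quantile)
    width = sigma0 * step_fraction
    n_bins = max(int(math.floor((hi - lo) / width)), 1)
    edges = lo + width * np.arange(n_bins + 1)
    edges[-1] = hi
    mids = 0.5 * (edges[:-1] + edges[1:])
    mass = np.diff(stats.norm.cdf(edges, loc=m0, scale=sigma0))
    mass /= mass.sum()
    return TabulatedEffectPrior(mids / root_n, mass, scale="delta")


def tabulated_prior_from_or_table(
    table: EffectSizeTable,
    effective_n: float,
    ctx: ORContext = SYMMETRIC_CONTEXT,
    scale: str = "delta",
) -> TabulatedEffectPrior:
    """Turn a tabulated odds-ratio distribution into an effect-size prior.

    Row weights are locus counts over the total number of tests; residual
    mass goes to the null OR and its inverse (split evenly).  Odds ratios
    map to delta through the pooled approximation at the given frequency
    context.  ``effective_n`` is accepted for interface symmetry with the
    conjugate path; deltas themselves do not depend on it.
    """
    if effective_n <= 0:
        raise ValueError("effective_n must be positive")
    pairs = table.weighted_or_values()
    deltas = np.array(
        [delta_from_or(o, ctx, pooled_approximation=True) for o, _ in pairs]
    )
    weights = np.array([w for _, w in pairs])
    order = np.argsort(deltas)
    deltas, weights = deltas[order], weights[order]
    uniq, inv = np.unique(np.round(deltas, 15), return_inverse=True)
    probs = np.zeros_like(uniq)
    np.add.at(probs, inv, weights)
    probs /= probs.sum()
    prior = TabulatedEffectPrior(uniq, probs, scale="delta")
    if scale == "delta_squared":
        return prior.folded_to_delta_squared()
    return prior


# ---------------------------------------------------------------------------
# noncentral density/CDF/quantile helpers (central fallback at gamma ~ 0)


def _component_gammas(
    prior: TabulatedEffectPrior, spec: TestSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(values, gammas, probs) with the prior folded if the family needs it."""
    if spec.family in _OMNIBUS:
        folded = prior.folded_to_delta_squared()
        return folded.values, spec.effective_n * folded.values, folded.probs
    if prior.scale == "delta_squared":
        raise ValueError(
            "delta_squared priors are only compatible with chi_square/f"
        )
    return (
        prior.values,
        math.sqrt(spec.effective_n) * prior.values,
        prior.probs,
    )


def _nc_logpdf(spec: TestSpec, x: float, gammas: np.ndarray) -> np.ndarray:
    fam = spec.family
    out = np.empty_like(gammas, dtype=float)
    central = np.abs(gammas) < _NC_EPS
    if fam is Family.NORMAL:
        return stats.norm.logpdf(x, loc=gammas)
    if fam is Family.STUDENT_T:
        out[central] = stats.t.logpdf(x, spec.df2)
        out[~central] = stats.nct.logpdf(x, spec.df2, gammas[~central])
        return out
    if fam is Family.CHI_SQUARE:
        out[central] = stats.chi2.logpdf(x, spec.df1)
        out[~central] = stats.ncx2.logpdf(x, spec.df1, gammas[~central])
        return out
    out[central] = stats.f.logpdf(x, spec.df1, spec.df2)
    out[~central] = stats.ncf.logpdf(x, spec.df1, spec.df2, gammas[~central])
    return out


def _nc_cdf(spec: TestSpec, x, gammas: np.ndarray) -> np.ndarray:
    """Component CDFs; broadcasts x against the component axis."""
    x = np.asarray(x, dtype=float)
    g = gammas.reshape((-1,) + (1,) * x.ndim)
    fam = spec.family
    if fam is Family.NORMAL:
        return ndtr(x[None, ...] - g)
    central = np.abs(gammas) < _NC_EPS
    out = np.empty((gammas.size,) + x.shape, dtype=float)
    if fam is Family.STUDENT_T:
        out[central] = stats.t.cdf(x, spec.df2)
        out[~central] = stats.nct.cdf(x[None, ...], spec.df2, g[~central])
    elif fam is Family.CHI_SQUARE:
        out[central] = stats.chi2.cdf(x, spec.df1)
        out[~central] = stats.ncx2.cdf(x[None, ...], spec.df1, g[~central])
    else:
        out[central] = stats.f.cdf(x, spec.df1, spec.df2)
        out[~central] = stats.ncf.cdf(
            x[None, ...], spec.df1, spec.df2, g[~central]
        )
    return out


def _nc_ppf(spec: TestSpec, q: float, gamma: float) -> float:
    fam = spec.family
    if fam is Family.NORMAL:
        return float(stats.norm.ppf(q, loc=gamma))
    if abs(gamma) < _NC_EPS:
        return float(spec.null_distribution().ppf(q))
    if fam is Family.STUDENT_T:
        return float(stats.nct.ppf(q, spec.df2, gamma))
    if fam is Family.CHI_SQUARE:
        return float(stats.ncx2.ppf(q, spec.df1, gamma))
    return float(stats.ncf.ppf(q, spec.df1, spec.df2, gamma))


# ---------------------------------------------------------------------------


def posterior_weights(
    prior: TabulatedEffectPrior,
    t_obt: float,
    spec: TestSpec = NORMAL_SPEC,
) -> MixturePosterior:
    """Update the prior grid with the observed statistic value.

    Posterior probabilities are proportional to prior probability times the
    noncentral density at ``t_obt``; normalization is carried out in log
    space so that observations deep in the tails (densities ~1e-80) do not
    underflow.
    """
    if t_obt < spec.support_lower:
        raise ValueError("t_obt outside the family's support")
    values, gammas, probs = _component_gammas(prior, spec)
    with np.errstate(divide="ignore"):
        log_prior = np.log(probs)
    log_w = log_prior + _nc_logpdf(spec, t_obt, gammas)
    norm = logsumexp(log_w)
    if not np.isfinite(norm):
        raise FloatingPointError(
            "all mixture components have vanishing density at "
            f"t_obt={t_obt}; the prior grid does not reach the observation"
        )
    post = np.exp(log_w - norm)
    post /= post.sum()
    return MixturePosterior(
        values=values,
        gammas=gammas,
        post_probs=post,
        posterior_mean=float(np.dot(post, values)),
    )


def predictive_cdf(
    post: MixturePosterior, x, spec: TestSpec = NORMAL_SPEC
):
    """CDF of the replication statistic: posterior-weighted noncentral CDFs."""
    x_arr = np.asarray(x, dtype=float)
    comp = _nc_cdf(spec, x_arr, post.gammas)
    w = post.post_probs.reshape((-1,) + (1,) * x_arr.ndim)
    out = np.sum(w * comp, axis=0)
    return float(out) if np.isscalar(x) or x_arr.ndim == 0 else out


def predictive_quantile(
    post: MixturePosterior,
    q: float,
    spec: TestSpec = NORMAL_SPEC,
    tol: float = 1e-10,
    max_doublings: int = 60,
) -> float:
    """Invert the predictive CDF at probability ``q``.

    The root is bracketed by the min and max of the component-wise
    q-quantiles (widened geometrically if needed) and solved with Brent's
    method to ``tol`` in CDF units.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    comp_q = [_nc_ppf(spec, q, g) for g in post.gammas]
    lo, hi = min(comp_q), max(comp_q)
    if hi - lo < 1e-12:
        lo, hi = lo - 1e-6, hi + 1e-6
    lo = max(lo, spec.support_lower)

    def f(x: float) -> float:
        return float(predictive_cdf(post, x, spec)) - q

    span = max(hi - lo, 1e-6)
    n_doublings = 0
    while f(lo) > 0.0:
        lo = max(lo - span, spec.support_lower)
        if lo == spec.support_lower and f(lo) > 0.0:
            return lo
        span *= 2.0
        n_doublings += 1
        if n_doublings > max_doublings:
            raise RuntimeError("failed to bracket the predictive quantile")
    while f(hi) < 0.0:
        hi += span
        span *= 2.0
        n_doublings += 1
        if n_doublings > max_doublings:
            raise RuntimeError("failed to bracket the predictive quantile")
    root = optimize.brentq(f, lo, hi, xtol=1e-14, maxiter=200)
    if abs(f(root)) > tol:
        raise RuntimeError(
            f"quantile inversion residual {abs(f(root)):.2e} exceeds {tol}"
        )
    return float(root)


def mixture_prediction_interval(
    p_obt: float | None = None,
    t_obt: float | None = None,
    prior: TabulatedEffectPrior | None = None,
    spec: TestSpec = NORMAL_SPEC,
    level: float = 0.95,
    conv: Sidedness = Sidedness.ONE_SIDED_UPPER,
) -> PredictionInterval:
    """Equal-tailed Mixture Bayes prediction interval.

    Endpoints are the alpha/2 and 1-alpha/2 quantiles of the predictive
    CDF, mapped to the P scale through the family's central upper tail.
    """
    if prior is None:
        raise ValueError("a TabulatedEffectPrior is required")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if t_obt is None:
        if p_obt is None:
            raise ValueError("supply p_obt or t_obt")
        t_obt = p_to_stat(p_obt, spec, conv)
    post = posterior_weights(prior, t_obt, spec)
    alpha = 1.0 - level
    lo = predictive_quantile(post, alpha / 2.0, spec)
    hi = predictive_quantile(post, 1.0 - alpha / 2.0, spec)
    return interval_from_stat_bounds(lo, hi, level, "mixture", spec=spec)


def normal_mixture_quantiles_batch(
    z_obs: np.ndarray,
    prior: TabulatedEffectPrior,
    qs: tuple[float, ...],
    x_tol: float = 1e-8,
) -> np.ndarray:
    """Vectorized predictive quantiles for many observed Z values at once.

    Normal family only; used by the coverage simulator, where a mixture
    interval must be inverted for every replicate.  Returns an array of
    shape ``(len(qs), len(z_obs))`` computed by vectorized bisection on the
    weighted-CDF equation.
    """
    z_obs = np.asarray(z_obs, dtype=float)
    gam = prior.values[:, None]  # normal family: gamma = delta at N = 1
    with np.errstate(divide="ignore"):
        log_prior = np.log(prior.probs)[:, None]
    log_w = log_prior + stats.norm.logpdf(z_obs[None, :], loc=gam)
    log_w -= logsumexp(log_w, axis=0, keepdims=True)
    w = np.exp(log_w)
    out = np.empty((len(qs), z_obs.size))
    for k, q in enumerate(qs):
        zq = stats.norm.ppf(q)
        lo = np.full(z_obs.size, prior.values.min() + zq - 1.0)
        hi = np.full(z_obs.size, prior.values.max() + zq + 1.0)
        while np.max(hi - lo) > x_tol:
            mid = 0.5 * (lo + hi)
            cdf = np.sum(w * ndtr(mid[None, :] - gam), axis=0)
            below = cdf < q
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
        out[k] = 0.5 * (lo + hi)
    return out
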