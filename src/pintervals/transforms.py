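"""Convention-explicit conversion between P-values and test-statistic values.

A P-value only determines a statistic value once two things are fixed: the
statistic family (normal Z, Student's t, chi-square, F) and the sidedness
convention under which the P-value was computed.  The functions here make
both explicit, so that observed P-values can be mapped losslessly onto the
statistic scale where prediction intervals are constructed, and interval
endpoints mapped back to the P scale.

Conventions
-----------
``one_sided_upper``
    P = Pr(X >= x) under the family's null distribution.  This is the
    default: replication studies target the direction of an effect, so
    one-sided P-values are the natural object of prediction.  For the
    nonnegative chi-square and F families this is the only (omnibus)
    convention.
``two_sided_positive_root``
    P is two-sided; the statistic is recovered as the positive root,
    x = Q(1 - P/2) >= 0.
``two_sided_negative_root``
    P is two-sided; the statistic is recovered as the negative root,
    x = Q(P/2) <= 0.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

from scipy import stats

__all__ = [
    "Family",
    "Sidedness",
    "TestSpec",
    "p_to_stat",
    "stat_to_p",
    "shift_log10_two_to_one_sided",
    "P_FLOOR",
]

#: P-values below this are clamped (with a warning) instead of mapping to
#: an infinite statistic.
P_FLOOR = 1e-300

LOG10_2 = math.log10(2.0)


class Family(str, enum.Enum):
    """Supported test-statistic families."""

    NORMAL = "normal"
    STUDENT_T = "student_t"
    CHI_SQUARE = "chi_square"
    F = "f"


class Sidedness(str, enum.Enum):
    """How an observed P-value relates to its statistic value."""

    ONE_SIDED_UPPER = "one_sided_upper"
    TWO_SIDED_POSITIVE_ROOT = "two_sided_positive_root"
    TWO_SIDED_NEGATIVE_ROOT = "two_sided_negative_root"


#: Families whose statistics are nonnegative and admit only the omnibus
#: (upper-tail) convention.
_OMNIBUS_ONLY = frozenset({Family.CHI_SQUARE, Family.F})


@dataclass(frozen=True)
class TestSpec:
    """Statistic family, degrees of freedom and effective sample size.

    The effective sample size ``N = 1/(1/n1 + 1/n2)`` (half the harmonic
    mean of the two group sizes) scales a standardized effect size delta
    into the noncentrality of the statistic's sampling distribution:
    gamma = sqrt(N)*delta for the normal and t families and
    gamma = N*delta**2 for chi-square and F.

    Parameters
    ----------
    family : Family
        Statistic family.
    df1, df2 : int, optional
        Degrees of freedom.  F requires both (numerator, denominator);
        chi-square requires ``df1``; Student's t requires ``df2`` (taken as
        ``n1 + n2 - 2`` when group sizes are given instead).
    n1, n2 : int, optional
        Per-group sample sizes; when given they determine ``effective_n``.
    effective_n : float, optional
        Supplied directly when group sizes are unavailable.  Defaults to 1,
        in which case standardized effects are already on the
        noncentrality scale.
    """

    __test__ = False  # not a test case despite the name

    family: Family = Family.NORMAL
    df1: int | None = None
    df2: int | None = None
    n1: int | None = None
    n2: int | None = None
    effective_n: float | None = None

    def __post_init__(self) -> None:
        fam = Family(self.family)
        object.__setattr__(self, "family", fam)
        if self.n1 is not None and self.n2 is not None:
            if self.n1 <= 0 or self.n2 <= 0:
                raise ValueError("group sizes must be positive")
            neff = 1.0 / (1.0 / self.n1 + 1.0 / self.n2)
            if self.effective_n is not None and not math.isclose(
                self.effective_n, neff, rel_tol=1e-9
            ):
                raise ValueError(
                    "effective_n inconsistent with n1, n2 "
                    f"({self.effective_n} vs {neff})"
                )
            object.__setattr__(self, "effective_n", neff)
        elif self.effective_n is None:
            object.__setattr__(self, "effective_n", 1.0)
        if self.effective_n <= 0:
            raise ValueError("effective_n must be positive")

        if fam is Family.F and (self.df1 is None or self.df2 is None):
            raise ValueError("family 'f' requires df1 and df2")
        if fam is Family.CHI_SQUARE and self.df1 is None:
            raise ValueError("family 'chi_square' requires df1")
        if fam is Family.STUDENT_T and self.df2 is None:
            if self.n1 is not None and self.n2 is not None:
                object.__setattr__(self, "df2", self.n1 + self.n2 - 2)
            else:
                raise ValueError("family 'student_t' requires df2 (or n1, n2)")
        for df in (self.df1, self.df2):
            if df is not None and df <= 0:
                raise ValueError("degrees of freedom must be positive")

    # -- distributions -------------------------------------------------

    def null_distribution(self):
        """Frozen scipy distribution of the statistic under the point null."""
        return self.noncentral_distribution(0.0)

    def noncentral_distribution(self, gamma: float):
        """Frozen sampling distribution at noncentrality ``gamma``.

        ``gamma`` is sqrt(N)*delta for normal/t and N*delta**2 for
        chi-square/F.
        """
        if self.family is Family.NORMAL:
            return stats.norm(loc=gamma)
        if self.family is Family.STUDENT_T:
            if gamma == 0.0:
                return stats.t(self.df2)
            return stats.nct(self.df2, gamma)
        if self.family is Family.CHI_SQUARE:
            if gamma == 0.0:
                return stats.chi2(self.df1)
            return stats.ncx2(self.df1, gamma)
        if gamma == 0.0:
            return stats.f(self.df1, self.df2)
        return stats.ncf(self.df1, self.df2, gamma)

    @property
    def support_lower(self) -> float:
        return 0.0 if self.family in _OMNIBUS_ONLY else -math.inf

    def gamma_from_delta(self, delta: float) -> float:
        """Noncentrality corresponding to a standardized effect size."""
        if self.family in _OMNIBUS_ONLY:
            return self.effective_n * delta**2
        return math.sqrt(self.effective_n) * delta


#: Convenience spec for a plain Z-statistic.
NORMAL_SPEC = TestSpec(Family.NORMAL)


def _check_convention(spec: TestSpec, conv: Sidedness) -> Sidedness:
    conv = Sidedness(conv)
    if spec.family in _OMNIBUS_ONLY and conv is not Sidedness.ONE_SIDED_UPPER:
        raise ValueError(
            f"family '{spec.family.value}' admits only the one_sided_upper "
            "(omnibus) convention"
        )
    return conv


def p_to_stat(
    p: float,
    spec: TestSpec = NORMAL_SPEC,
    conv: Sidedness = Sidedness.ONE_SIDED_UPPER,
) -> float:
    """Statistic value whose tail probability equals ``p`` under ``conv``.

    Inverse of :func:`stat_to_p`.  P-values below ``P_FLOOR`` are clamped
    with a warning rather than producing an infinite statistic.
    """
    conv = _check_convention(spec, conv)
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie in (0, 1), got {p}")
    if p < P_FLOOR:
        warnings.warn(
            f"P-value {p} below {P_FLOOR}; clamped", RuntimeWarning, stacklevel=2
        )
        p = P_FLOOR
    dist = spec.null_distribution()
    if conv is Sidedness.ONE_SIDED_UPPER:
        return float(dist.isf(p))
    if conv is Sidedness.TWO_SIDED_POSITIVE_ROOT:
        return float(dist.isf(p / 2.0))
    return float(dist.ppf(p / 2.0))


def stat_to_p(
    x: float,
    spec: TestSpec = NORMAL_SPEC,
    conv: Sidedness = Sidedness.ONE_SIDED_UPPER,
) -> float:
    """Tail probability of statistic value ``x`` under ``conv``."""
    conv = _check_convention(spec, conv)
    if x < spec.support_lower:
        raise ValueError(
            f"statistic {x} outside the support of family '{spec.family.value}'"
        )
    dist = spec.null_distribution()
    if conv is Sidedness.ONE_SIDED_UPPER:
        return float(dist.sf(x))
    if conv is Sidedness.TWO_SIDED_POSITIVE_ROOT:
        if x < 0:
            raise ValueError("two_sided_positive_root requires x >= 0")
        return float(2.0 * dist.sf(x))
    if x > 0:
        raise ValueError("two_sided_negative_root requires x <= 0")
    return float(2.0 * dist.cdf(x))


def shift_log10_two_to_one_sided(
    bounds: tuple[float, float],
) -> tuple[float, float]:
    """Convert -log10 interval bounds from two-sided to one-sided P-values.

    Halving a two-sided P-value subtracts log10(2) on the -log10 scale;
    the ordering of the bounds is preserved.
    """
    lo, hi = bounds
    if not (math.isfinite(lo) and math.isfinite(hi)):
        raise ValueError("bounds must be finite")
    if lo < 0 or hi < 0:
        raise ValueError("-log10 bounds must be nonnegative")
    return (lo - LOG10_2, hi - LOG10_2)
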