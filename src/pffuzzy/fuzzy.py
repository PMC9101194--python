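"""Half-triangular fuzzy numbers built from upper confidence limits.

For a point estimate ``PF*`` from ``n`` normal measurements, a conservative
one-sided 100(1-alpha)% upper confidence limit for the true index is

    U_PF = PF* * sqrt(chi2_{1-alpha/2; n-1} / n) + z_{1-alpha/2} / sqrt(n)

combining a chi-square bound on the variance with a normal bound on the
mean via Boole's inequality (actual coverage is at least 1-alpha).  Seen
as a function of the confidence level, these limits nest, and the family
of limits defines a half-triangular fuzzy number with

    apex  PF_M = PF* * sqrt(chi2_{0.5; n-1} / n)       (membership 1)
    right end PF_R = U_PF at the working alpha          (membership 0)

The membership eta(x) of a candidate index value x in (PF_M, PF_R) is the
level ``a`` at which x is exactly the upper confidence limit — the inverse
of a strictly decreasing map, found by bracketed root finding.

The fuzzy test of the requirement ``PF >= k`` compares the fraction of the
fuzzy number's base lying to the right of k,

    d_R / d_T = (PF_R - k) / (PF_R - PF_M),

against thresholds phi1 < phi2: at most phi1 means the requirement is
clearly missed (improve); at least phi2 means it is clearly met
(maintain); in between, no decision (re-evaluate).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from scipy.optimize import brentq
from scipy.stats import chi2, norm

from .errors import DegenerateFuzzyNumberError, NumericalError, ParameterError
from .indices import FitnessSpec

__all__ = [
    "FuzzyIndex",
    "FuzzyDecision",
    "Outcome",
    "upper_confidence_limit",
    "build_fuzzy_index",
    "membership",
    "fuzzy_test",
]

# Alpha-cuts below this level reuse the interval at the level itself, so the
# membership function is flat there; the working alpha plays this role.
_ALPHA_TOL = 1e-9


def _check_params(n: int, alpha: float) -> None:
    if not isinstance(n, (int,)) or isinstance(n, bool) or n < 2:
        raise ParameterError(f"sample size n must be an integer >= 2, got {n!r}")
    if not (isinstance(alpha, (int, float)) and 0.0 < alpha < 1.0):
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha!r}")


def _limit_at_level(pf_star: float, n: int, a: float) -> float:
    """Upper confidence limit as a function of the level a (Eq. family).

    Strictly decreasing in a for pf_star >= 0: at a -> 0 both quantiles
    blow up, at a = 1 the chi-square quantile is the median and the
    normal term vanishes, recovering the apex PF_M.
    """
    return pf_star * math.sqrt(chi2.ppf(1.0 - a / 2.0, n - 1) / n) + norm.ppf(
        1.0 - a / 2.0
    ) / math.sqrt(n)


def upper_confidence_limit(pf_star: float, n: int, alpha: float = 0.05) -> float:
    """One-sided 100(1-alpha)% upper confidence limit for the index.

    ``PF* * sqrt(chi2_{1-alpha/2; n-1}/n) + z_{1-alpha/2}/sqrt(n)``; the
    Boole-inequality construction makes the bound conservative (coverage
    >= 1-alpha).
    """
    _check_params(n, alpha)
    if not math.isfinite(pf_star):
        raise ParameterError(f"pf_star must be finite, got {pf_star!r}")
    return _limit_at_level(float(pf_star), n, float(alpha))


@dataclass(frozen=True)
class FuzzyIndex:
    """Half-triangular fuzzy number for one item's fitness index."""

    item_id: str
    pf_star: float
    n: int
    alpha: float
    pf_m: float
    pf_r: float

    @property
    def ucl(self) -> float:
        """Observed upper confidence limit; coincides with pf_r."""
        return self.pf_r


class Outcome(enum.Enum):
    IMPROVE = "improve"
    RE_EVALUATE = "re_evaluate"
    MAINTAIN = "maintain"


@dataclass(frozen=True)
class FuzzyDecision:
    """d_R/d_T ratio and tri-state outcome for one item."""

    item_id: str
    k: float
    d_r: float
    d_t: float
    ratio: float
    outcome: Outcome


def build_fuzzy_index(
    pf_star: float, n: int, alpha: float = 0.05, item_id: str = ""
) -> FuzzyIndex:
    """Construct the half-triangular fuzzy number for an index estimate.

    The apex uses the chi-square median quantile (level 0.5), so for
    pf_star > 0 the apex sits below pf_star; the right endpoint is the
    upper confidence limit at the working alpha.
    """
    _check_params(n, alpha)
    pf_m = float(pf_star) * math.sqrt(chi2.ppf(0.5, n - 1) / n)
    pf_r = upper_confidence_limit(pf_star, n, alpha)
    return FuzzyIndex(
        item_id=item_id,
        pf_star=float(pf_star),
        n=n,
        alpha=float(alpha),
        pf_m=pf_m,
        pf_r=pf_r,
    )


def membership(fz: FuzzyIndex, x: float) -> float:
    """Membership eta(x) of a candidate index value in the fuzzy number.

    Piecewise: 0 for x < pf_m, 1 at x = pf_m, the level ``a`` solving
    ``x = PF* sqrt(chi2_{1-a/2;n-1}/n) + z_{1-a/2}/sqrt(n)`` on
    (pf_m, pf_r), and 0 for x >= pf_r.  The drop from roughly alpha to 0
    at pf_r is a deliberate quirk of the construction: alpha-cuts below
    the working level reuse that level's interval, so no membership
    value below it ever arises.

    Raises
    ------
    NumericalError
        If the bracketed root finder fails (with diagnostics).
    """
    if not math.isfinite(x):
        raise ParameterError(f"x must be finite, got {x!r}")
    if x < fz.pf_m or x >= fz.pf_r:
        return 0.0 if x != fz.pf_m else 1.0
    if x == fz.pf_m:
        return 1.0

    def f(a: float) -> float:
        return _limit_at_level(fz.pf_star, fz.n, a) - x

    lo, hi = fz.alpha, 1.0
    flo, fhi = f(lo), f(hi)
    # f(lo) = pf_r - x > 0 and f(hi) = pf_m - x < 0 for x in (pf_m, pf_r);
    # guard anyway so a pathological (negative-pf_star) case fails loudly.
    if flo <= 0.0 or fhi >= 0.0:
        raise NumericalError(
            f"membership bracket failed for item {fz.item_id!r}: "
            f"x={x}, f({lo})={flo}, f({hi})={fhi}"
        )
    try:
        a = brentq(f, lo, hi, xtol=_ALPHA_TOL)
    except RuntimeError as exc:  # pragma: no cover - brentq rarely fails
        raise NumericalError(
            f"membership root finding did not converge for item "
            f"{fz.item_id!r} at x={x}: {exc}"
        ) from exc
    return float(a)


def fuzzy_test(fz: FuzzyIndex, spec: FitnessSpec) -> FuzzyDecision:
    """Tri-state fuzzy test of the requirement PF >= k.

    ``ratio = (pf_r - k) / (pf_r - pf_m)`` is left unclamped: it is
    negative when even the upper confidence limit falls short of k, and
    exceeds 1 when k lies left of the apex.

    Raises
    ------
    DegenerateFuzzyNumberError
        If the base d_T = pf_r - pf_m is not positive.
    """
    d_t = fz.pf_r - fz.pf_m
    if d_t <= 0.0:
        raise DegenerateFuzzyNumberError(
            f"item {fz.item_id!r}: fuzzy number base d_T = {d_t} <= 0"
        )
    d_r = fz.pf_r - spec.k
    ratio = d_r / d_t
    if ratio <= spec.phi1:
        outcome = Outcome.IMPROVE
    elif ratio < spec.phi2:
        outcome = Outcome.RE_EVALUATE
    else:
        outcome = Outcome.MAINTAIN
    return FuzzyDecision(
        item_id=fz.item_id,
        k=spec.k,
        d_r=float(d_r),
        d_t=float(d_t),
        ratio=float(ratio),
        outcome=outcome,
    )
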