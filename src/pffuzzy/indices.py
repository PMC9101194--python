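"""Physical-fitness indices from small repeated-measurement samples.

Each fitness item is a one-sided, capability-style quality characteristic:
the index ``PF`` measures how many population standard deviations the mean
sits on the good side of a specification limit,

    smaller-the-better (e.g. a run time with upper limit ``U``):
        PF = (U - mu) / sigma
    larger-the-better (e.g. sit-up counts with lower limit ``L``):
        PF = (mu - L) / sigma

under the assumption that repeated measurements are i.i.d. normal.  A
larger index means better compliance; the population proportion of
attempts meeting the limit is the compliance ratio ``Phi(PF)``.

This module owns the sample-level plumbing: specifications, sample
statistics, the plug-in point estimate ``PF*`` and the compliance ratio.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .errors import DegenerateSampleError, InvalidSampleError, ParameterError

__all__ = [
    "Orientation",
    "FitnessSpec",
    "MeasurementSample",
    "IndexEstimate",
    "summarize_sample",
    "estimate_index",
    "compliance_ratio",
]


class Orientation(enum.Enum):
    """Side of the specification limit a good measurement falls on."""

    SMALLER_BETTER = "smaller_better"
    LARGER_BETTER = "larger_better"

    @classmethod
    def parse(cls, value: "Orientation | str") -> "Orientation":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ParameterError(
                f"unknown orientation {value!r}; expected "
                f"'smaller_better' or 'larger_better'"
            ) from None


@dataclass(frozen=True)
class FitnessSpec:
    """Specification and test configuration for one fitness item.

    Parameters
    ----------
    item_id : str
        Short label, the join key against measurement rows.
    name : str
        Free-text description (e.g. "Cardiorespiratory endurance").
    orientation : Orientation or str
        Whether smaller or larger measurements are better.  Determines
        whether `limit` is an upper bound U or a lower bound L.
    limit : float
        The specification limit, in measurement units.
    k : float
        Required index level; the null hypothesis under test is
        ``PF >= k``.
    alpha : float
        Significance level of the one-sided upper confidence limit,
        default 0.05.
    phi1, phi2 : float
        Decision thresholds partitioning the d_R/d_T ratio into
        improve / re-evaluate / maintain; ``0 < phi1 < phi2 < 1``.
    """

    item_id: str
    name: str
    orientation: Orientation
    limit: float
    k: float
    alpha: float = 0.05
    phi1: float = 0.4
    phi2: float = 0.8

    def __post_init__(self) -> None:
        object.__setattr__(self, "orientation", Orientation.parse(self.orientation))
        for label in ("limit", "k", "alpha", "phi1", "phi2"):
            v = getattr(self, label)
            if not math.isfinite(float(v)):
                raise ParameterError(f"{label} must be finite, got {v!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.phi1 < self.phi2 < 1.0:
            raise ParameterError(
                f"thresholds must satisfy 0 < phi1 < phi2 < 1, "
                f"got phi1={self.phi1}, phi2={self.phi2}"
            )


@dataclass(frozen=True)
class MeasurementSample:
    """Raw repeated measurements for one item plus derived statistics.

    `mean` and `sd` are deterministic functions of `values`; `sd` uses
    the n-1 denominator by default (see :func:`summarize_sample`).
    """

    item_id: str
    values: tuple[float, ...]
    mean: float
    sd: float
    sd_denominator: str = "n_minus_1"

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class IndexEstimate:
    """Point estimate PF* of one item's fitness index."""

    item_id: str
    pf_star: float
    n: int


_DDOF = {"n_minus_1": 1, "n": 0}


def summarize_sample(
    values: Sequence[float] | Iterable[float],
    item_id: str = "",
    sd_denominator: str = "n_minus_1",
) -> MeasurementSample:
    """Compute the sample mean and standard deviation of one item.

    The standard deviation uses the n-1 denominator by default; pass
    ``sd_denominator="n"`` for the maximum-likelihood 1/n variant.

    Raises
    ------
    InvalidSampleError
        If fewer than two values are given or any value is non-finite.
    """
    if sd_denominator not in _DDOF:
        raise ParameterError(
            f"sd_denominator must be 'n' or 'n_minus_1', got {sd_denominator!r}"
        )
    arr = np.asarray(list(values), dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise InvalidSampleError(
            f"item {item_id!r}: need at least 2 measurements, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise InvalidSampleError(
            f"item {item_id!r}: non-finite measurement at position {bad}"
        )
    return MeasurementSample(
        item_id=item_id,
        values=tuple(float(v) for v in arr),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=_DDOF[sd_denominator])),
        sd_denominator=sd_denominator,
    )


def estimate_index(sample: MeasurementSample, spec: FitnessSpec) -> IndexEstimate:
    """Plug-in index estimate PF* = (U - x̄)/s or (x̄ - L)/s.

    The estimate may be negative when the sample mean falls on the wrong
    side of the limit; no clipping is applied.

    Raises
    ------
    DegenerateSampleError
        If the sample standard deviation is zero.
    """
    if sample.sd <= 0.0:
        raise DegenerateSampleError(
            f"item {sample.item_id!r}: zero standard deviation, index undefined"
        )
    if spec.orientation is Orientation.SMALLER_BETTER:
        pf = (spec.limit - sample.mean) / sample.sd
    else:
        pf = (sample.mean - spec.limit) / sample.sd
    return IndexEstimate(item_id=sample.item_id, pf_star=float(pf), n=sample.n)


def compliance_ratio(pf: float) -> float:
    """Population proportion of attempts meeting the limit, Phi(PF)."""
    return float(norm.cdf(pf))
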