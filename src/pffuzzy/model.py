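"""Model / Results interface for the fuzzy fitness evaluation.

:class:`PhysicalFitnessModel` is built from per-item measurements (or
directly from index estimates) together with per-item specifications;
``fit()`` chains sample summary -> index estimate -> fuzzy number ->
fuzzy test for every item and returns an :class:`EvaluationResults`
carrying the two report tables:

* a statistics table (item, limit, mean, sd, PF*), and
* a fuzzy evaluation table (PF_M, PF_R, d_R, d_T, d_R/d_T, outcome).

Everything is deterministic; rendering is the only place numbers are
rounded (2 decimals for PF*, 3 for fuzzy quantities).
"""

from __future__ import annotations

import datetime as _dt
import io as _io
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, PffuzzyError
from .fuzzy import FuzzyDecision, FuzzyIndex, build_fuzzy_index, fuzzy_test
from .indices import (
    FitnessSpec,
    IndexEstimate,
    MeasurementSample,
    estimate_index,
    summarize_sample,
)

__all__ = [
    "PhysicalFitnessModel",
    "EvaluationResults",
    "ItemResult",
    "evaluate",
    "render_report",
]

_STATS_COLUMNS = ["item_id", "name", "limit", "mean", "sd", "pf_star"]
_FUZZY_COLUMNS = ["item_id", "pf_m", "pf_r", "d_r", "d_t", "ratio", "outcome"]


@dataclass(frozen=True)
class ItemResult:
    """Everything computed for one fitness item."""

    spec: FitnessSpec
    sample: MeasurementSample | None
    estimate: IndexEstimate
    fuzzy: FuzzyIndex
    decision: FuzzyDecision


class EvaluationResults:
    """Fitted results: per-item estimates, fuzzy numbers and decisions.

    Not constructed directly; returned by
    :meth:`PhysicalFitnessModel.fit` or :func:`evaluate`.
    """

    def __init__(self, items: Sequence[ItemResult], metadata: dict):
        self.items: tuple[ItemResult, ...] = tuple(items)
        self.metadata = dict(metadata)

    # -- tabular views ------------------------------------------------

    @property
    def stats_table(self) -> pd.DataFrame:
        rows = []
        for it in self.items:
            rows.append(
                {
                    "item_id": it.spec.item_id,
                    "name": it.spec.name,
                    "limit": it.spec.limit,
                    "mean": it.sample.mean if it.sample is not None else np.nan,
                    "sd": it.sample.sd if it.sample is not None else np.nan,
                    "pf_star": it.estimate.pf_star,
                }
            )
        return pd.DataFrame(rows, columns=_STATS_COLUMNS)

    @property
    def fuzzy_table(self) -> pd.DataFrame:
        rows = []
        for it in self.items:
            rows.append(
                {
                    "item_id": it.spec.item_id,
                    "pf_m": it.fuzzy.pf_m,
                    "pf_r": it.fuzzy.pf_r,
                    "d_r": it.decision.d_r,
                    "d_t": it.decision.d_t,
                    "ratio": it.decision.ratio,
                    "outcome": it.decision.outcome.value,
                }
            )
        return pd.DataFrame(rows, columns=_FUZZY_COLUMNS)

    @property
    def outcomes(self) -> dict[str, str]:
        return {it.spec.item_id: it.decision.outcome.value for it in self.items}

    # -- rendering ----------------------------------------------------

    def summary(self) -> str:
        """Two plain-text tables in the report layout."""
        return render_report(self, "markdown")

    def render(self, format: str = "csv", timestamp: bool = False) -> str:
        return render_report(self, format, timestamp=timestamp)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<EvaluationResults: {len(self.items)} items, "
            f"outcomes={self.outcomes}>"
        )


class PhysicalFitnessModel:
    """Fuzzy evaluation model for a battery of fitness items.

    Parameters
    ----------
    samples : mapping item_id -> MeasurementSample, optional
        Raw repeated measurements per item.  Omit when constructing
        from pre-computed estimates.
    specs : mapping item_id -> FitnessSpec
        Specification and test configuration per item; every measured
        item must have one.
    estimates : mapping item_id -> IndexEstimate, optional
        Pre-computed point estimates; used for items without samples
        (e.g. when only published summary statistics are available).

    Examples
    --------
    >>> from pffuzzy import PhysicalFitnessModel, FitnessSpec
    >>> spec = FitnessSpec("run", "1600 m run", "smaller_better",
    ...                    limit=598, k=6)
    >>> model = PhysicalFitnessModel.from_measurements(
    ...     {"run": [589, 593, 590, 591, 589, 590, 589, 589, 592, 594]},
    ...     {"run": spec})
    >>> results = model.fit()
    >>> results.outcomes
    {'run': 'improve'}
    """

    def __init__(
        self,
        samples: Mapping[str, MeasurementSample] | None,
        specs: Mapping[str, FitnessSpec],
        estimates: Mapping[str, IndexEstimate] | None = None,
    ):
        self.samples = dict(samples or {})
        self.specs = dict(specs)
        self.estimates = dict(estimates or {})
        measured = set(self.samples) | set(self.estimates)
        if not measured:
            raise ParameterError("no measurements or estimates given")
        missing = sorted(measured - set(self.specs))
        if missing:
            raise ParameterError(
                f"no specification for measured item(s): {', '.join(missing)}"
            )

    # -- constructors -------------------------------------------------

    @classmethod
    def from_measurements(
        cls,
        values: Mapping[str, Sequence[float]],
        specs: Mapping[str, FitnessSpec],
        sd_denominator: str = "n_minus_1",
    ) -> "PhysicalFitnessModel":
        samples = {
            item: summarize_sample(v, item, sd_denominator=sd_denominator)
            for item, v in values.items()
        }
        return cls(samples, specs)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        specs: Mapping[str, FitnessSpec],
        sd_denominator: str = "n_minus_1",
    ) -> "PhysicalFitnessModel":
        """Build from a long-format frame with columns item_id, value."""
        for col in ("item_id", "value"):
            if col not in data.columns:
                raise ParameterError(f"data frame lacks required column {col!r}")
        grouped = {
            str(item): list(sub["value"].astype(float))
            for item, sub in data.groupby("item_id", sort=False)
        }
        return cls.from_measurements(grouped, specs, sd_denominator=sd_denominator)

    @classmethod
    def from_estimates(
        cls,
        pf_stars: Mapping[str, float],
        n: int,
        specs: Mapping[str, FitnessSpec],
    ) -> "PhysicalFitnessModel":
        """Build directly from point estimates (no raw data), all of
        common sample size n — e.g. published summary tables."""
        estimates = {
            item: IndexEstimate(item_id=item, pf_star=float(pf), n=n)
            for item, pf in pf_stars.items()
        }
        return cls(None, specs, estimates)

    # -- fitting ------------------------------------------------------

    def fit(self) -> EvaluationResults:
        """Run the full pipeline for every item."""
        items: list[ItemResult] = []
        order = [i for i in self.specs if i in self.samples or i in self.estimates]
        for item_id in order:
            spec = self.specs[item_id]
            sample = self.samples.get(item_id)
            try:
                if sample is not None:
                    est = estimate_index(sample, spec)
                else:
                    est = self.estimates[item_id]
                fz = build_fuzzy_index(
                    est.pf_star, est.n, spec.alpha, item_id=item_id
                )
                dec = fuzzy_test(fz, spec)
            except PffuzzyError as exc:
                raise type(exc)(f"item {item_id!r}: {exc}") from exc
            items.append(ItemResult(spec, sample, est, fz, dec))
        sd_modes = {
            s.sd_denominator for s in self.samples.values()
        } or {"n_minus_1"}
        metadata = {
            "sd_denominator": sorted(sd_modes)[0] if len(sd_modes) == 1 else "mixed",
            "alpha": {i: self.specs[i].alpha for i in order},
            "k": {i: self.specs[i].k for i in order},
            "phi1": {i: self.specs[i].phi1 for i in order},
            "phi2": {i: self.specs[i].phi2 for i in order},
        }
        return EvaluationResults(items, metadata)


def evaluate(
    measurements: Mapping[str, MeasurementSample],
    specs: Mapping[str, FitnessSpec],
) -> EvaluationResults:
    """One-shot pipeline: samples + specs -> fitted evaluation report."""
    return PhysicalFitnessModel(measurements, specs).fit()


# -- rendering ---------------------------------------------------------

_FUZZY_DECIMALS = 3
_PF_DECIMALS = 2


def _rounded_tables(res: EvaluationResults) -> tuple[pd.DataFrame, pd.DataFrame]:
    stats = res.stats_table.copy()
    stats["mean"] = stats["mean"].round(_FUZZY_DECIMALS)
    stats["sd"] = stats["sd"].round(_FUZZY_DECIMALS)
    stats["pf_star"] = stats["pf_star"].round(_PF_DECIMALS)
    fuzzy = res.fuzzy_table.copy()
    for col in ("pf_m", "pf_r", "d_r", "d_t", "ratio"):
        fuzzy[col] = fuzzy[col].round(_FUZZY_DECIMALS)
    return stats, fuzzy


def _markdown_table(df: pd.DataFrame) -> str:
    cells = df.astype(object).where(df.notna(), "")
    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "|".join(" --- " for _ in df.columns) + "|"
    body = [
        "| " + " | ".join(str(v) for v in row) + " |"
        for row in cells.itertuples(index=False)
    ]
    return "\n".join([header, sep, *body])


def render_report(
    report: EvaluationResults, format: str = "csv", timestamp: bool = False
) -> str:
    """Serialize the evaluation report.

    ``csv`` emits one wide table (both layouts merged, one row per
    item); ``json`` a structured object with metadata; ``markdown`` the
    two tables separately, mirroring the statistics / fuzzy-evaluation
    split.
    """
    stats, fuzzy = _rounded_tables(report)
    meta = dict(report.metadata)
    if timestamp:
        meta["timestamp"] = _dt.datetime.now(_dt.timezone.utc).isoformat()
    if format == "csv":
        wide = stats.merge(fuzzy, on="item_id")
        buf = _io.StringIO()
        wide.to_csv(buf, index=False)
        return buf.getvalue()
    if format == "json":
        payload = {
            "metadata": meta,
            "statistics": stats.to_dict(orient="records"),
            "fuzzy_evaluation": fuzzy.to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2, default=float) + "\n"
    if format == "markdown":
        parts = [
            "## Testing statistics and index estimates",
            "",
            _markdown_table(stats),
            "",
            "## Fuzzy evaluation table",
            "",
            _markdown_table(fuzzy),
            "",
        ]
        if timestamp:
            parts.append(f"_generated: {meta['timestamp']}_")
        return "\n".join(parts)
    raise ParameterError(f"unknown report format {format!r}")
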