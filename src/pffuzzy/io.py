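"""Reading measurements, spec configs and scenario files.

Formats are deliberately plain: long-format CSV for measurements
(columns ``item_id,value``; an optional ``date`` column is ignored),
YAML or JSON for specifications and simulation scenarios.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .errors import ParseError
from .indices import FitnessSpec, MeasurementSample, summarize_sample
from .simulation import SimulationScenario

__all__ = ["read_measurements", "read_specs", "read_scenarios"]

# Per-item keys that fall back to file-level defaults when absent.
_DEFAULTABLE = ("k", "alpha", "phi1", "phi2")


def read_measurements(
    path: str | Path, sd_denominator: str = "n_minus_1"
) -> dict[str, MeasurementSample]:
    """Read a long-format measurements CSV into per-item samples.

    One :class:`MeasurementSample` per distinct ``item_id``, preserving
    row order.  Malformed files raise :class:`ParseError` naming the
    offending line (1-based, counting the header).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except FileNotFoundError:
        raise ParseError(f"{path}: file not found") from None
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = {"item_id", "value"} - set(frame.columns)
    if missing:
        raise ParseError(
            f"{path}: missing required column(s): {', '.join(sorted(missing))}"
        )
    numeric = pd.to_numeric(frame["value"], errors="coerce")
    bad = numeric.isna() & frame["value"].notna() | frame["value"].isna()
    if bad.any():
        row = int(bad.idxmax())
        raise ParseError(
            f"{path}: non-numeric value {frame['value'].iloc[row]!r} "
            f"on line {row + 2}"
        )
    frame = frame.assign(value=numeric)
    out: dict[str, MeasurementSample] = {}
    for item, sub in frame.groupby("item_id", sort=False):
        out[str(item)] = summarize_sample(
            sub["value"].tolist(), str(item), sd_denominator=sd_denominator
        )
    return out


def _load_structured(path: Path):
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix.lower() == ".json":
            return json.loads(text)
        return yaml.safe_load(text)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse: {exc}") from exc


def _build_spec(item_id: str, entry: Mapping, defaults: Mapping) -> FitnessSpec:
    merged = {k: defaults[k] for k in _DEFAULTABLE if k in defaults}
    merged.update(entry)
    try:
        return FitnessSpec(
            item_id=item_id,
            name=str(merged.get("name", item_id)),
            orientation=merged["orientation"],
            limit=float(merged["limit"]),
            k=float(merged["k"]),
            alpha=float(merged.get("alpha", 0.05)),
            phi1=float(merged.get("phi1", 0.4)),
            phi2=float(merged.get("phi2", 0.8)),
        )
    except KeyError as exc:
        raise ParseError(
            f"spec for item {item_id!r}: missing required key {exc}"
        ) from None


def read_specs(path: str | Path) -> dict[str, FitnessSpec]:
    """Read a YAML/JSON spec config into per-item specifications.

    Layout: an ``items`` mapping item_id -> {name, orientation, limit,
    k?, alpha?, phi1?, phi2?}; keys absent per item fall back to the
    file-level ``defaults`` mapping.  A bare mapping without ``items``
    is treated as the items mapping itself.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    doc = _load_structured(path)
    if not isinstance(doc, Mapping):
        raise ParseError(f"{path}: expected a mapping at top level")
    items = doc.get("items", doc)
    defaults = doc.get("defaults", {})
    if not isinstance(items, Mapping) or not items:
        raise ParseError(f"{path}: no items defined")
    return {
        str(item): _build_spec(str(item), entry, defaults)
        for item, entry in items.items()
        if item not in ("defaults",)
    }


def read_scenarios(path: str | Path) -> list[SimulationScenario]:
    """Read a YAML/JSON list of simulation scenarios.

    Each entry carries ``true_mu``, ``true_sigma``, an inline ``spec``
    mapping, and optional ``n_per_sample`` / ``n_replicates`` / ``seed``.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    doc = _load_structured(path)
    if isinstance(doc, Mapping):
        doc = doc.get("scenarios", doc)
    if not isinstance(doc, list):
        raise ParseError(f"{path}: expected a list of scenarios")
    out = []
    for i, entry in enumerate(doc):
        try:
            spec_entry = dict(entry["spec"])
            item_id = str(spec_entry.pop("item_id", f"scenario-{i}"))
            spec = _build_spec(item_id, spec_entry, {})
            out.append(
                SimulationScenario(
                    true_mu=float(entry["true_mu"]),
                    true_sigma=float(entry["true_sigma"]),
                    spec=spec,
                    n_per_sample=int(entry.get("n_per_sample", 10)),
                    n_replicates=int(entry.get("n_replicates", 10_000)),
                    seed=int(entry.get("seed", 0)),
                )
            )
        except KeyError as exc:
            raise ParseError(
                f"{path}: scenario {i}: missing required key {exc}"
            ) from None
    return out
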