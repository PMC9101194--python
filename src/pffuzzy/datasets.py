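"""The packaged worked example: four fitness items, ten tests each.

An 18-year-old male student measured each of four fitness items on ten
days: 1600 m run/walk time (upper limit 598 s), sit-ups per minute
(lower limit 33), standing long jump (lower limit 185 cm) and seated
forward flexion (lower limit 18 cm), evaluated against required index
level k = 6 at alpha = 0.05.

Both the raw measurement lists and the published summary statistics are
shipped, as separate accessors, because they disagree for two items:
the jump sample's mean is 190.3 but the published table says 192, and
the flexion sample's sd is 0.137 against a published 0.099.  Analyses
that must reproduce the published fuzzy-evaluation table should start
from :func:`example_printed_statistics`; analyses of the raw data use
:func:`example_measurements`.  Neither is "corrected" to match the
other.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .indices import FitnessSpec
from .io import read_measurements, read_specs

__all__ = [
    "example_measurements",
    "example_specs",
    "example_printed_statistics",
    "write_example_files",
]

ITEM_IDS = ("cardio", "situps", "jump", "flex")


def _data_path(name: str) -> Path:
    return Path(resources.files("pffuzzy").joinpath("data", name))


def example_measurements(sd_denominator: str = "n_minus_1"):
    """Raw repeated measurements, as item_id -> MeasurementSample."""
    return read_measurements(
        _data_path("example_measurements.csv"), sd_denominator=sd_denominator
    )


def example_specs() -> dict[str, FitnessSpec]:
    """Per-item specifications (limits, k = 6, alpha = 0.05, phi = 0.4/0.8)."""
    return read_specs(_data_path("example_spec.yaml"))


def example_printed_statistics() -> pd.DataFrame:
    """Published summary statistics (mean, sd, PF*) per item.

    These are the rounded values from the published statistics table;
    for two items they are not reproducible from the raw measurements
    (see module docstring).
    """
    return pd.read_csv(_data_path("example_printed_stats.csv"))


def write_example_files(directory: str | Path) -> list[Path]:
    """Copy the fixture files into `directory`; returns written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in (
        "example_measurements.csv",
        "example_spec.yaml",
        "example_printed_stats.csv",
    ):
        target = directory / name
        target.write_text(_data_path(name).read_text(encoding="utf-8"),
                          encoding="utf-8")
        written.append(target)
    return written
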