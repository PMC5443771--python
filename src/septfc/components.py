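"""Energy-based categorization of time-frequency components.

Every decomposed recording is split into exactly one *high-energy* TFC (the
component with the largest power), *middle-energy* TFCs (relative energy
strictly greater than a threshold, 2% by default) and *low-energy* TFCs (the
remainder). The high component tracks the classical main SEP peak; the middle
and low components are the small constituents whose time-frequency
distribution carries the injury-level information exploited downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matching_pursuit import TFC
from .recording import Condition, ValidationError

__all__ = ["CategorizedTFCs", "categorize", "tfc_points", "DEFAULT_ENERGY_THRESHOLD"]

#: relative-energy boundary between middle- and low-energy components
DEFAULT_ENERGY_THRESHOLD = 0.02


@dataclass
class CategorizedTFCs:
    """A recording's TFCs partitioned by relative energy.

    Invariants: ``high`` has the maximal power; middle components have
    ``relative_energy > energy_threshold`` (strict); low components sit at or
    below it; the three parts partition the input list.
    """

    subject_id: str
    condition: Condition
    high: TFC
    middle: list[TFC] = field(default_factory=list)
    low: list[TFC] = field(default_factory=list)
    energy_threshold: float = DEFAULT_ENERGY_THRESHOLD

    @property
    def all_tfcs(self) -> list[TFC]:
        return [self.high, *self.middle, *self.low]

    def __len__(self) -> int:
        return 1 + len(self.middle) + len(self.low)


def _high_sort_key(tfc: TFC):
    # highest power first; ties -> earliest time, then lowest frequency
    return (-tfc.power, tfc.time_ms, tfc.frequency_hz)


def categorize(
    tfcs,
    energy_threshold: float = DEFAULT_ENERGY_THRESHOLD,
    subject_id: str = "",
    condition: Condition | str = Condition.UNKNOWN,
) -> CategorizedTFCs:
    """Partition a recording's TFCs into high/middle/low energy classes.

    The single highest-power component is the high-energy TFC regardless of
    the threshold; among the rest, components with relative energy strictly
    above ``energy_threshold`` are middle-energy (a component exactly at the
    boundary is low-energy). Ties for highest power resolve to the earliest
    time, then the lowest frequency.
    """
    tfcs = list(tfcs)
    if not tfcs:
        raise ValidationError("cannot categorize an empty TFC list")
    if not (0 < energy_threshold < 1):
        raise ValidationError(f"energy_threshold must be in (0, 1), got {energy_threshold}")
    ordered = sorted(tfcs, key=_high_sort_key)
    high, rest = ordered[0], ordered[1:]
    middle = [t for t in rest if t.relative_energy > energy_threshold]
    low = [t for t in rest if t.relative_energy <= energy_threshold]
    return CategorizedTFCs(
        subject_id=subject_id,
        condition=Condition.coerce(condition),
        high=high,
        middle=middle,
        low=low,
        energy_threshold=energy_threshold,
    )


def tfc_points(group, category: str) -> pd.DataFrame:
    """Flatten one category of a group of categorized recordings to points.

    Returns a subject-tagged point cloud: columns ``subject_id``,
    ``condition``, ``time_ms``, ``frequency_hz`` and, for the high category
    only, ``power_uv2`` (the high component lives in time-frequency-power
    space; middle/low distributions are two-dimensional).
    """
    group = list(group)
    if not group:
        raise ValidationError("tfc_points requires a non-empty group")
    if category not in ("high", "middle", "low"):
        raise ValidationError(f"unknown category {category!r}")
    rows = []
    for cat in group:
        tfcs = [cat.high] if category == "high" else getattr(cat, category)
        for t in tfcs:
            row = {
                "subject_id": cat.subject_id,
                "condition": cat.condition.value,
                "time_ms": t.time_ms,
                "frequency_hz": t.frequency_hz,
            }
            if category == "high":
                row["power_uv2"] = t.power
            rows.append(row)
    columns = ["subject_id", "condition", "time_ms", "frequency_hz"]
    if category == "high":
        columns.append("power_uv2")
    return pd.DataFrame(rows, columns=columns)


def categorized_table(group) -> pd.DataFrame:
    """Export a group of categorized recordings as a flat table.

    Mirrors the TFC table schema with a ``category`` column appended.
    """
    rows = []
    for cat in group:
        for cname, tfcs in (("high", [cat.high]), ("middle", cat.middle), ("low", cat.low)):
            for t in tfcs:
                rows.append(
                    {
                        "subject_id": cat.subject_id,
                        "condition": cat.condition.value,
                        "rank": t.rank,
                        "time_ms": t.time_ms,
                        "frequency_hz": t.frequency_hz,
                        "power_uv2": t.power,
                        "relative_energy": t.relative_energy,
                        "category": cname,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "condition",
            "rank",
            "time_ms",
            "frequency_hz",
            "power_uv2",
            "relative_energy",
            "category",
        ],
    )
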