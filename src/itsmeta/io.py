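"""Reading the tabular ITS repository and applying the inclusion filters.

Canonical long-format schema (CSV), one row per observed time point:

    meta_id, study_id, time, interval_unit, interruption_time, segment,
    value, outcome_type, beneficial_direction[, is_control]

``segment`` is 1 before the first interruption, 2 from the first
interruption, and 3+ for segments after any later interruptions (those
are truncated away by the filters). ``interruption_time`` is the time
index of the first interruption. A ``column_map`` argument lets callers
rename foreign column layouts onto this schema.

Inclusion filters mirror standard ITS meta-analysis eligibility: at least
three datapoints per segment, a zero-value proportion no greater than 40%
(strict: exactly 40% is retained; the 30% sensitivity mode tightens this),
control series removed, and multi-interruption series truncated to the
first interruption and its adjacent segments. Meta-analyses left with
fewer than two studies are dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .types import INTERVAL_UNITS, TimeSeriesStudy, ValidationError

__all__ = [
    "RepositoryStudy",
    "RepositoryData",
    "read_repository",
    "apply_inclusion_filters",
    "Exclusion",
]

REQUIRED_COLUMNS = (
    "meta_id",
    "study_id",
    "time",
    "interval_unit",
    "interruption_time",
    "segment",
    "value",
    "outcome_type",
    "beneficial_direction",
)


@dataclass
class RepositoryStudy:
    """One raw series as read from the repository, before eligibility filtering."""

    meta_id: str
    study_id: str
    times: np.ndarray
    values: np.ndarray
    segments: np.ndarray
    interruption_time: int
    interval_unit: str
    outcome_type: str
    beneficial_direction: str
    is_control: bool = False

    @property
    def zero_proportion(self) -> float:
        """Fraction of observed values exactly equal to zero."""
        return float(np.mean(self.values == 0.0))


@dataclass
class RepositoryData:
    studies: list[RepositoryStudy]
    source: Optional[str] = None

    def by_meta(self) -> dict[str, list[RepositoryStudy]]:
        out: dict[str, list[RepositoryStudy]] = {}
        for s in self.studies:
            out.setdefault(s.meta_id, []).append(s)
        return out


def read_repository(path, column_map: Optional[dict[str, str]] = None) -> RepositoryData:
    """Read and structurally validate a repository CSV.

    Raises :class:`ValidationError` naming the offending study / line for
    missing columns, duplicate (meta_id, study_id, time) keys, gaps in the
    time index, missing values, or unknown interval units.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValidationError(f"{path}: repository file is empty")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    if "is_control" not in df.columns:
        df["is_control"] = 0

    dup = df.duplicated(subset=["meta_id", "study_id", "time"])
    if dup.any():
        i = int(np.argmax(dup.to_numpy()))
        r = df.iloc[i]
        raise ValidationError(
            f"{path} line {i + 2}: duplicate key (meta_id={r.meta_id!r}, "
            f"study_id={r.study_id!r}, time={r.time})"
        )
    if df["value"].isna().any():
        i = int(df.index[df["value"].isna()][0])
        r = df.iloc[i]
        raise ValidationError(f"{path} line {i + 2}: missing value in study {r.study_id!r}")

    studies: list[RepositoryStudy] = []
    for (meta_id, study_id), g in df.groupby(["meta_id", "study_id"], sort=True):
        g = g.sort_values("time")
        times = g["time"].to_numpy(dtype=int)
        gaps = np.diff(times)
        if np.any(gaps != 1):
            bad = int(np.argmax(gaps != 1))
            raise ValidationError(
                f"{path}: study {study_id!r} (meta {meta_id!r}) has a gap in its "
                f"time index between t={times[bad]} and t={times[bad + 1]}"
            )
        unit = str(g["interval_unit"].iloc[0])
        if unit not in INTERVAL_UNITS:
            raise ValidationError(
                f"{path}: study {study_id!r} has unknown interval_unit {unit!r}"
            )
        studies.append(
            RepositoryStudy(
                meta_id=str(meta_id),
                study_id=str(study_id),
                times=times,
                values=g["value"].to_numpy(dtype=float),
                segments=g["segment"].to_numpy(dtype=int),
                interruption_time=int(g["interruption_time"].iloc[0]),
                interval_unit=unit,
                outcome_type=str(g["outcome_type"].iloc[0]),
                beneficial_direction=str(g["beneficial_direction"].iloc[0]),
                is_control=bool(g["is_control"].iloc[0]),
            )
        )
    return RepositoryData(studies=studies, source=str(path))


@dataclass
class Exclusion:
    meta_id: str
    study_id: str
    rule: str
    detail: str


@dataclass
class FilterResult:
    included: dict[str, list[TimeSeriesStudy]]
    directions: dict[str, str]
    exclusions: list[Exclusion]
    truncated: list[str] = field(default_factory=list)
    dropped_metas: list[str] = field(default_factory=list)

    @property
    def n_included(self) -> int:
        return sum(len(v) for v in self.included.values())


def _truncate_first_interruption(s: RepositoryStudy) -> tuple[RepositoryStudy, bool]:
    """Keep only segments 1 and 2 (up to the point before a second interruption)."""
    keep = s.segments <= 2
    if keep.all():
        return s, False
    return (
        RepositoryStudy(
            meta_id=s.meta_id,
            study_id=s.study_id,
            times=s.times[keep],
            values=s.values[keep],
            segments=s.segments[keep],
            interruption_time=s.interruption_time,
            interval_unit=s.interval_unit,
            outcome_type=s.outcome_type,
            beneficial_direction=s.beneficial_direction,
            is_control=s.is_control,
        ),
        True,
    )


def apply_inclusion_filters(
    data: RepositoryData,
    zero_threshold: float = 0.40,
    min_points_per_segment: int = 3,
    first_interruption_only: bool = True,
    drop_controls: bool = True,
) -> FilterResult:
    """Apply the eligibility rules; nothing here raises, everything is logged.

    Exclusion rules, each recorded with the study it removed:
      - ``control_series``: is_control set and drop_controls requested;
      - ``zero_proportion``: strictly more than ``zero_threshold`` of the
        observed values are exactly zero (set 0.30 for the sensitivity
        analysis);
      - ``min_points``: fewer than ``min_points_per_segment`` datapoints
        before or after the (first) interruption, after any truncation;
      - ``meta_too_small``: the parent meta-analysis retained fewer than
        two studies (each surviving study is re-logged under this rule).
    """
    included: dict[str, list[TimeSeriesStudy]] = {}
    directions: dict[str, str] = {}
    exclusions: list[Exclusion] = []
    truncated: list[str] = []

    for s in data.studies:
        directions.setdefault(s.meta_id, s.beneficial_direction)
        if drop_controls and s.is_control:
            exclusions.append(Exclusion(s.meta_id, s.study_id, "control_series", "control arm removed"))
            continue
        if first_interruption_only:
            s, was_truncated = _truncate_first_interruption(s)
            if was_truncated:
                truncated.append(s.study_id)
        zp = s.zero_proportion
        if zp > zero_threshold:
            exclusions.append(
                Exclusion(s.meta_id, s.study_id, "zero_proportion",
                          f"{100 * zp:.1f}% of values are zero (> {100 * zero_threshold:.0f}%)")
            )
            continue
        n_pre = int(np.sum(s.times < s.interruption_time))
        n_post = int(np.sum((s.times >= s.interruption_time) & (s.segments <= 2)))
        if n_pre < min_points_per_segment or n_post < min_points_per_segment:
            exclusions.append(
                Exclusion(s.meta_id, s.study_id, "min_points",
                          f"{n_pre} pre / {n_post} post datapoints (< {min_points_per_segment})")
            )
            continue
        # times may start anywhere; shift onto the canonical 1..T index
        offset = int(s.times[0]) - 1
        study = TimeSeriesStudy(
            study_id=s.study_id,
            times=s.times - offset,
            values=s.values,
            interruption_index=s.interruption_time - offset,
            interval_unit=s.interval_unit,
            outcome_type=s.outcome_type,
        )
        included.setdefault(s.meta_id, []).append(study)

    dropped_metas = [m for m, studies in included.items() if len(studies) < 2]
    for m in dropped_metas:
        for st in included[m]:
            exclusions.append(
                Exclusion(m, st.study_id, "meta_too_small",
                          "meta-analysis retained fewer than two ITS studies")
            )
        del included[m]
    return FilterResult(
        included=included,
        directions=directions,
        exclusions=exclusions,
        truncated=truncated,
        dropped_metas=dropped_metas,
    )


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
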