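"""TSV experiment tables: chemostat series, fermenter time courses, and
expression matrices.

All tables are tab-separated with a header row; lines starting with ``#``
are comments and conventionally carry unit declarations and provenance.
Exchange-rate columns follow the model sign convention (uptake negative)
unless a direction map declares magnitudes-with-direction. Column names are
mapped onto exchange-reaction ids through a user-supplied alias map.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ..data import ChemostatRecord, OmicsMatrix, TimeCoursePoint

__all__ = [
    "read_experiment_table",
    "write_chemostat_table",
    "write_timecourse_table",
    "write_expression_table",
    "TableError",
]


class TableError(ValueError):
    """Malformed experiment table."""


_CHEMOSTAT_REQUIRED = ("condition", "dilution_rate")
_TIMECOURSE_REQUIRED = ("time",)
_TIMECOURSE_SPECIAL = ("time", "biomass", "act_rate", "red_rate")


def _read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _require(frame: pd.DataFrame, required: Sequence[str], kind: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TableError(
            f"{kind} table is missing column(s) {missing}; expected headers "
            f"include {list(required)}"
        )


def _apply_direction(value: float, column: str, directions: Optional[Mapping[str, str]]) -> float:
    if directions and column in directions:
        d = directions[column]
        if d == "uptake":
            return -abs(value)
        if d == "production":
            return abs(value)
        raise TableError(f"unknown direction {d!r} for column {column!r}")
    return value


def read_experiment_table(
    path: str,
    kind: str,
    alias_map: Optional[Mapping[str, str]] = None,
    directions: Optional[Mapping[str, str]] = None,
) -> Union[List[ChemostatRecord], List[TimeCoursePoint], OmicsMatrix]:
    """Read a chemostat, time-course or expression table.

    ``alias_map`` translates rate column names to exchange-reaction ids
    (identity by default). ``directions`` may mark columns as ``"uptake"``
    or ``"production"`` magnitudes, which are then signed on read.
    """
    if kind == "chemostat":
        return _read_chemostat(path, alias_map, directions)
    if kind == "timecourse":
        return _read_timecourse(path, alias_map, directions)
    if kind == "expression":
        return _read_expression(path)
    raise TableError(
        f"unknown table kind {kind!r}; expected chemostat, timecourse or expression"
    )


def _read_chemostat(path, alias_map, directions) -> List[ChemostatRecord]:
    frame = _read_tsv(path)
    _require(frame, _CHEMOSTAT_REQUIRED, "chemostat")
    alias = dict(alias_map or {})
    records: List[ChemostatRecord] = []
    for _, row in frame.iterrows():
        rates: Dict[str, float] = {}
        for col in frame.columns:
            if col in _CHEMOSTAT_REQUIRED:
                continue
            val = row[col]
            if pd.isna(val):
                continue
            rates[alias.get(col, col)] = _apply_direction(float(val), col, directions)
        records.append(
            ChemostatRecord(
                dilution_rate=float(row["dilution_rate"]),
                exchange_rates=rates,
                condition=str(row["condition"]),
            )
        )
    return records


def _read_timecourse(path, alias_map, directions) -> List[TimeCoursePoint]:
    frame = _read_tsv(path)
    _require(frame, _TIMECOURSE_REQUIRED, "time-course")
    times = frame["time"].to_numpy(dtype=float)
    if len(times) and np.any(np.diff(times) <= 0):
        raise TableError("time column must be strictly increasing")
    alias = dict(alias_map or {})
    points: List[TimeCoursePoint] = []
    for _, row in frame.iterrows():
        rates: Dict[str, float] = {}
        for col in frame.columns:
            if col in _TIMECOURSE_SPECIAL:
                continue
            val = row[col]
            if pd.isna(val):
                continue
            rates[alias.get(col, col)] = _apply_direction(float(val), col, directions)
        anti: Dict[str, float] = {}
        for key, col in (("act", "act_rate"), ("red", "red_rate")):
            if col in frame.columns and not pd.isna(row[col]):
                anti[key] = float(row[col])
        biomass = None
        if "biomass" in frame.columns and not pd.isna(row["biomass"]):
            biomass = float(row["biomass"])
        points.append(
            TimeCoursePoint(
                time=float(row["time"]),
                biomass=biomass,
                exchange_rates=rates,
                antibiotic_rates=anti,
            )
        )
    return points


def _read_expression(path) -> OmicsMatrix:
    frame = _read_tsv(path)
    if frame.columns[0] != "gene_id":
        raise TableError(
            "expression table must start with a gene_id column followed by "
            "time-stamped columns"
        )
    frame = frame.set_index("gene_id")
    try:
        frame.columns = [float(c) for c in frame.columns]
    except ValueError as exc:
        raise TableError("expression column headers must be numeric times") from exc
    return OmicsMatrix(frame)


# --- writers ---------------------------------------------------------------


def _write_with_header(path: str, frame: pd.DataFrame, comments: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def write_chemostat_table(
    records: Sequence[ChemostatRecord], path: str, comments: Sequence[str] = ()
) -> None:
    """One row per steady state: condition, dilution_rate, exchange columns."""
    exchanges: List[str] = []
    for rec in records:
        for ex in rec.exchange_rates:
            if ex not in exchanges:
                exchanges.append(ex)
    rows = [
        {
            "condition": rec.condition or f"D{i + 1}",
            "dilution_rate": rec.dilution_rate,
            **{ex: rec.exchange_rates.get(ex, "") for ex in exchanges},
        }
        for i, rec in enumerate(records)
    ]
    header = ["units: dilution_rate h^-1; exchange rates mmol gDW^-1 h^-1 "
              "(uptake negative)"]
    _write_with_header(path, pd.DataFrame(rows), [*header, *comments])


def write_timecourse_table(
    points: Sequence[TimeCoursePoint], path: str, comments: Sequence[str] = ()
) -> None:
    """One row per time point: time, biomass, exchange columns, act/red rates."""
    exchanges: List[str] = []
    for pt in points:
        for ex in pt.exchange_rates:
            if ex not in exchanges:
                exchanges.append(ex)
    rows = [
        {
            "time": pt.time,
            "biomass": "" if pt.biomass is None else pt.biomass,
            **{ex: pt.exchange_rates.get(ex, "") for ex in exchanges},
            "act_rate": pt.antibiotic_rates.get("act", 0.0),
            "red_rate": pt.antibiotic_rates.get("red", 0.0),
        }
        for pt in points
    ]
    header = ["units: time h; biomass gDW L^-1; rates mmol gDW^-1 h^-1 "
              "(uptake negative)"]
    _write_with_header(path, pd.DataFrame(rows), [*header, *comments])


def write_expression_table(
    matrix: OmicsMatrix, path: str, comments: Sequence[str] = ()
) -> None:
    """gene_id column followed by one column per time point."""
    frame = matrix.values.copy()
    frame.insert(0, "gene_id", frame.index)
    _write_with_header(
        path, frame, ["expression matrix: gene_id then time (h) columns", *comments]
    )
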