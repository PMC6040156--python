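"""Containers for experimental data: chemostat steady states, fermenter
time courses, and omics (transcript/protein) time-series matrices.

Exchange rates follow the model sign convention everywhere: uptake negative,
production positive, in mmol·gDW⁻¹·h⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["ChemostatRecord", "TimeCoursePoint", "OmicsMatrix", "DataError"]


class DataError(ValueError):
    """Invalid experimental data."""


@dataclass
class ChemostatRecord:
    """One chemostat steady state: dilution rate D (h⁻¹, equal to μ at
    steady state) plus measured exchange rates keyed by exchange-reaction id."""

    dilution_rate: float
    exchange_rates: Dict[str, float] = field(default_factory=dict)
    condition: str = ""

    def __post_init__(self):
        if self.dilution_rate <= 0:
            raise DataError(f"dilution rate must be > 0, got {self.dilution_rate}")
        if not any(v < 0 for v in self.exchange_rates.values()):
            raise DataError("chemostat record needs at least one uptake (negative) rate")


@dataclass
class TimeCoursePoint:
    """One fermenter measurement: time (h), biomass (gDW·L⁻¹, optional),
    exchange rates, and specific antibiotic production rates ("act", "red")."""

    time: float
    biomass: Optional[float] = None
    exchange_rates: Dict[str, float] = field(default_factory=dict)
    antibiotic_rates: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.biomass is not None and self.biomass <= 0:
            raise DataError(f"biomass must be > 0 when present, got {self.biomass}")


def check_timecourse(points: Sequence[TimeCoursePoint]) -> None:
    """Raise unless times are strictly increasing."""
    times = [p.time for p in points]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise DataError(f"time points must be strictly increasing, got {times}")


class OmicsMatrix:
    """Entities (genes or proteins) × ordered time points.

    Thin wrapper around a pandas DataFrame (index = entity ids, columns =
    time points as floats). Missing values (NaN) are allowed, as is typical
    for proteomics. ``meta`` carries generator ground truth when the matrix
    is synthetic.
    """

    def __init__(self, values: pd.DataFrame, meta: Optional[dict] = None):
        if values.columns.duplicated().any():
            raise DataError("duplicated time points")
        self.values = values.copy()
        self.values.columns = [float(c) for c in values.columns]
        self.meta = dict(meta or {})

    @property
    def entities(self) -> List[str]:
        return list(self.values.index)

    @property
    def times(self) -> List[float]:
        return list(self.values.columns)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def series(self, entity: str) -> np.ndarray:
        return self.values.loc[entity].to_numpy(dtype=float)

    def __contains__(self, entity: str) -> bool:
        return entity in self.values.index

    def __len__(self) -> int:
        return self.values.shape[0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, OmicsMatrix):
            return NotImplemented
        return self.values.equals(other.values)
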