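"""Batch-fermentation kinetics: interval rates and end-point yields.

Ethanol yield is expressed as a percentage of the stoichiometric maximum of
alcoholic fermentation, 0.511 g ethanol per g glucose; glycerol yield is a
plain g/g ratio on glucose consumed.  Rates are interval volumetric rates,
|dC| / dt over a stated window (default 0-24 h), with linear interpolation
between measured time points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

#: stoichiometric maximum of alcoholic fermentation, g ethanol per g glucose
THEORETICAL_ETHANOL_YIELD = 0.511

TIMECOURSE_COLUMNS = ("time_h", "cells_per_ml", "glucose_gL", "ethanol_gL", "glycerol_gL")

_ANALYTES = {
    "cells": "cells_per_ml",
    "glucose": "glucose_gL",
    "ethanol": "ethanol_gL",
    "glycerol": "glycerol_gL",
}


@dataclass
class FermentationTimecourse:
    """Timed concentrations from one closed-vessel fermentation."""

    data: pd.DataFrame
    strain: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        missing = set(TIMECOURSE_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"time course missing columns: {sorted(missing)}")
        t = self.data["time_h"].to_numpy(dtype=float)
        if len(t) < 2 or not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing with >= 2 points")
        for col in TIMECOURSE_COLUMNS[1:]:
            v = self.data[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(v)) or (v < 0).any():
                raise ValueError(f"{col}: values must be finite and >= 0")
        glc = self.data["glucose_gL"].to_numpy(dtype=float)
        if (np.diff(glc) > 1e-9).any():
            warnings.warn("glucose concentration increases between some time points")

    @property
    def times(self) -> np.ndarray:
        return self.data["time_h"].to_numpy(dtype=float)

    def at(self, analyte: str, t: float) -> float:
        """Concentration at time ``t`` (linear interpolation between grid points)."""
        col = _ANALYTES.get(analyte, analyte)
        if col not in self.data.columns:
            raise KeyError(f"unknown analyte {analyte!r}")
        times = self.times
        if not (times[0] <= t <= times[-1]):
            raise ValueError(f"t={t} outside measured range [{times[0]}, {times[-1]}]")
        return float(np.interp(t, times, self.data[col].to_numpy(dtype=float)))

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def read_timecourse(
    source: str | Path, strain: str = "", condition: str = ""
) -> FermentationTimecourse:
    return FermentationTimecourse(
        pd.read_csv(source, sep="\t"), strain=strain, condition=condition
    )


class IntervalRate(NamedTuple):
    rate: float  # g/(L·h), always >= 0
    direction: str  # consumption | production | flat


def interval_rate(
    tc: FermentationTimecourse, analyte: str, t0: float, t1: float
) -> IntervalRate:
    """Volumetric rate |C(t1) - C(t0)| / (t1 - t0) with direction recorded."""
    if t1 <= t0:
        raise ValueError(f"need t0 < t1, got ({t0}, {t1})")
    c0, c1 = tc.at(analyte, t0), tc.at(analyte, t1)
    delta = c1 - c0
    rate = abs(delta) / (t1 - t0)
    if delta < 0:
        direction = "consumption"
    elif delta > 0:
        direction = "production"
    else:
        direction = "flat"
    return IntervalRate(rate=rate, direction=direction)


def ethanol_yield_percent(ethanol_produced: float, glucose_consumed: float) -> float:
    """Ethanol yield as percent of the 0.511 g/g stoichiometric maximum."""
    if glucose_consumed <= 0:
        raise ValueError("glucose consumed must be > 0")
    if ethanol_produced < 0:
        raise ValueError("ethanol produced must be >= 0")
    return 100.0 * ethanol_produced / (THEORETICAL_ETHANOL_YIELD * glucose_consumed)


def glycerol_yield(glycerol_produced: float, glucose_consumed: float) -> float:
    """Glycerol yield in g per g glucose consumed."""
    if glucose_consumed <= 0:
        raise ValueError("glucose consumed must be > 0")
    if glycerol_produced < 0:
        raise ValueError("glycerol produced must be >= 0")
    return glycerol_produced / glucose_consumed


@dataclass
class KineticsSummary:
    strain: str
    condition: str
    glucose_consumption_rate: float  # g/(L·h) over [t0, t1]
    ethanol_production_rate: float  # g/(L·h) over [t0, t1]
    ethanol_yield_percent: float  # % of theoretical, at end_time
    glycerol_yield: float  # g/g glucose consumed, at end_time
    residual_glucose: float  # g/L at end_time
    rate_interval: tuple[float, float]
    end_time: float

    def to_dict(self) -> dict:
        return {
            "strain": self.strain,
            "condition": self.condition,
            "glucose_consumption_rate_gLh": self.glucose_consumption_rate,
            "ethanol_production_rate_gLh": self.ethanol_production_rate,
            "ethanol_yield_percent": self.ethanol_yield_percent,
            "glycerol_yield_gg": self.glycerol_yield,
            "residual_glucose_gL": self.residual_glucose,
            "rate_interval_h": list(self.rate_interval),
            "end_time_h": self.end_time,
        }


def kinetics_summary(
    tc: FermentationTimecourse,
    t0: float = 0.0,
    t1: float = 24.0,
    end_time: float | None = None,
) -> KineticsSummary:
    """Rates over [t0, t1] and yields at ``end_time`` (default: last time point).

    Glucose consumed is measured from the observed initial concentration,
    C_glucose(t0=0) - C_glucose(end), not from a nominal medium recipe.
    """
    if end_time is None:
        end_time = float(tc.times[-1])
    q_s = interval_rate(tc, "glucose", t0, t1).rate
    q_p = interval_rate(tc, "ethanol", t0, t1).rate
    g0 = tc.at("glucose", tc.times[0])
    g_end = tc.at("glucose", end_time)
    consumed = g0 - g_end
    eth = tc.at("ethanol", end_time) - tc.at("ethanol", tc.times[0])
    gly = tc.at("glycerol", end_time) - tc.at("glycerol", tc.times[0])
    if consumed > 0:
        y_e = ethanol_yield_percent(eth, consumed)
        y_g = glycerol_yield(gly, consumed)
    else:
        y_e = float("nan")
        y_g = float("nan")
    return KineticsSummary(
        strain=tc.strain,
        condition=tc.condition,
        glucose_consumption_rate=q_s,
        ethanol_production_rate=q_p,
        ethanol_yield_percent=y_e,
        glycerol_yield=y_g,
        residual_glucose=g_end,
        rate_interval=(t0, t1),
        end_time=end_time,
    )


def carbon_balance_ok(tc: FermentationTimecourse, end_time: float | None = None) -> bool:
    """Sanity check (reported, never enforced): product carbon <= substrate carbon.

    Carbon fractions by mass: glucose 0.400, ethanol 0.522, glycerol 0.391.
    """
    if end_time is None:
        end_time = float(tc.times[-1])
    consumed = tc.at("glucose", tc.times[0]) - tc.at("glucose", end_time)
    eth = tc.at("ethanol", end_time) - tc.at("ethanol", tc.times[0])
    gly = tc.at("glycerol", end_time) - tc.at("glycerol", tc.times[0])
    return eth * 0.522 + gly * 0.391 <= consumed * 0.400 + 1e-9
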