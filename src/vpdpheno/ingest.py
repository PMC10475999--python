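"""Readers and writers for the tabular inputs and outputs of the pipeline.

Three input kinds are handled:

* instrument-style leaf gas-exchange CSV (one row per logged record,
  several plants per file, a user-supplied column map accommodating
  export variants);
* balance logs (time, total pot mass) joined with a per-plant leaf-area
  table;
* the experiment design file (YAML) describing the humidity step-change
  protocol.

All CSVs are comma-separated, '.' decimal, UTF-8, one header row.
Numeric output is written at 12 significant digits so a write-then-read
round trip is lossless for practical purposes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .envphys import vpd

__all__ = [
    "Step",
    "StepDesign",
    "GasExchangeSeries",
    "BalanceSeries",
    "FormatError",
    "read_gas_exchange",
    "write_gas_exchange",
    "read_balance",
    "write_balance",
    "read_design",
    "write_design",
    "write_table",
    "read_table",
    "DEFAULT_GASEX_COLUMNS",
    "DEFAULT_BALANCE_COLUMNS",
]

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


# ---------------------------------------------------------------------------
# Experiment design


@dataclass(frozen=True)
class Step:
    """One humidity step of the protocol.

    ``realized_vpd`` is the measured chamber-mean VPD when available;
    it is kept distinct from the set-point computation (the two are
    close but not identical in practice and are never asserted equal).
    """

    index: int
    target_rh: float  # percent
    temperature: float  # deg C set-point (air or leaf, per measurement level)
    duration_min: float
    realized_vpd: float | None = None

    def target_vpd(self) -> float:
        """Set-point VPD from temperature and target RH."""
        return vpd(self.temperature, self.target_rh / 100.0)

    def vpd_value(self) -> float:
        """Realized VPD when recorded, else the set-point VPD."""
        return self.realized_vpd if self.realized_vpd is not None else self.target_vpd()


@dataclass(frozen=True)
class StepDesign:
    """Ordered VPD step schedule; RH strictly decreases across steps."""

    steps: tuple[Step, ...]

    def __post_init__(self):
        if not self.steps:
            raise ValueError("StepDesign needs at least one step")
        rh = [s.target_rh for s in self.steps]
        if any(s.duration_min <= 0 for s in self.steps):
            raise ValueError("step durations must be positive")
        if any(b >= a for a, b in zip(rh, rh[1:])):
            raise ValueError("target RH must strictly decrease across steps")
        if [s.index for s in self.steps] != list(range(len(self.steps))):
            raise ValueError("step indices must be 0..n-1 in order")

    @property
    def n_levels(self) -> int:
        return len(self.steps)

    def boundaries_s(self) -> np.ndarray:
        """Cumulative step boundaries in seconds: [0, t1, ..., t_end]."""
        durs = np.array([s.duration_min for s in self.steps]) * 60.0
        return np.concatenate([[0.0], np.cumsum(durs)])

    def step_of(self, time_s) -> np.ndarray:
        """Step index for each elapsed time (-1 outside the protocol).

        Steps own the half-open interval (start, end]: a record logged
        exactly at a boundary is the last reading of the ending step.
        """
        t = np.asarray(time_s, dtype=float)
        edges = self.boundaries_s()
        idx = np.searchsorted(edges[1:], t, side="left")
        idx = np.where((t < 0) | (t > edges[-1]), -1, np.clip(idx, 0, len(self.steps) - 1))
        return idx

    def vpd_values(self) -> np.ndarray:
        return np.array([s.vpd_value() for s in self.steps])


def read_design(path) -> StepDesign:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    try:
        items = raw["steps"]
    except (TypeError, KeyError) as exc:
        raise FormatError(f"design file {path} lacks a 'steps' list") from exc
    steps = tuple(
        Step(
            index=int(d["index"]),
            target_rh=float(d["target_rh"]),
            temperature=float(d["temperature"]),
            duration_min=float(d["duration_min"]),
            realized_vpd=None if d.get("realized_vpd") is None else float(d["realized_vpd"]),
        )
        for d in items
    )
    return StepDesign(steps=steps)


def write_design(design: StepDesign, path) -> None:
    payload = {
        "steps": [
            {
                "index": s.index,
                "target_rh": s.target_rh,
                "temperature": s.temperature,
                "duration_min": s.duration_min,
                "realized_vpd": s.realized_vpd,
            }
            for s in design.steps
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Time-series containers


@dataclass
class GasExchangeSeries:
    """Time-ordered leaf gas-exchange records for one plant.

    ``data`` columns: time_s, gs (mol m-2 s-1), e (mmol m-2 s-1),
    a (umol m-2 s-1), t_leaf (deg C), rh (percent), vpd_leaf (kPa).
    """

    plant_id: str
    accession_id: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        t = self.data["time_s"].to_numpy(dtype=float)
        if len(t) and np.any(np.diff(t) <= 0):
            bad = int(np.argmax(np.diff(t) <= 0)) + 1
            raise FormatError(
                f"plant {self.plant_id}: time not strictly increasing at row {bad}"
            )
        if np.any(self.data["gs"].to_numpy(dtype=float) < 0):
            raise FormatError(f"plant {self.plant_id}: negative gs")
        if np.any(self.data["vpd_leaf"].to_numpy(dtype=float) <= 0):
            raise FormatError(f"plant {self.plant_id}: non-positive VPD_leaf")


@dataclass
class BalanceSeries:
    """Time-ordered balance (total mass) records for one plant."""

    plant_id: str
    accession_id: str
    data: pd.DataFrame = field(repr=False)  # columns: time_s, mass_g
    leaf_area_m2: float = float("nan")

    def __post_init__(self):
        t = self.data["time_s"].to_numpy(dtype=float)
        if len(t) and np.any(np.diff(t) <= 0):
            bad = int(np.argmax(np.diff(t) <= 0)) + 1
            raise FormatError(
                f"plant {self.plant_id}: time not strictly increasing at row {bad}"
            )
        if np.any(self.data["mass_g"].to_numpy(dtype=float) <= 0):
            raise FormatError(f"plant {self.plant_id}: non-positive mass")
        if not (self.leaf_area_m2 > 0):
            raise ValueError(
                f"plant {self.plant_id}: leaf area must be positive, "
                f"got {self.leaf_area_m2}"
            )


# Logical name -> file column for the default instrument-style export.
DEFAULT_GASEX_COLUMNS: dict[str, str] = {
    "time_s": "elapsed",
    "gs": "gsw",
    "e": "E",
    "a": "A",
    "t_leaf": "Tleaf",
    "rh": "rh_s",
    "vpd_leaf": "VPDleaf",
    "plant": "plant_id",
    "accession": "accession",
}

DEFAULT_BALANCE_COLUMNS: dict[str, str] = {
    "time_s": "elapsed",
    "mass_g": "mass",
    "plant": "plant_id",
    "accession": "accession",
}


def _remap(df: pd.DataFrame, column_map: Mapping[str, str], path) -> pd.DataFrame:
    missing = [src for src in column_map.values() if src not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    out = df[[column_map[k] for k in column_map]].copy()
    out.columns = list(column_map)
    return out


def read_gas_exchange(path, column_map: Mapping[str, str] | None = None) -> list[GasExchangeSeries]:
    """Read an instrument-style gas-exchange CSV into per-plant series.

    Rows with any missing required field are dropped (count logged).
    Raises :class:`FormatError` for missing columns or non-monotone time.
    """
    column_map = dict(column_map or DEFAULT_GASEX_COLUMNS)
    df = _remap(pd.read_csv(path), column_map, path)
    value_cols = ["time_s", "gs", "e", "a", "t_leaf", "rh", "vpd_leaf"]
    n0 = len(df)
    df = df.dropna(subset=value_cols + ["plant", "accession"])
    dropped = n0 - len(df)
    if dropped:
        log.warning("%s: dropped %d row(s) with missing fields", path, dropped)
    series = []
    for (plant, accession), grp in df.groupby(["plant", "accession"], sort=True):
        series.append(
            GasExchangeSeries(
                plant_id=str(plant),
                accession_id=str(accession),
                data=grp[value_cols].reset_index(drop=True).astype(float),
            )
        )
    return series


def write_gas_exchange(series: Sequence[GasExchangeSeries], path,
                       column_map: Mapping[str, str] | None = None) -> None:
    column_map = dict(column_map or DEFAULT_GASEX_COLUMNS)
    frames = []
    for s in series:
        df = s.data.copy()
        df["plant"] = s.plant_id
        df["accession"] = s.accession_id
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out = out.rename(columns=column_map)[list(column_map.values())]
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_balance(path, leaf_areas, column_map: Mapping[str, str] | None = None) -> list[BalanceSeries]:
    """Read a balance log CSV; join leaf areas (m^2) by plant id.

    ``leaf_areas`` is a mapping plant id -> area, or a path to a CSV with
    columns ``plant_id,leaf_area_m2``.  A plant in the log with no area
    is an error; an area-table entry with no log rows is ignored with a
    warning.
    """
    column_map = dict(column_map or DEFAULT_BALANCE_COLUMNS)
    if not isinstance(leaf_areas, Mapping):
        tbl = pd.read_csv(leaf_areas)
        if not {"plant_id", "leaf_area_m2"} <= set(tbl.columns):
            raise FormatError(
                f"{leaf_areas}: leaf-area table needs columns plant_id, leaf_area_m2"
            )
        leaf_areas = dict(zip(tbl["plant_id"].astype(str), tbl["leaf_area_m2"].astype(float)))
    leaf_areas = {str(k): float(v) for k, v in leaf_areas.items()}
    for pid, area in leaf_areas.items():
        if not area > 0:
            raise ValueError(f"leaf area for plant {pid} must be positive, got {area}")

    df = _remap(pd.read_csv(path), column_map, path)
    n0 = len(df)
    df = df.dropna()
    if n0 - len(df):
        log.warning("%s: dropped %d row(s) with missing fields", path, n0 - len(df))

    seen = set()
    series = []
    for (plant, accession), grp in df.groupby(["plant", "accession"], sort=True):
        plant = str(plant)
        seen.add(plant)
        if plant not in leaf_areas:
            raise FormatError(f"{path}: no leaf area for plant {plant}")
        series.append(
            BalanceSeries(
                plant_id=plant,
                accession_id=str(accession),
                data=grp[["time_s", "mass_g"]].reset_index(drop=True).astype(float),
                leaf_area_m2=leaf_areas[plant],
            )
        )
    unused = set(leaf_areas) - seen
    if unused:
        log.warning("%s: leaf-area entries for unknown plant id(s) %s ignored",
                    path, sorted(unused))
    return series


def write_balance(series: Sequence[BalanceSeries], path, area_path=None,
                  column_map: Mapping[str, str] | None = None) -> None:
    column_map = dict(column_map or DEFAULT_BALANCE_COLUMNS)
    frames = []
    for s in series:
        df = s.data.copy()
        df["plant"] = s.plant_id
        df["accession"] = s.accession_id
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out = out.rename(columns=column_map)[list(column_map.values())]
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    if area_path is not None:
        areas = pd.DataFrame(
            {"plant_id": [s.plant_id for s in series],
             "leaf_area_m2": [s.leaf_area_m2 for s in series]}
        )
        areas.to_csv(area_path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Generic output tables


def write_table(df: pd.DataFrame, path) -> None:
    """Write an output table as CSV at 12 significant digits."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
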