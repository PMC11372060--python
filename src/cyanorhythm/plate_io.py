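"""Read, write and validate plate-reader time-series data.

The canonical on-disk representation is long-format delimited text with a
header row and the columns ``well,strain,time_h,backscatter`` (column order is
irrelevant; columns are keyed by name).  In memory, a plate is a
:class:`PlateSeries`: one strictly uniform time grid shared by every well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GridError, ParseError, ShapeError

#: Absolute tolerance (hours) for grid-spacing uniformity.
GRID_ATOL_H = 1e-9

REQUIRED_COLUMNS = ("well", "strain", "time_h", "backscatter")


@dataclass(frozen=True)
class WellTrace:
    """A single well's backscatter trace (arbitrary units)."""

    well_id: str
    strain: str
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ShapeError(f"well {self.well_id!r}: values must be 1-D")
        if not np.all(np.isfinite(values)):
            raise ParseError(f"well {self.well_id!r}: missing or non-finite values")
        object.__setattr__(self, "values", values)


def _validate_grid(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise GridError("time grid needs at least 2 points")
    steps = np.diff(times)
    if np.any(steps <= 0):
        raise GridError("time grid must be strictly increasing")
    if np.max(np.abs(steps - steps.mean())) > GRID_ATOL_H:
        raise GridError("time grid is not uniform (spacing varies by more than 1e-9 h)")
    return times


@dataclass
class PlateSeries:
    """A uniform time grid (hours) plus one trace per well."""

    times: np.ndarray
    wells: list[WellTrace] = field(default_factory=list)

    def __post_init__(self):
        self.times = _validate_grid(self.times)
        for w in self.wells:
            if w.values.size != self.times.size:
                raise ShapeError(
                    f"well {w.well_id!r}: {w.values.size} values for "
                    f"{self.times.size} time points"
                )

    def __len__(self) -> int:
        return len(self.wells)

    def strains(self) -> list[str]:
        """Distinct strain labels in first-appearance order."""
        seen: dict[str, None] = {}
        for w in self.wells:
            seen.setdefault(w.strain, None)
        return list(seen)

    def wells_of(self, strain: str) -> list[WellTrace]:
        return [w for w in self.wells if w.strain == strain]

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame, one row per (well, time point)."""
        frames = [
            pd.DataFrame(
                {
                    "well": w.well_id,
                    "strain": w.strain,
                    "time_h": self.times,
                    "backscatter": w.values,
                }
            )
            for w in self.wells
        ]
        if not frames:
            return pd.DataFrame(columns=list(REQUIRED_COLUMNS))
        return pd.concat(frames, ignore_index=True)


def sampling_interval(series: PlateSeries) -> float:
    """Constant grid spacing Δt in hours: (t_last − t_first)/(n − 1)."""
    t = series.times
    if t.size < 2:
        raise GridError("need at least 2 time points")
    return (t[-1] - t[0]) / (t.size - 1)


def read_plate_long(
    path, delimiter: str = ",", time_unit: str = "h"
) -> PlateSeries:
    """Read a long-format plate file into a validated :class:`PlateSeries`.

    Parameters
    ----------
    path : path-like or file-like
        Delimited text with columns ``well,strain,time_h,backscatter``.
    delimiter : str
        Field delimiter (comma by default).
    time_unit : {"h", "min"}
        Unit of the time column; minutes are converted to hours so that all
        downstream formulas operate in hours.
    """
    if time_unit not in ("h", "min"):
        raise ParseError(f"unknown time unit {time_unit!r}; expected 'h' or 'min'")
    df = pd.read_csv(path, sep=delimiter, dtype={"well": str, "strain": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing required column(s): {', '.join(missing)}")
    for col in ("time_h", "backscatter"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            bad = df.loc[coerced.isna(), col].iloc[0]
            raise ParseError(f"non-numeric value {bad!r} in column {col!r}")
        df[col] = coerced.astype(float)
    if df[["well", "strain"]].isna().any().any():
        raise ParseError("missing well or strain label")
    if time_unit == "min":
        df["time_h"] = df["time_h"] / 60.0

    well_order = list(dict.fromkeys(df["well"]))
    grid = None
    wells: list[WellTrace] = []
    for well_id in well_order:
        sub = df[df["well"] == well_id].sort_values("time_h")
        times = sub["time_h"].to_numpy()
        if np.unique(times).size != times.size:
            raise ShapeError(f"well {well_id!r}: duplicate time points")
        if grid is None:
            grid = _validate_grid(times)
        elif times.size != grid.size or np.max(np.abs(times - grid)) > GRID_ATOL_H:
            raise ShapeError(f"well {well_id!r}: time set differs from first well")
        strains = sub["strain"].unique()
        if strains.size != 1:
            raise ParseError(f"well {well_id!r}: conflicting strain labels {strains!r}")
        wells.append(
            WellTrace(well_id=well_id, strain=strains[0], values=sub["backscatter"].to_numpy())
        )
    if grid is None:
        raise ParseError("file contains no data rows")
    return PlateSeries(times=grid, wells=wells)


def write_plate_long(series: PlateSeries, path, delimiter: str = ",") -> None:
    """Write a :class:`PlateSeries` as long-format delimited text (header included)."""
    series.to_frame().to_csv(path, sep=delimiter, index=False)


def convert_xlsx(path, sheet=0) -> pd.DataFrame:
    """Thin spreadsheet ingestion helper: read one sheet with the canonical
    long-format columns into a DataFrame that `read_plate_long` would accept
    when written back as CSV."""
    df = pd.read_excel(path, sheet_name=sheet)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing required column(s): {', '.join(missing)}")
    return df[list(REQUIRED_COLUMNS)]
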