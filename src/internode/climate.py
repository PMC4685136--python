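"""Daily greenhouse climate series and rank-specific signal windows.

The simulator consumes contiguous daily records of mean PAR
(photosynthetically active radiation, umol m^-2 s^-1, above the canopy)
and mean air temperature (degC).  Each internode perceives its light and
temperature environment through a short window anchored to its appearance:
by default the 4 days starting 6 days before the event, i.e. the inclusive
day range [event-6, event-3].  The means over that window (PAR4d, T4d) are
the organ's effective environmental signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "ClimateSeries",
    "SignalWindow",
    "window_mean",
    "read_climate_csv",
    "write_climate_csv",
]

logger = logging.getLogger(__name__)

_TEMP_MIN = -20.0
_TEMP_MAX = 60.0


@dataclass(frozen=True)
class SignalWindow:
    """Placement of the environmental signal window relative to an event day.

    ``offset_before_event=6, width=4`` (the defaults) select the inclusive
    integer days ``[event-6, event-3]`` — 4 days starting 6 days before
    the internode reaches its maximum growth rate, which under first-order
    elongation coincides with its appearance.
    """

    offset_before_event: int = 6
    width: int = 4

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError(f"window width must be >= 1, got {self.width}")

    def days(self, event_day: int) -> range:
        """Inclusive day range covered by the window for ``event_day``."""
        start = event_day - self.offset_before_event
        return range(start, start + self.width)


class ClimateSeries:
    """Contiguous daily series of mean PAR and mean air temperature.

    Days are plain consecutive integers (day of year or simulation step —
    no calendar semantics).  PAR must be non-negative; temperatures must
    lie within -20..60 degC.
    """

    def __init__(self, day, par, temperature):
        day = np.asarray(day, dtype=int)
        par = np.asarray(par, dtype=float)
        temperature = np.asarray(temperature, dtype=float)
        if day.ndim != 1 or len(day) == 0:
            raise ValueError("climate series must be a non-empty 1-D record set")
        if not (len(day) == len(par) == len(temperature)):
            raise ValueError("day, par and temperature must have equal length")
        gaps = np.flatnonzero(np.diff(day) != 1)
        if gaps.size:
            missing = day[gaps[0]] + 1
            raise ValueError(
                f"day indices must be strictly consecutive; gap after day "
                f"{day[gaps[0]]} (missing day {missing})"
            )
        bad_par = np.flatnonzero(~(par >= 0))
        if bad_par.size:
            raise ValueError(
                f"PAR must be >= 0; day {day[bad_par[0]]} has par={par[bad_par[0]]}"
            )
        bad_t = np.flatnonzero((temperature < _TEMP_MIN) | (temperature > _TEMP_MAX))
        if bad_t.size:
            raise ValueError(
                f"temperature must be within {_TEMP_MIN}..{_TEMP_MAX} degC; "
                f"day {day[bad_t[0]]} has {temperature[bad_t[0]]}"
            )
        self.day = day
        self.par = par
        self.temperature = temperature

    def __len__(self) -> int:
        return len(self.day)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ClimateSeries):
            return NotImplemented
        return (
            np.array_equal(self.day, other.day)
            and np.array_equal(self.par, other.par)
            and np.array_equal(self.temperature, other.temperature)
        )

    @property
    def first_day(self) -> int:
        return int(self.day[0])

    @property
    def last_day(self) -> int:
        return int(self.day[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.day, "par": self.par, "temperature": self.temperature}
        )

    def value(self, variable: str, day: int) -> float:
        """Scalar value of ``variable`` on ``day``."""
        arr = self._variable(variable)
        idx = day - self.first_day
        if not 0 <= idx < len(self):
            raise IndexError(f"day {day} outside series {self.first_day}..{self.last_day}")
        return float(arr[idx])

    def _variable(self, variable: str) -> np.ndarray:
        try:
            return {"par": self.par, "temperature": self.temperature}[variable]
        except KeyError:
            raise ValueError(
                f"unknown variable {variable!r}; expected 'par' or 'temperature'"
            ) from None


def window_mean(
    series: ClimateSeries,
    variable: Literal["par", "temperature"],
    event_day: int,
    window: SignalWindow | None = None,
) -> float:
    """Mean of a climate variable over the signal window before ``event_day``.

    Window days that precede the series start are dropped and the mean is
    taken over the remaining days (the earliest internodes of a simulation
    have windows that predate the climate record).  If no window day falls
    inside the series at all, the value on the first recorded day is used.

    Raises
    ------
    IndexError
        If ``event_day`` lies after the end of the series.
    """
    if window is None:
        window = SignalWindow()
    if event_day > series.last_day:
        raise IndexError(
            f"event day {event_day} is after the series end {series.last_day}"
        )
    arr = series._variable(variable)
    days = window.days(event_day)
    idx = np.array([d - series.first_day for d in days])
    keep = idx[(idx >= 0) & (idx < len(series))]
    if keep.size < len(idx):
        logger.info(
            "signal window for event day %d truncated from %d to %d day(s)",
            event_day,
            len(idx),
            keep.size,
        )
    if keep.size == 0:
        return float(arr[0])
    return float(arr[keep].mean())


def read_climate_csv(path: str | Path) -> ClimateSeries:
    """Read a ``day,par,temperature`` CSV into a validated :class:`ClimateSeries`.

    Lines starting with ``#`` are treated as metadata comments.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = ["day", "par", "temperature"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; header must be day,par,temperature")
    try:
        return ClimateSeries(df["day"], df["par"], df["temperature"])
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_climate_csv(series: ClimateSeries, path: str | Path) -> None:
    """Write a climate series as a ``day,par,temperature`` CSV (round-trip safe)."""
    # pandas' default float repr is shortest-round-trip, i.e. lossless
    series.to_frame().to_csv(path, index=False)
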