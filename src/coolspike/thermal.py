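"""Accumulated cooling temperature (ACT) in degree-hours.

*Phalaenopsis* spiking is induced by moving plants from a warm vegetative
room into a cooler induction room.  The thermal dose is measured as the
accumulated cooling temperature: the day and night set-point differentials
between the vegetative reference and the cooling room, weighted by the
hours spent at each, summed over days in the cooling room::

    ACT     = sum_d (T_vd - T_cd) * H_d  +  sum_d (T_vn - T_cn) * H_n
    Day-ACT = sum_d (T_vd - T_cd) * H_d

Temperatures in degrees Celsius, durations in hours, ACT in °C·h.  A cooling
temperature at or above its vegetative counterpart contributes nothing: each
term is clamped at zero independently, so warm excursions never accumulate a
negative dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureRegime",
    "TemperatureLog",
    "ACTSeries",
    "DayNightWindow",
    "daily_act",
    "daily_day_act",
    "accumulate_regime",
    "accumulate_log",
]

_TEMP_MIN, _TEMP_MAX = 0.0, 45.0


@dataclass(frozen=True)
class TemperatureRegime:
    """A six-number day/night thermal environment.

    Parameters
    ----------
    t_vd, t_vn : float
        Vegetative-stage day and night set-points (°C).  These are the
        reference temperatures the plant is adapted to before cooling.
    t_cd, t_cn : float
        Cooling-room day and night set-points (°C).
    h_d, h_n : float
        Day (photoperiod) and night lengths in hours; must sum to 24.
    """

    t_vd: float
    t_vn: float
    t_cd: float
    t_cn: float
    h_d: float = 14.0
    h_n: float = 10.0

    def __post_init__(self) -> None:
        if not (self.h_d > 0 and self.h_n >= 0):
            raise ValueError(f"day length must be > 0 and night length >= 0, got H_d={self.h_d}, H_n={self.h_n}")
        if abs(self.h_d + self.h_n - 24.0) > 1e-9:
            raise ValueError(f"H_d + H_n must equal 24 h, got {self.h_d + self.h_n}")
        for name in ("t_vd", "t_vn", "t_cd", "t_cn"):
            t = getattr(self, name)
            if not np.isfinite(t) or not (_TEMP_MIN <= t <= _TEMP_MAX):
                raise ValueError(f"{name}={t!r} outside the plausible window [{_TEMP_MIN}, {_TEMP_MAX}] °C")


@dataclass(frozen=True)
class DayNightWindow:
    """Clock window classifying hourly samples as day or night.

    ``lights_on`` is the hour-of-day (0-24) when the photoperiod starts and
    ``hours`` its duration.  The window may wrap midnight.
    """

    lights_on: float = 8.0
    hours: float = 14.0

    def __post_init__(self) -> None:
        if not (0 <= self.lights_on < 24):
            raise ValueError(f"lights_on must lie in [0, 24), got {self.lights_on}")
        if not (0 < self.hours < 24):
            raise ValueError(f"photoperiod must lie in (0, 24) h, got {self.hours}")

    def is_day(self, hour_of_day: np.ndarray) -> np.ndarray:
        end = (self.lights_on + self.hours) % 24.0
        h = np.asarray(hour_of_day, dtype=float) % 24.0
        if self.lights_on + self.hours <= 24.0:
            return (h >= self.lights_on) & (h < self.lights_on + self.hours)
        return (h >= self.lights_on) | (h < end)


@dataclass
class ACTSeries:
    """Per-day increments and the running ACT total, both in °C·h."""

    day: np.ndarray
    increment: np.ndarray
    cumulative: np.ndarray

    def __post_init__(self) -> None:
        self.day = np.asarray(self.day, dtype=int)
        self.increment = np.asarray(self.increment, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if np.any(np.diff(self.cumulative) < -1e-9):
            raise ValueError("cumulative ACT must be monotone nondecreasing")
        if not np.allclose(self.cumulative, np.cumsum(self.increment), atol=1e-9):
            raise ValueError("cumulative series inconsistent with increments")

    @property
    def total(self) -> float:
        return float(self.cumulative[-1]) if len(self.cumulative) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.day, "increment_c_h": self.increment, "cumulative_c_h": self.cumulative}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _clamped_terms(regime: TemperatureRegime, clamp: bool) -> tuple[float, float]:
    day = (regime.t_vd - regime.t_cd) * regime.h_d
    night = (regime.t_vn - regime.t_cn) * regime.h_n
    if clamp:
        day, night = max(0.0, day), max(0.0, night)
    return day, night


def daily_act(
    regime: TemperatureRegime,
    *,
    clamp: bool = True,
    inhibition_threshold: float | None = None,
) -> float:
    """One day's accumulated cooling temperature (°C·h).

    Day and night differentials are clamped at zero independently, so a
    cooling room warmer than the vegetative reference accumulates nothing
    rather than a negative dose.  ``clamp=False`` exposes the unclamped
    algebraic sum for sensitivity checks.

    ``inhibition_threshold`` optionally zeroes the whole day when the day
    temperature reaches the threshold, mirroring reports that days above
    roughly 28-29 °C actively inhibit spike initiation; off by default.
    """
    if inhibition_threshold is not None and regime.t_vd >= inhibition_threshold:
        return 0.0
    day, night = _clamped_terms(regime, clamp)
    return day + night


def daily_day_act(
    regime: TemperatureRegime,
    *,
    clamp: bool = True,
    inhibition_threshold: float | None = None,
) -> float:
    """One day's day-term-only accumulation (°C·h): ``max(0, T_vd - T_cd) * H_d``."""
    if inhibition_threshold is not None and regime.t_vd >= inhibition_threshold:
        return 0.0
    day, _ = _clamped_terms(regime, clamp)
    return day


def accumulate_regime(
    regime: TemperatureRegime,
    days: int,
    index: str = "full",
    *,
    clamp: bool = True,
    inhibition_threshold: float | None = None,
) -> ACTSeries:
    """ACT series over ``days`` days in the cooling room under fixed set-points.

    ``index`` selects the abscissa: ``"full"`` (day + night terms) or
    ``"day_only"``.  Under constant set-points the increment is constant and
    the cumulative series is linear in the day index.
    """
    if days < 1:
        raise ValueError(f"days must be >= 1, got {days}")
    if index == "full":
        inc = daily_act(regime, clamp=clamp, inhibition_threshold=inhibition_threshold)
    elif index == "day_only":
        inc = daily_day_act(regime, clamp=clamp, inhibition_threshold=inhibition_threshold)
    else:
        raise ValueError(f"index must be 'full' or 'day_only', got {index!r}")
    day = np.arange(1, days + 1)
    increments = np.full(days, inc)
    return ACTSeries(day=day, increment=increments, cumulative=np.cumsum(increments))


class TemperatureLog:
    """Ordered (timestamp, °C) records at a declared sampling interval.

    Greenhouse climate computers log the realized cooling-room temperature;
    this class validates such a log (strictly increasing timestamps, no gap
    wider than twice the declared interval) so accumulation over it is
    well defined.
    """

    def __init__(self, frame: pd.DataFrame, interval_hours: float | None = None):
        if not {"timestamp", "temp_c"} <= set(frame.columns):
            raise ValueError("temperature log needs columns 'timestamp' and 'temp_c'")
        frame = frame.copy()
        frame["timestamp"] = pd.to_datetime(frame["timestamp"])
        frame["temp_c"] = pd.to_numeric(frame["temp_c"])
        deltas = frame["timestamp"].diff().dropna().dt.total_seconds() / 3600.0
        if len(deltas) and (deltas <= 0).any():
            bad = frame["timestamp"].iloc[int(np.argmax(deltas.to_numpy() <= 0)) + 1]
            raise ValueError(f"timestamps must be strictly increasing; violation at {bad}")
        if interval_hours is None:
            if not len(deltas):
                raise ValueError("cannot infer sampling interval from a single record")
            interval_hours = float(deltas.median())
        gaps = deltas[deltas > 2.0 * interval_hours]
        if len(gaps):
            first = frame["timestamp"].iloc[gaps.index[0] - 1]
            raise ValueError(
                f"gap of {gaps.iloc[0]:.2f} h in log after {first} exceeds twice the "
                f"{interval_hours:.2f} h sampling interval"
            )
        self.frame = frame
        self.interval_hours = float(interval_hours)

    @classmethod
    def from_csv(cls, path, interval_hours: float | None = None) -> "TemperatureLog":
        return cls(pd.read_csv(path), interval_hours=interval_hours)

    def __len__(self) -> int:
        return len(self.frame)


def accumulate_log(
    log: TemperatureLog,
    vegetative_reference: tuple[float, float],
    window: DayNightWindow = DayNightWindow(),
    *,
    clamp: bool = True,
) -> ACTSeries:
    """ACT series from an hourly cooling-room log.

    Each sample contributes ``max(0, T_ref - T_sample) * interval_hours``
    where the reference is the vegetative day or night set-point according
    to the sample's clock-window classification.  On a square-wave log that
    exactly matches a set-point regime this reproduces
    :func:`accumulate_regime`.
    """
    t_vd, t_vn = vegetative_reference
    ts = log.frame["timestamp"]
    temps = log.frame["temp_c"].to_numpy(dtype=float)
    hours = ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
    is_day = window.is_day(hours.to_numpy())
    ref = np.where(is_day, t_vd, t_vn)
    contrib = (ref - temps) * log.interval_hours
    if clamp:
        contrib = np.maximum(0.0, contrib)
    by_day = pd.Series(contrib).groupby(ts.dt.normalize().to_numpy()).sum()
    increments = by_day.to_numpy()
    return ACTSeries(
        day=np.arange(1, len(increments) + 1),
        increment=increments,
        cumulative=np.cumsum(increments),
    )
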