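"""Cooling-room scheduling: target spike percentage -> required cooling days.

Inverts the fitted induction sigmoid to the required accumulated cooling
dose and divides by a regime's daily increment, rounding up to whole days
(plants are moved in and out of the cooling room daily).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .model import SigmoidParams, inverse, predict
from .thermal import TemperatureRegime, daily_act

__all__ = ["SchedulePlan", "required_act", "days_to_target"]


def required_act(params: SigmoidParams, target: float) -> float:
    """ACT (°C·h) required to reach ``target`` percent spiking, clamped at 0.

    A target already met at move-in (below the day-zero prediction
    ``Ymax/(1+B)``) needs no cooling and returns 0.
    """
    if not (0 < target < params.ymax):
        raise ValueError(
            f"target {target}% is unreachable: the fitted plateau is Ymax = {params.ymax:.4f}%"
        )
    return max(0.0, inverse(params, target))


@dataclass
class SchedulePlan:
    """A whole-day cooling plan for one regime and one target percentage."""

    target_pct: float
    required_act_c_h: float
    daily_increment_c_h: float
    days: int
    trajectory: list[float] = field(default_factory=list)  # predicted % after day 1..days

    def to_dict(self) -> dict:
        return {
            "target_pct": self.target_pct,
            "required_act_c_h": self.required_act_c_h,
            "daily_increment_c_h": self.daily_increment_c_h,
            "days": self.days,
            "trajectory_pct": self.trajectory,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def table(self) -> str:
        lines = [
            f"target: {self.target_pct}%   required ACT: {self.required_act_c_h:.1f} °C·h",
            f"daily increment: {self.daily_increment_c_h:.1f} °C·h/day   days in cooling room: {self.days}",
            f"{'day':>4}{'ACT (°C·h)':>14}{'predicted %':>14}",
        ]
        for d, y in enumerate(self.trajectory, start=1):
            lines.append(f"{d:>4}{d * self.daily_increment_c_h:>14.1f}{y:>14.2f}")
        return "\n".join(lines)


def days_to_target(
    params: SigmoidParams,
    regime: TemperatureRegime,
    target: float,
) -> SchedulePlan:
    """Whole days of cooling needed for ``target`` percent spiking.

    ``days = ceil(required_act / daily_act)``, so the plan's final day is the
    first on which the predicted percentage meets or exceeds the target.
    """
    inc = daily_act(regime)
    if inc <= 0:
        raise ValueError(
            "regime accumulates no cooling (daily ACT increment is 0); "
            "the target can never be reached"
        )
    need = required_act(params, target)
    days = math.ceil(need / inc) if need > 0 else 0
    traj = [float(predict(params, d * inc)) for d in range(1, days + 1)]
    return SchedulePlan(
        target_pct=float(target),
        required_act_c_h=float(need),
        daily_increment_c_h=float(inc),
        days=int(days),
        trajectory=traj,
    )
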