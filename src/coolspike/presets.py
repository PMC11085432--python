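"""Published parameter sets and experimental regimes used as fixtures.

The three sigmoid parameter triples are the fitted induction curves reported
for (i) the four-variety greenhouse trial, (ii) the pooled literature data,
and (iii) the grand pool of both.  The regimes are the vegetative day/night
set-points of the four commercial varieties together with the shared
22/19 °C cooling room at a 14 h photoperiod.
"""

from __future__ import annotations

from .model import SigmoidParams
from .thermal import TemperatureRegime

# Fitted (Ymax, B, K) of the cool-induction sigmoid Y = Ymax / (1 + B e^(-ACT/K))
FOUR_VARIETY_PARAMS = SigmoidParams(ymax=99.2781, b=38.585, k=662.397)
LITERATURE_PARAMS = SigmoidParams(ymax=98.9971, b=169.87, k=534.504)
POOLED_PARAMS = SigmoidParams(ymax=99.31181, b=83.4511, k=594.1813)

COOLING_DAY_C = 22.0
COOLING_NIGHT_C = 19.0
PHOTOPERIOD_H = 14.0
NIGHT_H = 24.0 - PHOTOPERIOD_H

# Vegetative day/night set-points by variety
VEGETATIVE_SETPOINTS: dict[str, tuple[float, float]] = {
    "KHM1431": (32.0, 24.0),
    "KHM1220": (27.0, 23.0),
    "SogoF1691": (26.0, 23.0),
    "SogoF2032": (26.0, 23.0),
}


def study_regime(variety: str) -> TemperatureRegime:
    """The trial regime for one of the four varieties: its vegetative
    set-points against the shared cooling room."""
    try:
        t_vd, t_vn = VEGETATIVE_SETPOINTS[variety]
    except KeyError:
        raise KeyError(
            f"unknown variety {variety!r}; known: {sorted(VEGETATIVE_SETPOINTS)}"
        ) from None
    return TemperatureRegime(
        t_vd=t_vd,
        t_vn=t_vn,
        t_cd=COOLING_DAY_C,
        t_cn=COOLING_NIGHT_C,
        h_d=PHOTOPERIOD_H,
        h_n=NIGHT_H,
    )
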