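"""Per-plant cohort simulation of cool-induced spiking.

The greenhouse trial this package models scored cohorts of 1000 plants per
variety for spike emergence while they accumulated cooling degree-hours; the
raw per-plant records are not published, so this module generates cohorts
with the same statistical structure for testing and calibration.

Noise models
------------
``plant_threshold`` (default)
    Each plant draws a latent induction threshold u ~ Uniform(0, 1) once and
    is counted as spiked on every scoring day where the model probability
    has reached it.  Spiking is irreversible, so counts are cumulative and
    monotone in time, and the ever-spiking fraction converges to Ymax/100.
``binomial``
    Independent Binomial(n, p_day) per scoring day — not cumulative; kept
    for variance calibration.
``none``
    Exact model values, no noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import SigmoidParams, predict
from .presets import LITERATURE_PARAMS, POOLED_PARAMS, VEGETATIVE_SETPOINTS, study_regime
from .thermal import TemperatureRegime, daily_act, daily_day_act

__all__ = ["CohortSpec", "generate_cohort", "generate_study_fixtures", "DEFAULT_OBSERVATION_DAYS"]

# scoring cadence used throughout: every 2 days to day 40
DEFAULT_OBSERVATION_DAYS: tuple[int, ...] = tuple(range(2, 41, 2))

_NOISE_MODELS = ("none", "binomial", "plant_threshold")


@dataclass(frozen=True)
class CohortSpec:
    """Specification for one simulated variety cohort."""

    variety: str
    regime: TemperatureRegime
    true_params: SigmoidParams
    n_plants: int = 1000
    observation_days: tuple[int, ...] = DEFAULT_OBSERVATION_DAYS
    noise: str = "plant_threshold"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_plants < 1:
            raise ValueError(f"n_plants must be >= 1, got {self.n_plants}")
        days = tuple(self.observation_days)
        if not days or any(b <= a for a, b in zip(days, days[1:])) or days[0] < 1:
            raise ValueError("observation_days must be a strictly increasing sequence of days >= 1")
        if self.noise not in _NOISE_MODELS:
            raise ValueError(f"noise must be one of {_NOISE_MODELS}, got {self.noise!r}")
        object.__setattr__(self, "observation_days", days)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate one cohort; returns an observation table.

    Columns: ``group``, ``day``, ``act_c_h``, ``day_act_c_h``,
    ``pct_spiked``, ``n_plants``.  A fixed seed reproduces the table
    bit for bit.
    """
    days = np.asarray(spec.observation_days, dtype=int)
    act = days * daily_act(spec.regime)
    day_act = days * daily_day_act(spec.regime)
    p = np.asarray(predict(spec.true_params, act), dtype=float) / 100.0

    if spec.noise == "none":
        pct = 100.0 * p
    elif spec.noise == "plant_threshold":
        rng = np.random.default_rng(spec.seed)
        u = rng.uniform(size=spec.n_plants)
        # plant spiked by day d iff its latent threshold has been passed;
        # p is increasing in d so counts are automatically cumulative
        counts = (p[:, None] >= u[None, :]).sum(axis=1)
        pct = 100.0 * counts / spec.n_plants
    else:  # binomial
        rng = np.random.default_rng(spec.seed)
        counts = rng.binomial(spec.n_plants, p)
        pct = 100.0 * counts / spec.n_plants

    return pd.DataFrame(
        {
            "group": spec.variety,
            "day": days,
            "act_c_h": act,
            "day_act_c_h": day_act,
            "pct_spiked": pct,
            "n_plants": spec.n_plants,
        }
    )


def generate_study_fixtures(
    seed: int,
    noise: str = "plant_threshold",
    n_plants: int = 1000,
    true_params: SigmoidParams = POOLED_PARAMS,
) -> dict[str, pd.DataFrame]:
    """Simulated stand-ins for the trial's cohorts plus a literature-like set.

    Four variety cohorts under their vegetative regimes and the shared
    22/19 °C cooling room, all driven by one true parameter set (the trial
    found the four varieties to share a common curve in full ACT), plus a
    ``literature`` cohort generated from the pooled-literature parameters at
    a 110 °C·h/day increment.  Pure function of ``(seed, noise, n_plants)``.
    """
    child_seeds = np.random.SeedSequence(seed).generate_state(len(VEGETATIVE_SETPOINTS) + 1)
    fixtures: dict[str, pd.DataFrame] = {}
    for child, variety in zip(child_seeds, VEGETATIVE_SETPOINTS):
        spec = CohortSpec(
            variety=variety,
            regime=study_regime(variety),
            true_params=true_params,
            n_plants=n_plants,
            noise=noise,
            seed=int(child),
        )
        fixtures[variety] = generate_cohort(spec)
    lit_regime = study_regime("KHM1220")  # 110 °C·h/day stand-in increment
    fixtures["literature"] = generate_cohort(
        CohortSpec(
            variety="literature",
            regime=lit_regime,
            true_params=LITERATURE_PARAMS,
            n_plants=n_plants,
            noise=noise,
            seed=int(child_seeds[-1]),
        )
    )
    return fixtures
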