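"""Three-parameter sigmoid model of cool-induced inflorescence formation.

The fraction of a cohort that has initiated a flower spike after receiving an
accumulated cooling dose ``ACT`` (°C·h) is modelled as

    Y(ACT) = Ymax / (1 + B * exp(-ACT / K))

with ``Ymax`` the plateau percentage, ``K`` the ACT scale (°C·h) and ``B`` a
dimensionless offset fixing the starting point ``Y(0) = Ymax / (1 + B)``.
The curve is strictly increasing in ACT, reaches half its plateau at
``ACT = K ln B``, and is estimated from cohort observations by unweighted
nonlinear least squares on the percentage scale.

Usage follows the model/results pattern::

    model = InflorescenceModel.from_dataframe(obs)
    res = model.fit()
    print(res.summary())
    res.params.k, res.r_squared, res.s
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "SigmoidParams",
    "predict",
    "inverse",
    "fit_statistics",
    "goodness_of_fit",
    "InflorescenceModel",
    "InflorescenceFit",
    "IndexComparison",
    "compare_indices",
]

N_PARAMS = 3
YMAX_BOUND = 200.0  # optimisation bound; biologically Ymax <= 100, see fit()


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters (Ymax, B, K) of the induction sigmoid.

    ymax : plateau inflorescence-formation percentage, in (0, 200]
           (values above 100 are admitted so a boundary-attracted fit is
           visible rather than censored; a warning is issued on fit).
    b    : dimensionless shape/offset, > 0.
    k    : accumulated-cooling-temperature scale in °C·h, > 0.
    """

    ymax: float
    b: float
    k: float

    def __post_init__(self) -> None:
        if not (0 < self.ymax <= YMAX_BOUND):
            raise ValueError(f"ymax must lie in (0, {YMAX_BOUND}], got {self.ymax}")
        if not self.b > 0:
            raise ValueError(f"b must be > 0, got {self.b}")
        if not self.k > 0:
            raise ValueError(f"k must be > 0, got {self.k}")

    def as_array(self) -> np.ndarray:
        return np.array([self.ymax, self.b, self.k], dtype=float)

    @property
    def midpoint_act(self) -> float:
        """ACT at which the curve reaches Ymax/2: K ln B."""
        return self.k * float(np.log(self.b))


def predict(params: SigmoidParams, act):
    """Predicted inflorescence-formation percentage at dose ``act`` (°C·h)."""
    act = np.asarray(act, dtype=float)
    out = params.ymax / (1.0 + params.b * np.exp(-act / params.k))
    return float(out) if out.ndim == 0 else out


def inverse(params: SigmoidParams, y_target):
    """ACT (°C·h) at which the curve reaches ``y_target`` percent.

    Closed form: ``ACT = -K ln[(Ymax/Y - 1)/B]``.  The result is negative
    when the target lies below the day-zero prediction ``Ymax/(1+B)``.

    Raises
    ------
    ValueError
        If ``y_target`` is outside the attainable open interval (0, Ymax).
    """
    y = np.asarray(y_target, dtype=float)
    if np.any(y <= 0) or np.any(y >= params.ymax):
        raise ValueError(
            f"target percentage must lie strictly inside (0, {params.ymax}); got {y_target}"
        )
    out = -params.k * np.log((params.ymax / y - 1.0) / params.b)
    return float(out) if out.ndim == 0 else out


def fit_statistics(y_obs, y_fit, n_params: int = N_PARAMS) -> tuple[float, float]:
    """(R², s) of a fitted curve against observations.

    R² = 1 - SS_res/SS_tot with SS_tot taken about the mean of the
    observations (the convention nonlinear-regression packages print even
    though R² lacks its linear-model interpretation here); s is the residual
    standard error sqrt(SS_res / (n - p)).  A constant response has
    SS_tot = 0 and R² is returned as NaN while s is still computed.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_fit = np.asarray(y_fit, dtype=float)
    resid = y_obs - y_fit
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
    n = len(y_obs)
    if n <= n_params:
        raise ValueError(f"need more than {n_params} observations, got {n}")
    s = float(np.sqrt(ss_res / (n - n_params)))
    r2 = np.nan if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return r2, s


def goodness_of_fit(obs: pd.DataFrame, params: SigmoidParams) -> tuple[float, float]:
    """(R², s) of ``params`` against an observation table
    (columns ``act_c_h``, ``pct_spiked``)."""
    act = obs["act_c_h"].to_numpy(dtype=float)
    y = obs["pct_spiked"].to_numpy(dtype=float)
    return fit_statistics(y, predict(params, act))


def _default_start(act: np.ndarray, y: np.ndarray) -> SigmoidParams:
    # Moment-style start in the model's own geometry: plateau slightly above
    # the largest observation, scale from the dose span, offset from the
    # response at the smallest dose.
    ymax0 = min(100.0, 1.05 * float(np.max(y)))
    ymax0 = max(ymax0, 1.0)
    k0 = max((float(np.max(act)) - float(np.min(act))) / 4.0, 1.0)
    y_at_min = float(y[np.argmin(act)])
    b0 = float(np.clip(ymax0 / max(y_at_min, 0.5) - 1.0, 1.0, 500.0))
    return SigmoidParams(ymax=ymax0, b=b0, k=k0)


class InflorescenceModel:
    """Cool-induction sigmoid bound to an observation table.

    Parameters
    ----------
    act : array-like
        Accumulated cooling temperature per observation, °C·h, all >= 0.
    pct : array-like
        Observed inflorescence-formation percentage, in [0, 100].
    n_plants : array-like, optional
        Cohort sizes (kept for provenance; the estimator is unweighted
        unless explicit weights are passed to :meth:`fit`).
    groups : array-like, optional
        Variety / data-source labels.
    """

    def __init__(self, act, pct, n_plants=None, groups=None):
        act = np.asarray(act, dtype=float)
        pct = np.asarray(pct, dtype=float)
        if act.shape != pct.shape or act.ndim != 1:
            raise ValueError("act and pct must be one-dimensional and the same length")
        if len(act) < N_PARAMS + 1:
            raise ValueError(
                f"need at least {N_PARAMS + 1} observations to fit {N_PARAMS} parameters, got {len(act)}"
            )
        if np.all(act == act[0]):
            raise ValueError("all ACT values are equal; the dose-response curve is unidentifiable")
        if np.any(act < 0):
            raise ValueError("ACT values must be nonnegative")
        if np.any((pct < 0) | (pct > 100)):
            raise ValueError("percentages must lie in [0, 100]")
        self.act = act
        self.pct = pct
        self.n_plants = None if n_plants is None else np.asarray(n_plants)
        self.groups = None if groups is None else np.asarray(groups)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        act_col: str = "act_c_h",
        pct_col: str = "pct_spiked",
        n_col: str = "n_plants",
        group_col: str = "group",
    ) -> "InflorescenceModel":
        return cls(
            frame[act_col],
            frame[pct_col],
            n_plants=frame[n_col] if n_col in frame else None,
            groups=frame[group_col] if group_col in frame else None,
        )

    def fit(
        self,
        start: SigmoidParams | None = None,
        weights=None,
        max_nfev: int = 2000,
    ) -> "InflorescenceFit":
        """Unweighted (or weighted) least squares on the percentage scale.

        Trust-region reflective minimisation with the analytic Jacobian and
        box constraints Ymax ∈ (0, 200], B > 0, K > 0.  The Ymax bound sits
        deliberately above 100 so that a plateau pushed past 100 shows up as
        such (with a warning) instead of silently converging onto the
        biological bound.
        """
        act, y = self.act, self.pct
        if start is None:
            start = _default_start(act, y)
        w = np.ones_like(y) if weights is None else np.sqrt(np.asarray(weights, dtype=float))

        def residual(theta):
            ymax, b, k = theta
            return w * (ymax / (1.0 + b * np.exp(-act / k)) - y)

        def jac(theta):
            ymax, b, k = theta
            e = np.exp(-act / k)
            denom = 1.0 + b * e
            d_ymax = 1.0 / denom
            d_b = -ymax * e / denom**2
            d_k = -ymax * b * e * act / (k**2 * denom**2)
            return (w[:, None]) * np.column_stack([d_ymax, d_b, d_k])

        sol = least_squares(
            residual,
            start.as_array(),
            jac=jac,
            bounds=([1e-8, 1e-8, 1e-8], [YMAX_BOUND, np.inf, np.inf]),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=max_nfev,
        )
        params = SigmoidParams(ymax=sol.x[0], b=sol.x[1], k=sol.x[2])
        fitted = predict(params, act)
        r2, s = fit_statistics(y, fitted)
        # parameter covariance s^2 (J'J)^-1 from the unweighted Jacobian
        J = jac(sol.x)
        try:
            cov = s**2 * np.linalg.inv(J.T @ J)
            bse = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            cov = np.full((3, 3), np.nan)
            bse = np.full(3, np.nan)
        if params.ymax > 100.0:
            warnings.warn(
                f"fitted plateau Ymax = {params.ymax:.3f}% exceeds 100%; the data may not "
                "constrain the asymptote",
                stacklevel=2,
            )
        return InflorescenceFit(
            model=self,
            params=params,
            r_squared=r2,
            s=s,
            residuals=y - fitted,
            n=len(y),
            converged=bool(sol.success),
            n_evaluations=int(sol.nfev),
            bse=bse,
            cov_params=cov,
            message=str(sol.message),
        )


@dataclass
class InflorescenceFit:
    """Results of fitting the induction sigmoid to one observation table."""

    model: InflorescenceModel
    params: SigmoidParams
    r_squared: float
    s: float
    residuals: np.ndarray
    n: int
    converged: bool
    n_evaluations: int
    bse: np.ndarray
    cov_params: np.ndarray
    message: str = ""

    def predict(self, act):
        return predict(self.params, act)

    def inverse(self, y_target):
        return inverse(self.params, y_target)

    def summary(self) -> str:
        p, se = self.params, self.bse
        lines = [
            "Cool-induction sigmoid fit:  Y = Ymax / (1 + B exp(-ACT/K))",
            "-" * 62,
            f"{'param':<8}{'estimate':>14}{'std err':>14}",
            f"{'Ymax':<8}{p.ymax:>14.5f}{se[0]:>14.5f}",
            f"{'B':<8}{p.b:>14.5f}{se[1]:>14.5f}",
            f"{'K':<8}{p.k:>14.5f}{se[2]:>14.5f}",
            "-" * 62,
            f"n = {self.n}    R² = {self.r_squared:.4f}    s = {self.s:.4f} %",
            f"converged = {self.converged}    function evaluations = {self.n_evaluations}",
            "R² about the mean of Y_obs; s = sqrt(SS_res / (n - 3)).",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": {"ymax": self.params.ymax, "b": self.params.b, "k": self.params.k},
            "bse": {"ymax": float(self.bse[0]), "b": float(self.bse[1]), "k": float(self.bse[2])},
            "r_squared": None if np.isnan(self.r_squared) else float(self.r_squared),
            "s": float(self.s),
            "n": int(self.n),
            "converged": self.converged,
            "n_evaluations": self.n_evaluations,
            "residuals": [float(r) for r in self.residuals],
            "definitions": {
                "model": "Y = Ymax / (1 + B * exp(-ACT/K)); ACT in degree-hours (°C·h)",
                "r_squared": "1 - SS_res/SS_tot, SS_tot about the mean of Y_obs",
                "s": "sqrt(SS_res / (n - 3)), percent",
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def plot(self, ax=None):
        """Observations with the fitted curve overlaid; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        act = self.model.act
        grid = np.linspace(0.0, float(act.max()) * 1.05 if act.max() > 0 else 1.0, 200)
        ax.scatter(act, self.model.pct, s=12, label="observed")
        ax.plot(grid, self.predict(grid), color="C1", label="fitted sigmoid")
        ax.set_xlabel("accumulated cooling temperature (°C·h)")
        ax.set_ylabel("inflorescence formation (%)")
        ax.legend()
        return ax


@dataclass
class IndexComparison:
    """Pooled fits of the same cohorts on two thermal-dose abscissas."""

    full_fit: InflorescenceFit
    day_fit: InflorescenceFit
    group_spread_full: dict[str, float]
    group_spread_day: dict[str, float]
    preferred_index: str

    def summary(self) -> str:
        lines = [
            "Thermal-dose index comparison (pooled across groups)",
            "-" * 62,
            f"{'index':<22}{'R²':>10}{'s (%)':>10}",
            f"{'full ACT (day+night)':<22}{self.full_fit.r_squared:>10.4f}{self.full_fit.s:>10.4f}",
            f"{'Day-ACT (day only)':<22}{self.day_fit.r_squared:>10.4f}{self.day_fit.s:>10.4f}",
            "-" * 62,
            f"preferred index (smaller pooled s): {self.preferred_index}",
            "per-group residual SD about the pooled curve:",
        ]
        for g in self.group_spread_full:
            lines.append(
                f"  {g:<14} full {self.group_spread_full[g]:>8.3f}   day-only {self.group_spread_day[g]:>8.3f}"
            )
        return "\n".join(lines)


def compare_indices(
    frame: pd.DataFrame,
    full_col: str = "act_c_h",
    day_col: str = "day_act_c_h",
) -> IndexComparison:
    """Does the day+night dose or the day-only dose pool the cohorts better?

    Expects one table carrying both abscissas (columns ``act_c_h`` and
    ``day_act_c_h``) plus ``group`` and ``pct_spiked``.  One pooled sigmoid
    is fitted per index; the index with the smaller pooled residual standard
    error is flagged, and the per-group residual spread about each pooled
    curve is reported.
    """
    if "group" not in frame.columns:
        frame = frame.assign(group="pooled")
    fits = {}
    spreads = {}
    for label, col in (("full", full_col), ("day_only", day_col)):
        try:
            model = InflorescenceModel(
                frame[col].to_numpy(float),
                frame["pct_spiked"].to_numpy(float),
                groups=frame["group"].to_numpy(),
            )
            fits[label] = model.fit()
        except Exception as err:
            raise RuntimeError(f"pooled fit on index {label!r} failed: {err}") from err
        resid = pd.Series(fits[label].residuals, index=frame.index)
        spreads[label] = {
            str(g): float(resid[frame["group"] == g].std(ddof=0))
            for g in pd.unique(frame["group"])
        }
    preferred = "full" if fits["full"].s <= fits["day_only"].s else "day_only"
    return IndexComparison(
        full_fit=fits["full"],
        day_fit=fits["day_only"],
        group_spread_full=spreads["full"],
        group_spread_day=spreads["day_only"],
        preferred_index=preferred,
    )
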