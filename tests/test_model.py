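"""Sigmoid dose-response model: prediction, inversion, estimation, fit stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq, curve_fit

from coolspike import (
    FOUR_VARIETY_PARAMS,
    POOLED_PARAMS,
    InflorescenceModel,
    SigmoidParams,
    goodness_of_fit,
    inverse,
    predict,
)
from coolspike.model import fit_statistics

params_strategy = st.builds(
    SigmoidParams,
    ymax=st.floats(min_value=10.0, max_value=100.0),
    b=st.floats(min_value=0.5, max_value=500.0),
    k=st.floats(min_value=50.0, max_value=2000.0),
)


def test_predict_matches_closed_form_values(pooled_params):
    assert predict(pooled_params, 0.0) == pytest.approx(
        pooled_params.ymax / (1 + pooled_params.b), rel=1e-12
    )
    assert predict(pooled_params, 0.0) == pytest.approx(1.1760, abs=1e-4)
    assert predict(pooled_params, 1e7) == pytest.approx(pooled_params.ymax, rel=1e-9)


@given(params=params_strategy)
def test_curve_reaches_half_plateau_at_k_log_b(params):
    assert predict(params, params.midpoint_act) == pytest.approx(params.ymax / 2, rel=1e-9)


@given(params=params_strategy)
def test_predict_increasing_and_bounded(params):
    # dose grid scaled to K so the curve is probed away from float saturation
    act = np.linspace(-2.0, 6.0, 97) * params.k
    y = predict(params, act)
    assert np.all(np.diff(y) > 0)
    assert np.all((y > 0) & (y < params.ymax))


@given(
    params=params_strategy,
    frac=st.floats(min_value=1e-6, max_value=1 - 1e-6),
)
def test_forward_inverse_round_trip(params, frac):
    y = params.ymax * frac
    act = inverse(params, y)
    assert predict(params, act) == pytest.approx(y, abs=1e-9)


@pytest.mark.parametrize("act", [0.0, 500.0, 2000.0])
def test_inverse_of_predict_is_identity(pooled_params, act):
    assert inverse(pooled_params, predict(pooled_params, act)) == pytest.approx(act, abs=1e-9)


def test_inverse_agrees_with_bisection_oracle(pooled_params):
    closed = inverse(pooled_params, pooled_params.ymax / 2)
    bisected = brentq(lambda a: predict(pooled_params, a) - pooled_params.ymax / 2, 0, 1e5)
    assert closed == pytest.approx(bisected, abs=1e-6)
    assert closed == pytest.approx(2628.8, abs=0.1)


@pytest.mark.parametrize("target", [0.0, -5.0, 100.0, 99.31181])
def test_inverse_rejects_unattainable_targets(pooled_params, target):
    with pytest.raises(ValueError, match="attainable|inside"):
        inverse(pooled_params, target)


@pytest.mark.parametrize(
    "kwargs",
    [dict(ymax=0.0, b=1.0, k=1.0), dict(ymax=50.0, b=0.0, k=1.0), dict(ymax=50.0, b=1.0, k=-2.0), dict(ymax=250.0, b=1.0, k=1.0)],
)
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ValueError):
        SigmoidParams(**kwargs)


@pytest.mark.parametrize(
    "truth", [POOLED_PARAMS, FOUR_VARIETY_PARAMS, SigmoidParams(ymax=50.0, b=10.0, k=300.0)]
)
def test_noise_free_recovery_to_1e4_relative(truth):
    """Fitting exact model values must return the generating parameters."""
    act = np.arange(0.0, 4001.0, 100.0)
    fit = InflorescenceModel(act, predict(truth, act)).fit()
    for est, true in zip(fit.params.as_array(), truth.as_array()):
        assert abs(est - true) / true < 1e-4
    assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
    assert fit.s == pytest.approx(0.0, abs=1e-8)
    assert fit.converged


@pytest.mark.parametrize(
    "start",
    [
        SigmoidParams(ymax=80.0, b=1.0, k=100.0),
        SigmoidParams(ymax=120.0, b=500.0, k=2000.0),
        SigmoidParams(ymax=100.0, b=10.0, k=500.0),
    ],
)
def test_recovery_from_anywhere_in_the_documented_basin(start):
    act = np.arange(0.0, 4001.0, 100.0)
    fit = InflorescenceModel(act, predict(POOLED_PARAMS, act)).fit(start=start)
    for est, true in zip(fit.params.as_array(), POOLED_PARAMS.as_array()):
        assert abs(est - true) / true < 1e-4


def test_fit_agrees_with_independent_curve_fit_route():
    """Cross-check: scipy.curve_fit on noisy data lands on the same optimum."""
    rng = np.random.default_rng(42)
    act = np.arange(0.0, 4001.0, 200.0)
    y = np.clip(predict(POOLED_PARAMS, act) + rng.normal(0, 2.0, act.size), 0, 100)
    fit = InflorescenceModel(act, y).fit()
    popt, _ = curve_fit(
        lambda a, ymax, b, k: ymax / (1 + b * np.exp(-a / k)),
        act,
        y,
        p0=[100.0, 10.0, 500.0],
        maxfev=10000,
    )
    np.testing.assert_allclose(fit.params.as_array(), popt, rtol=1e-5)


def test_underdetermined_tables_rejected():
    with pytest.raises(ValueError, match="at least 4"):
        InflorescenceModel([0, 100, 200], [1, 2, 3])
    with pytest.raises(ValueError, match="unidentifiable"):
        InflorescenceModel([100, 100, 100, 100], [1, 2, 3, 4])


def test_fit_statistics_hand_table():
    """Five observations with residuals (1,-1,2,-2,0) and SS_tot = 100."""
    y_obs = np.array([55.0, 45.0, 55.0, 45.0, 50.0])  # SS_tot = 25*4 = 100
    y_fit = y_obs - np.array([1.0, -1.0, 2.0, -2.0, 0.0])  # SS_res = 10
    r2, s = fit_statistics(y_obs, y_fit)
    assert r2 == pytest.approx(0.9, abs=1e-12)
    assert s == pytest.approx(np.sqrt(10.0 / 2.0), abs=1e-12)


def test_perfect_fit_and_mean_predictor_edge_cases():
    y = np.array([10.0, 20.0, 30.0, 40.0])
    r2, s = fit_statistics(y, y)
    assert (r2, s) == (1.0, 0.0)
    r2, s = fit_statistics(y, np.full(4, y.mean()))
    assert r2 == pytest.approx(0.0, abs=1e-12)


def test_constant_response_reports_undefined_r2():
    y = np.full(5, 40.0)
    r2, s = fit_statistics(y, y - 1.0)
    assert np.isnan(r2)
    assert s == pytest.approx(np.sqrt(5 / 2))


@given(seed=st.integers(min_value=0, max_value=10_000))
def test_goodness_of_fit_matches_brute_force(seed, pooled_params):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 30))
    obs = pd.DataFrame(
        {
            "act_c_h": rng.uniform(0, 5000, n),
            "pct_spiked": rng.uniform(0, 100, n),
        }
    )
    r2, s = goodness_of_fit(obs, pooled_params)
    fitted = predict(pooled_params, obs["act_c_h"].to_numpy())
    ss_res = sum((yo - yf) ** 2 for yo, yf in zip(obs["pct_spiked"], fitted))
    mean = obs["pct_spiked"].mean()
    ss_tot = sum((yo - mean) ** 2 for yo in obs["pct_spiked"])
    assert abs((1 - ss_res / ss_tot) - r2) < 1e-12
    assert abs(np.sqrt(ss_res / (n - 3)) - s) < 1e-12


def test_fit_warns_when_plateau_exceeds_100():
    # early stretch of a curve whose extrapolated plateau sits at 110%
    act = np.arange(0.0, 2001.0, 100.0)
    y = predict(SigmoidParams(ymax=110.0, b=50.0, k=400.0), act)
    assert y.max() < 100
    with pytest.warns(UserWarning, match="exceeds 100"):
        InflorescenceModel(act, y).fit()


def test_summary_and_json_report_the_estimates(pooled_params):
    act = np.arange(0.0, 4001.0, 100.0)
    fit = InflorescenceModel(act, predict(pooled_params, act)).fit()
    text = fit.summary()
    assert "Ymax" in text and "R²" in text
    payload = fit.to_dict()
    assert payload["params"]["k"] == pytest.approx(pooled_params.k, rel=1e-4)
    assert payload["n"] == 41
    assert len(payload["residuals"]) == 41
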