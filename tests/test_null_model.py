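"""Fitting and diagnosing the size-dependent logitSST null model."""

import math

import numpy as np
import pytest

from methrank.null_model import (
    FitConfig,
    NullModel,
    SizedObservation,
    centile_coverage,
    centile_curves,
    fit_null_model,
    model_aic_bic,
    null_pvalue,
    null_pvalues,
    quantile_residuals,
)
from methrank.simulate import simulate_null_observations

SURFACE = dict(mu=-2.0, sigma=0.55, nu=1.25, tau=6.0)


@pytest.fixture(scope="module")
def fitted():
    obs = simulate_null_observations(SURFACE, 8000, (3, 9), seed=42)
    model = fit_null_model(obs, FitConfig(smoothing="fixed", lambda_init=1e4))
    return obs, model


def test_insufficient_observations_rejected():
    obs = simulate_null_observations(SURFACE, 10, (3, 9), seed=0)
    with pytest.raises(ValueError, match="insufficient observations"):
        fit_null_model(obs)


def test_sized_observation_validation():
    with pytest.raises(ValueError):
        SizedObservation(0.0, 3.0)
    with pytest.raises(ValueError):
        SizedObservation(0.5, -1.0)


def test_pvalue_endpoints_and_quantile_consistency(fitted):
    _, model = fitted
    assert null_pvalue(0.0, 5.0, model) == 1.0
    assert null_pvalue(1.0, 5.0, model) == 0.0
    params = model.params_scalar(5.0)
    from methrank.null_model import logitsst_quantile

    t95 = logitsst_quantile(0.95, params)
    assert null_pvalue(t95, 5.0, model) == pytest.approx(0.05, abs=1e-6)


def test_held_out_pvalues_uniform(fitted):
    _, model = fitted
    held = simulate_null_observations(SURFACE, 4000, (3, 9), seed=43)
    t = np.array([o.t for o in held])
    s = np.array([o.s for o in held])
    from scipy.stats import kstest

    assert kstest(null_pvalues(t, s, model), "uniform").pvalue > 0.01


def test_quantile_residuals_standard_normal_on_model_data(fitted):
    _, model = fitted
    rng = np.random.default_rng(7)
    s = rng.uniform(3, 9, 10000)
    t = model.rvs(rng, s)
    res = quantile_residuals(np.column_stack([t, s]), model)
    assert abs(res.mean()) < 0.05
    assert 0.95 < res.std() < 1.05


def test_quantile_residuals_increase_with_t(fitted):
    _, model = fitted
    t = np.linspace(0.02, 0.9, 50)
    res = quantile_residuals(np.column_stack([t, np.full(50, 5.0)]), model)
    assert np.all(np.diff(res) > 0)


def test_residual_zero_at_conditional_median(fitted):
    _, model = fitted
    t_med = float(model.ppf(0.5, 5.0)[0])
    res = quantile_residuals(np.array([[t_med, 5.0]]), model)
    assert res[0] == pytest.approx(0.0, abs=1e-8)


def test_centile_curves_ordered_and_covering(fitted):
    _, model = fitted
    s_grid = np.linspace(3, 9, 25)
    curves = centile_curves([25, 75], model, s_grid)
    assert np.all(curves[25.0] < curves[75.0])
    with pytest.raises(ValueError):
        centile_curves([0], model, s_grid)

    rng = np.random.default_rng(11)
    s = rng.uniform(3, 9, 20000)
    obs = np.column_stack([model.rvs(rng, s), s])
    assert centile_coverage(50, obs, model) == pytest.approx(50, abs=1.5)
    assert centile_coverage(99.9, obs, model) >= 99


def test_s_clamped_outside_training_range(fitted):
    _, model = fitted
    lo, hi = model.s_range
    assert null_pvalue(0.3, hi + 5.0, model) == pytest.approx(
        null_pvalue(0.3, hi, model), abs=1e-12
    )
    assert null_pvalue(0.3, 0.0, model) == pytest.approx(
        null_pvalue(0.3, lo, model), abs=1e-12
    )


def test_serialization_round_trip(fitted, tmp_path):
    _, model = fitted
    from methrank.io import load_null_model, save_null_model

    path = tmp_path / "model.json"
    save_null_model(model, path)
    loaded = load_null_model(path)
    s = np.linspace(3, 9, 13)
    for key, val in model.params_at(s).items():
        np.testing.assert_allclose(loaded.params_at(s)[key], val, rtol=1e-12)
    assert loaded.edf == pytest.approx(model.edf)


def test_constant_fit_edf_and_aic_bic_identity():
    """An unpenalized constant fit spends exactly one df per parameter."""
    obs = simulate_null_observations(SURFACE, 4000, (3, 9), seed=5)
    model = fit_null_model(obs, FitConfig(basis="constant"))
    aic, bic, edf = model_aic_bic(model, obs)
    assert edf == pytest.approx(4.0, abs=1e-6)
    n = len(obs)
    assert aic - bic == pytest.approx(8 - 4 * math.log(n), abs=1e-8)


def test_stronger_penalty_reduces_edf():
    obs = simulate_null_observations(SURFACE, 4000, (3, 9), seed=6)
    light = fit_null_model(obs, FitConfig(smoothing="fixed", lambda_init=1.0))
    heavy = fit_null_model(obs, FitConfig(smoothing="fixed", lambda_init=1e4))
    assert heavy.edf < light.edf


def test_skewed_data_prefer_sst_over_logitnormal():
    """AIC ranks the generating family above a misspecified logit-normal."""
    skewed = dict(mu=-1.5, sigma=0.6, nu=2.2, tau=4.0)
    obs = simulate_null_observations(skewed, 20000, (3, 9), seed=9)
    cfg = dict(basis="constant")
    sst = fit_null_model(obs, FitConfig(family="logitsst", **cfg))
    lno = fit_null_model(obs, FitConfig(family="logitnormal", **cfg))
    aic_sst, bic_sst, _ = model_aic_bic(sst, obs)
    aic_lno, bic_lno, edf_lno = model_aic_bic(lno, obs)
    assert edf_lno == pytest.approx(2.0, abs=1e-6)
    assert aic_sst < aic_lno
    assert bic_sst < bic_lno
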