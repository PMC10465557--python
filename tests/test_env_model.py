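"""Predictor handling, regression machinery, selection and identifiability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from macrogd import env_model, synthetic


def test_prune_collinear_identical_and_independent(rng):
    x = rng.normal(size=200)
    env = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=200)})
    retained, corr = env_model.prune_collinear(env, priority=["a", "b", "c"])
    assert retained == ["a", "c"]
    env2 = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("wxyz"))
    retained2, _ = env_model.prune_collinear(env2)
    assert retained2 == list("wxyz")


def test_prune_collinear_block_keeps_priority_survivor(rng):
    base = rng.normal(size=500)
    env = pd.DataFrame(
        {
            "first": base + rng.normal(0, 0.2, 500),
            "second": base + rng.normal(0, 0.2, 500),
            "third": base + rng.normal(0, 0.2, 500),
        }
    )
    retained, _ = env_model.prune_collinear(env, priority=["second", "first", "third"])
    assert retained == ["second"]


def test_standardize_against_arithmetic():
    env = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 2.0, 4.0]})
    z, tr = env_model.standardize(env)
    # sample sd convention: {1,2,3} -> {-1, 0, 1}
    assert np.allclose(z["a"], [-1.0, 0.0, 1.0])
    assert np.allclose(tr.inverse(z), env)
    # prediction at the training mean maps to zero
    probe = pd.DataFrame({"a": [2.0], "b": [8.0 / 3.0]})
    assert np.allclose(tr.transform(probe), 0.0)


def test_standardize_zero_variance_names_column():
    env = pd.DataFrame({"ok": [1.0, 2.0], "flat": [5.0, 5.0]})
    with pytest.raises(ValueError, match="flat"):
        env_model.standardize(env)


def test_split_train_test_stratified_counts():
    cells = pd.DataFrame(
        {"continent": ["A"] * 40 + ["B"] * 60}, index=[f"c{i}" for i in range(100)]
    )
    train, test = env_model.split_train_test(cells, seed=0)
    assert len(train) == 75 and len(test) == 25
    assert (cells.loc[train, "continent"] == "A").sum() == 30
    assert (cells.loc[test, "continent"] == "B").sum() == 15
    train2, test2 = env_model.split_train_test(cells, seed=0)
    assert list(train) == list(train2) and list(test) == list(test2)


def test_split_single_cell_stratum_goes_to_train():
    cells = pd.DataFrame({"continent": ["A"] * 8 + ["B"]}, index=range(9))
    with pytest.warns(UserWarning):
        train, test = env_model.split_train_test(cells, seed=1)
    assert 8 in train


@pytest.fixture(scope="module")
def quick_fit():
    w = synthetic.simulate_cell_world(n_cells=100, slopes=(0.4, 0.0), seed=21)
    fit = env_model.fit_spatial_glmm(
        w.y,
        w.X,
        w.coords,
        mcmc=env_model.MCMCConfig(n_steps=700, n_burn=300, n_draws=600, seed=5),
        n_knots=25,
    )
    return w, fit


def test_glmm_recovers_planted_slope(quick_fit):
    w, fit = quick_fit
    med = np.median(fit.beta, axis=0)
    assert abs(med[0] - 0.4) < 0.12
    lo, hi = env_model.hdi(fit.beta[:, 1], 0.95)
    assert lo < 0.0 < hi or abs(med[1]) < 0.05


def test_glmm_r2_and_sigma_sane(quick_fit):
    w, fit = quick_fit
    r2 = env_model.bayesian_r2(fit)
    assert 0.0 <= r2["median"] <= 1.0
    assert r2["hdi_low"] <= r2["median"] <= r2["hdi_high"]
    assert np.median(fit.sigma) < 3 * w.noise_sd + 0.2


def test_predictions_at_training_cells_consistent(quick_fit):
    w, fit = quick_fit
    pred = env_model.predict_cells(
        fit, w.X, w.coords, n_draws=300, seed=2, allow_unconverged=True
    )
    resid = pred["median"].to_numpy() - w.y
    assert np.mean(np.abs(resid)) < 0.5
    assert (pred["hdi_low"] <= pred["median"]).all()
    assert (pred["median"] <= pred["hdi_high"]).all()
    with pytest.raises(ValueError, match="lack predictors"):
        env_model.predict_cells(fit, w.X.rename(columns={"x1": "zz"}), w.coords, allow_unconverged=True)


def test_prior_posterior_overlap_identified_vs_prior(quick_fit):
    """A sharply identified slope overlaps its prior far less than the
    analytic Normal-Normal overlap of a no-data posterior (=100%)."""
    w, fit = quick_fit
    ov = env_model.prior_posterior_overlap(fit)
    # planted slope 0.4 is ~4 prior sd from 0 with a narrow posterior
    assert ov["beta_x1"] < 20.0
    # analytic oracle: overlap of two equal normals is 100%
    prior = stats.norm(0, fit.priors.slope_sd)
    grid = np.linspace(-1, 1, 4001)
    self_overlap = np.trapezoid(np.minimum(prior.pdf(grid), prior.pdf(grid)), grid) * 100
    assert self_overlap == pytest.approx(100.0, abs=0.5)
    # overlap is symmetric in the two densities by construction (min)
    assert all(0.0 <= v <= 100.5 for v in ov.values())


def test_overlap_requires_enough_draws(quick_fit):
    _, fit = quick_fit
    small = type(fit)(**{**fit.__dict__})
    small.intercept = fit.intercept[:100]
    with pytest.raises(ValueError):
        env_model.prior_posterior_overlap(small)


def test_select_variables_finds_planted_predictor():
    w = synthetic.simulate_cell_world(
        n_cells=150, slopes=(0.5, 0, 0, 0, 0, 0, 0, 0, 0), field_sd=0.0, seed=31
    )
    sel, path = env_model.select_variables(w.X, w.y, seed=1)
    assert sel and sel[0] == "x1"
    # duplicated informative predictor: exactly one of the pair selected
    x_dup = w.X.copy()
    x_dup["x1_copy"] = w.X["x1"] + np.random.default_rng(0).normal(0, 1e-6, len(w.X))
    sel2, _ = env_model.select_variables(x_dup, w.y, seed=1)
    assert ("x1" in sel2) ^ ("x1_copy" in sel2)


def test_select_variables_all_noise_selects_nothing_much():
    w = synthetic.simulate_cell_world(
        n_cells=120, slopes=(0, 0, 0, 0, 0), field_sd=0.0, seed=32
    )
    sel, _ = env_model.select_variables(w.X, w.y, seed=2)
    assert len(sel) <= 1


def test_freeze_helpers(rng):
    assert list(env_model.freeze_from_mtcm([-5.0, 0.0, 3.0])) == [True, True, False]
    coords = rng.uniform(0, 1000, (40, 2))
    freeze = coords[:, 0] > 500
    vals = 0.5 + 0.3 * freeze + rng.normal(0, 0.05, 40)
    res = env_model.freeze_test(vals, freeze, coords)
    assert res.r > 0 and res.p < 0.05
    with pytest.raises(ValueError):
        env_model.freeze_test(vals, np.ones(40), coords)
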