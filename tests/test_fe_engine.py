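"""Fixed-effects engine: demeaning, oracle equivalence, inference, errors."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

from conftest import make_users
from mhdid.benchmarks import null_config, simulate_panel
from mhdid.config import CohortWindow, SimConfig, month_range
from mhdid.errors import ConvergenceError, EstimationError
from mhdid.fe import ModelSpec, ddd_terms, demean, fit
from mhdid.panel import build_panel
from mhdid.specs import dd_design, ddd_design
from mhdid.synth import generate_outcomes, generate_users
from oracles import dummy_ols_cluster

MONTHS = month_range("2019-01", "2019-12")


def _exact(spec):
    return dataclasses.replace(spec, demean_tol=1e-13, max_sweeps=5000)


def test_single_dim_demeaning_one_sweep_closed_form():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"g": np.repeat([0, 1, 2], 4), "y": rng.normal(size=12)})
    out, diag = demean(df, ["y"], ["g"])
    assert diag["sweeps"] == 1
    expected = df["y"] - df.groupby("g")["y"].transform("mean")
    np.testing.assert_allclose(out["y"], expected, atol=1e-14)


def test_balanced_two_way_matches_closed_form():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(
        {"i": np.repeat(np.arange(4), 3), "t": np.tile(np.arange(3), 4), "y": rng.normal(size=12)}
    )
    out, _ = demean(df, ["y"], ["i", "t"], tol=1e-13, max_sweeps=1000)
    y = df["y"]
    expected = (
        y
        - df.groupby("i")["y"].transform("mean")
        - df.groupby("t")["y"].transform("mean")
        + y.mean()
    )
    np.testing.assert_allclose(out["y"], expected, atol=1e-12)


def test_column_constant_within_cells_demeaned_to_zero():
    df = pd.DataFrame({"g": [0, 0, 1, 1], "x": [3.0, 3.0, -1.0, -1.0]})
    out, _ = demean(df, ["x"], ["g"])
    np.testing.assert_allclose(out["x"], 0.0, atol=1e-14)


def test_nonconvergence_raises_with_diagnostics():
    rng = np.random.default_rng(2)
    df = pd.DataFrame(
        {"i": np.repeat(np.arange(6), 4), "t": np.tile(np.arange(4), 6), "y": rng.normal(size=24)}
    )
    df = df.iloc[[0, 1, 2, 5, 6, 7, 9, 10, 13, 14, 17, 18, 21, 22, 23]]  # unbalanced
    with pytest.raises(ConvergenceError) as exc:
        demean(df, ["y"], ["i", "t"], tol=0.0, max_sweeps=1)
    assert exc.value.sweeps == 1


def test_null_outcome_gives_zero_coefficients(window=CohortWindow()):
    cfg = SimConfig(
        n_users=40, p_used=0.5, noise_sd=0.0, zero_inflation=0.0,
        true_dynamic_effects={}, exclusion_rates={}, p_multi_category=0.0,
        baseline_log_hours=3.0, seed=11,
    )
    users = generate_users(cfg)
    truth = generate_outcomes(users, cfg)
    panel = build_panel(truth, users, window, MONTHS, outcome="hours")
    # outcome is exactly gamma_i + delta_t: every event coefficient is 0
    design, spec = dd_design(panel, window)
    res = fit(_exact(spec), design)
    np.testing.assert_allclose(res.params, 0.0, atol=1e-8)


def test_small_panel_matches_dummy_ols_and_statsmodels():
    """6 users x 5 months with seeded noise: demeaned estimates and clustered
    SEs equal explicit dummy-variable OLS (and statsmodels) to 1e-8."""
    rng = np.random.default_rng(3)
    n_u, n_t = 6, 5
    df = pd.DataFrame(
        {
            "user_id": np.repeat(np.arange(n_u), n_t),
            "month_idx": np.tile(np.arange(n_t), n_u),
        }
    )
    df["x1"] = rng.normal(size=len(df))
    df["x2"] = rng.normal(size=len(df))
    df["y"] = (
        0.5 * df["x1"] - 0.3 * df["x2"]
        + np.repeat(rng.normal(size=n_u), n_t)
        + np.tile(rng.normal(size=n_t), n_u)
        + 0.2 * rng.normal(size=len(df))
    )
    spec = ModelSpec(
        outcome="y", regressors=("x1", "x2"), fe_dims=("user_id", "month_idx"),
        demean_tol=1e-13, max_sweeps=5000,
    )
    res = fit(spec, df)
    p_o, se_o = dummy_ols_cluster(df, "y", ["x1", "x2"], ["user_id", "month_idx"], "user_id")
    np.testing.assert_allclose(res.params, p_o, atol=1e-8)
    np.testing.assert_allclose(res.se, se_o, atol=1e-8)

    smf = pytest.importorskip("statsmodels.formula.api")
    sm = smf.ols("y ~ x1 + x2 + C(user_id) + C(month_idx)", data=df).fit(
        cov_type="cluster", cov_kwds={"groups": df["user_id"]}
    )
    np.testing.assert_allclose(res.params, sm.params[["x1", "x2"]], atol=1e-8)
    np.testing.assert_allclose(res.se, sm.bse[["x1", "x2"]], atol=1e-8)


def test_frisch_waugh_fe_dim_equals_explicit_dummies():
    rng = np.random.default_rng(4)
    n_u, n_t = 8, 6
    df = pd.DataFrame(
        {"user_id": np.repeat(np.arange(n_u), n_t), "month_idx": np.tile(np.arange(n_t), n_u)}
    )
    df["x"] = rng.normal(size=len(df))
    df["y"] = 0.7 * df["x"] + np.tile(rng.normal(size=n_t), n_u) + rng.normal(size=len(df))
    for t in range(1, n_t):
        df[f"m_{t}"] = (df["month_idx"] == t).astype(float)
    via_fe = fit(
        ModelSpec(outcome="y", regressors=("x",), fe_dims=("user_id", "month_idx"),
                  demean_tol=1e-13, max_sweeps=5000),
        df,
    )
    via_dummies = fit(
        ModelSpec(outcome="y", regressors=("x",) + tuple(f"m_{t}" for t in range(1, n_t)),
                  fe_dims=("user_id",), demean_tol=1e-13, max_sweeps=5000),
        df,
    )
    assert via_fe.params["x"] == pytest.approx(via_dummies.params["x"], abs=1e-9)


def test_duplicate_regressor_name_rejected():
    with pytest.raises(EstimationError):
        ModelSpec(outcome="y", regressors=("x", "x"), fe_dims=("user_id",))


def test_rank_deficiency_names_offending_column():
    rng = np.random.default_rng(5)
    df = pd.DataFrame(
        {"user_id": np.repeat(np.arange(5), 4), "month_idx": np.tile(np.arange(4), 5)}
    )
    df["x1"] = rng.normal(size=len(df))
    df["x1_copy"] = df["x1"]
    df["y"] = rng.normal(size=len(df))
    spec = ModelSpec(outcome="y", regressors=("x1", "x1_copy"), fe_dims=("user_id",))
    with pytest.raises(EstimationError, match="x1"):
        fit(spec, df)


def test_regressor_absorbed_by_fe_rejected():
    df = pd.DataFrame({"user_id": np.repeat(np.arange(4), 3), "y": np.random.default_rng(6).normal(size=12)})
    df["month_idx"] = np.tile(np.arange(3), 4)
    df["cohort"] = (df["user_id"] >= 2).astype(float)  # constant within user
    spec = ModelSpec(outcome="y", regressors=("cohort",), fe_dims=("user_id",))
    with pytest.raises(EstimationError, match="cohort"):
        fit(spec, df)


def test_too_few_clusters_rejected():
    df = pd.DataFrame({"user_id": 0, "month_idx": np.arange(6), "x": np.random.default_rng(7).normal(size=6)})
    df["y"] = df["x"]
    spec = ModelSpec(outcome="y", regressors=("x",), fe_dims=("month_idx",))
    with pytest.raises(EstimationError):
        fit(spec, df)


def test_ddd_terms_zero_for_nonused_and_indicator_for_used():
    users = make_users(4, used_flag=[True, False, True, False])
    grid = pd.MultiIndex.from_product([users["user_id"], MONTHS], names=["user_id", "month"])
    v = pd.DataFrame(index=grid).assign(visit_hours=1).reset_index()
    panel = build_panel(v, users, CohortWindow(), MONTHS)
    terms = ddd_terms(panel, CohortWindow())
    nonused = panel["used"] == 0
    assert (terms.loc[nonused] == 0).all().all()
    used_r2 = (panel["used"] == 1) & (panel["event_time"] == 2)
    assert (terms.loc[used_r2, "ev_p2_x_used"] == 1).all()
    assert (terms.loc[used_r2].drop(columns="ev_p2_x_used") == 0).all().all()


def test_ddd_terms_require_both_subgroups():
    users = make_users(3, used_flag=True)
    grid = pd.MultiIndex.from_product([users["user_id"], MONTHS], names=["user_id", "month"])
    v = pd.DataFrame(index=grid).assign(visit_hours=1).reset_index()
    panel = build_panel(v, users, CohortWindow(), MONTHS)
    with pytest.raises(EstimationError, match="subgroup"):
        ddd_terms(panel, CohortWindow())


def test_vcov_psd_and_ci_shape(small_panel, window):
    design, spec = ddd_design(small_panel, window)
    res = fit(spec, design)
    eigs = np.linalg.eigvalsh(res.vcov.to_numpy())
    assert eigs.min() > -1e-12
    np.testing.assert_allclose(res.ci_high - res.ci_low, 2 * 1.96 * res.se, atol=1e-12)
    assert res.n_clusters <= res.n_obs


def test_ci_coverage_under_null_small_panels():
    """95% CIs cover zero ~95% of the time across 500 null replications."""
    window = CohortWindow()
    cover = []
    for rep in range(500):
        cfg = null_config(seed=40000 + rep, n_users=120)
        design, spec = ddd_design(simulate_panel(cfg, window), window)
        res = fit(spec, design)
        term = "ev_p2_x_used"
        cover.append(res.ci_low[term] <= 0.0 <= res.ci_high[term])
    rate = np.mean(cover)
    assert abs(rate - 0.95) <= 3 * np.sqrt(0.95 * 0.05 / 500)
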