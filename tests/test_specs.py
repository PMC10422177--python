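"""Spec builders: DD/DDD structure, moderation design, pre-trend report."""
import numpy as np
import pandas as pd
import pytest

from mhdid.benchmarks import null_config, simulate_panel
from mhdid.config import CohortWindow, RunConfig, SimConfig
from mhdid.errors import ConfigError, EstimationError
from mhdid.fe import FitResult, ModelSpec, fit
from mhdid.specs import (
    ModerationSpec,
    build_dd,
    build_moderation,
    dd_design,
    ddd_design,
    moderation_design,
    pretrend_report,
)


def test_dd_regressor_count_reported_plus_caps():
    spec = build_dd(CohortWindow(report_leads=2, report_lags=3))
    assert len(spec.regressors) == 5 + 2
    assert set(spec.fe_dims) == {"user_id", "month_idx"}
    assert spec.cluster == "user_id"


def test_model_spec_yaml_round_trip(tmp_path):
    spec = build_dd(CohortWindow())
    path = tmp_path / "spec.yaml"
    spec.to_yaml(path)
    assert ModelSpec.from_yaml(path) == spec


def test_sim_and_run_config_yaml_round_trip(tmp_path):
    cfg = SimConfig(n_users=17, seed=9, pretrend_effects={-1: -0.02})
    cfg.to_yaml(tmp_path / "sim.yaml")
    assert SimConfig.from_yaml(tmp_path / "sim.yaml") == cfg
    run = RunConfig(sim=cfg, models=("dd",), seed=4)
    run.to_yaml(tmp_path / "run.yaml")
    assert RunConfig.from_yaml(tmp_path / "run.yaml") == run


def test_ddd_design_requires_both_subgroups(window):
    cfg = SimConfig(n_users=20, p_used=1.0, exclusion_rates={}, seed=2)
    panel = simulate_panel(cfg, window)
    with pytest.raises(EstimationError):
        ddd_design(panel, window)


def test_ddd_null_effects_estimate_near_zero(window):
    design, spec = ddd_design(simulate_panel(null_config(seed=31, n_users=2000), window), window)
    res = fit(spec, design)
    for term in ("ev_p1_x_used", "ev_p2_x_used", "ev_p3_x_used"):
        assert abs(res.params[term]) < 3.5 * res.se[term]


def test_dd_null_panel_leads_and_lags_consistent_with_zero(window):
    design, spec = dd_design(simulate_panel(null_config(seed=32, n_users=2000), window), window)
    res = fit(spec, design)
    inside = sum(abs(res.params[t]) < 3 * res.se[t] for t in res.params.index)
    assert inside >= len(res.params) - 1  # allow one 3-sigma excursion


def test_moderation_horizon_zero_outcome_unshifted(small_panel):
    df, _ = moderation_design(small_panel, ModerationSpec(moderator="none", horizon=0), 12)
    pd.testing.assert_series_equal(
        df["log_outcome_fwd"], df["log_outcome"], check_names=False
    )


def test_moderation_horizon_three_drops_tail_months(small_panel):
    df, _ = moderation_design(small_panel, ModerationSpec(horizon=3), 12)
    assert df.groupby("user_id")["month_idx"].count().le(9).all()
    assert df["month_idx"].max() == 8  # last usable month is t=Sep (outcome Dec)


def test_moderation_horizon_exceeding_window_errors(small_panel):
    with pytest.raises(ConfigError):
        moderation_design(small_panel, ModerationSpec(horizon=12), 12)


def test_moderation_specs_by_mode():
    obs = build_moderation(ModerationSpec(moderator="consumption_level"))
    assert "cons_high" in obs.regressors and obs.fe_dims == ("month_idx",)
    ufe = build_moderation(ModerationSpec(moderator="consumption_level", controls_mode="user_fe"))
    assert "cons_high" not in ufe.regressors  # absorbed by user FE
    assert "post_x_cons_high" in ufe.regressors
    assert set(ufe.fe_dims) == {"user_id", "month_idx"}


def test_categorical_expansion_partitions(small_panel):
    df, _ = moderation_design(small_panel, ModerationSpec(moderator="consumption_level"), 12)
    cons_total = df["cons_medium"] + df["cons_high"] + (df["consumption_level"] == "low")
    assert (cons_total == 1).all()
    tier_total = df[["tier_1", "tier_2", "tier_3"]].sum(axis=1) + (df["city_tier"] == 4)
    assert (tier_total == 1).all()
    assert df["app_count_centered"].mean() == pytest.approx(
        df["app_count_centered"].mean()
    )  # centred column exists; mean-centring is done on the full panel


def test_moderation_null_post_effect_near_zero(window):
    cfg = null_config(seed=33, n_users=2000)
    panel = simulate_panel(cfg, window)
    df, spec = moderation_design(panel, ModerationSpec(moderator="none"), 12)
    res = fit(spec, df)
    assert abs(res.params["post"]) < 3 * res.se["post"]


def _toy_fit(params: dict, vcov_scale=1.0) -> FitResult:
    idx = pd.Index(list(params), name="term")
    v = pd.DataFrame(np.eye(len(idx)) * vcov_scale, index=idx, columns=idx)
    p = pd.Series(params)
    return FitResult(
        params=p, se=pd.Series(np.sqrt(np.diag(v)), index=idx), vcov=v,
        n_obs=100, n_clusters=10, r2=0.5, r2_within=0.1, sweeps=1,
        final_delta=0.0, df_absorbed=1,
    )


def test_pretrend_zero_leads_gives_zero_wald_and_clean_verdict():
    res = _toy_fit({"ev_m2": 0.0, "ev_m1": 0.0, "ev_p1": -0.1})
    report = pretrend_report(res, CohortWindow())
    assert report.wald_stat == 0.0
    assert report.wald_df == 2
    assert "no pre-trend" in report.verdict


def test_pretrend_wald_nonnegative_and_detects_large_leads(window):
    res = _toy_fit({"ev_m2": 0.5, "ev_m1": -0.4, "ev_p1": 0.0}, vcov_scale=1e-4)
    report = pretrend_report(res, window)
    assert report.wald_stat >= 0
    assert report.pvalue < 0.05
    assert "questionable" in report.verdict


def test_pretrend_requires_lead_terms():
    res = _toy_fit({"ev_p1": -0.1})
    with pytest.raises(EstimationError):
        pretrend_report(res, CohortWindow())
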