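"""Generator behaviour: determinism, marginals, injected-truth structure."""
import numpy as np
import pandas as pd
import pytest

from mhdid.config import SimConfig
from mhdid.errors import ConfigError, DataError
from mhdid.synth import generate_epoch_streams, generate_outcomes, generate_users


def test_seeded_determinism_bit_identical():
    cfg = SimConfig(n_users=10, seed=1)
    u1, u2 = generate_users(cfg), generate_users(cfg)
    pd.testing.assert_frame_equal(u1, u2)
    o1, o2 = generate_outcomes(u1, cfg), generate_outcomes(u2, cfg)
    pd.testing.assert_frame_equal(o1, o2)
    s1, r1 = generate_epoch_streams(o1, cfg)
    s2, r2 = generate_epoch_streams(o2, cfg)
    pd.testing.assert_frame_equal(s1, s2)
    pd.testing.assert_frame_equal(r1, r2)


def test_different_seeds_differ():
    u1 = generate_users(SimConfig(n_users=200, seed=1))
    u2 = generate_users(SimConfig(n_users=200, seed=2))
    assert not u1["adoption_month"].equals(u2["adoption_month"])


def test_degenerate_use_probability():
    users = generate_users(SimConfig(n_users=50, p_used=0.0, seed=3))
    assert not users["used_flag"].any()
    users = generate_users(SimConfig(n_users=50, p_used=1.0, seed=3))
    assert users["used_flag"].all()


def test_marginals_within_three_binomial_se():
    cfg = SimConfig(n_users=5000, seed=7)
    users = generate_users(cfg)
    n = len(users)

    def within(share, p):
        return abs(share - p) <= 3 * np.sqrt(p * (1 - p) / n)

    assert within(users["used_flag"].mean(), cfg.p_used)
    shares = users["consumption_level"].value_counts(normalize=True)
    for level, p in zip(("low", "medium", "high"), cfg.consumption_probs):
        assert within(shares[level], p)
    tiers = users["city_tier"].value_counts(normalize=True)
    for t, p in zip((1, 2, 3, 4), cfg.city_tier_probs):
        assert within(tiers[t], p)
    # adoption months uniform over the six-month window
    am = users["adoption_month"].value_counts(normalize=True)
    for m in cfg.adoption_months:
        assert within(am[m], 1 / 6)


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        SimConfig(adoption_window=("2018-12", "2019-03"))
    with pytest.raises(ConfigError):
        SimConfig(p_used=1.5)
    with pytest.raises(ConfigError):
        SimConfig(true_dynamic_effects={0: -0.1})  # r=0 is the reference
    with pytest.raises(ConfigError):
        SimConfig(zero_inflation=-0.1)


def test_null_model_outcome_is_user_plus_month_effect():
    cfg = SimConfig(
        n_users=8, noise_sd=0.0, zero_inflation=0.0, true_dynamic_effects={},
        exclusion_rates={}, seed=5,
    )
    users = generate_users(cfg)
    truth = generate_outcomes(users, cfg)
    delta = np.asarray(cfg.month_effects)
    # eta - delta_t must be constant within user (the user effect)
    resid = truth["log_latent"].to_numpy() - delta[truth["month_idx"].to_numpy()]
    spread = truth.assign(g=resid).groupby("user_id")["g"].agg(lambda s: s.max() - s.min())
    assert (spread < 1e-12).all()
    # and log1p(hours) inverts the link exactly where eta > 0
    pos = truth["log_latent"] > 0
    np.testing.assert_allclose(
        np.log1p(truth.loc[pos, "hours"]), truth.loc[pos, "log_latent"], rtol=1e-12
    )


def test_zero_inflation_one_gives_all_zero_hours():
    cfg = SimConfig(n_users=30, zero_inflation=1.0, exclusion_rates={}, seed=6)
    truth = generate_outcomes(generate_users(cfg), cfg)
    assert (truth["hours"] == 0).all()


def test_injected_effect_appears_as_subgroup_mean_gap():
    """Sample-mean contrast oracle: at event time r=2 the used/never-used gap
    in the latent log outcome matches the injected effect at large n."""
    from mhdid.benchmarks import RECOVERY_EFFECTS, recovery_config

    cfg = recovery_config(seed=9, n_users=20000)
    users = generate_users(cfg)
    truth = generate_outcomes(users, cfg)
    at2 = truth[truth["event_time"] == 2]
    gap = (
        at2.loc[at2["used_flag"], "log_latent"].mean()
        - at2.loc[~at2["used_flag"], "log_latent"].mean()
    )
    var = cfg.user_fe_sd**2 + cfg.noise_sd**2
    se = np.sqrt(var / at2["used_flag"].sum() + var / (~at2["used_flag"]).sum())
    assert abs(gap - RECOVERY_EFFECTS[2]) < 3 * se


def test_effects_touch_only_used_subgroup():
    cfg = SimConfig(
        n_users=400, p_used=0.5, noise_sd=0.0, zero_inflation=0.0,
        true_dynamic_effects={1: -0.5}, exclusion_rates={}, seed=10,
    )
    users = generate_users(cfg)
    truth = generate_outcomes(users, cfg)
    delta = np.asarray(cfg.month_effects)
    dev = truth["log_latent"].to_numpy() - delta[truth["month_idx"].to_numpy()]
    truth = truth.assign(dev=dev)
    for _, g in truth.groupby("user_id"):
        base = g.loc[g["event_time"] == 0, "dev"].iloc[0]
        shift = g.loc[g["event_time"] == 1, "dev"].iloc[0] - base
        expected = -0.5 if g["used_flag"].iloc[0] else 0.0
        assert shift == pytest.approx(expected, abs=1e-12)


def test_stream_target_exceeding_month_capacity_errors():
    cfg = SimConfig(n_users=1, seed=2)
    truth = pd.DataFrame(
        {"user_id": [0], "month": ["2019-02"], "hours": [700.0]}  # Feb has 672
    )
    with pytest.raises(DataError):
        generate_epoch_streams(truth, cfg)


def test_stream_zero_hours_emits_no_epochs():
    cfg = SimConfig(n_users=2, zero_inflation=1.0, exclusion_rates={}, seed=4)
    truth = generate_outcomes(generate_users(cfg), cfg)
    streams, realised = generate_epoch_streams(truth, cfg)
    assert streams.empty
    assert (realised["hours"] == 0).all()


def test_stream_runs_respect_requested_mix():
    from mhdid.visits import find_runs

    cfg = SimConfig(n_users=25, zero_inflation=0.3, exclusion_rates={}, seed=8)
    truth = generate_outcomes(generate_users(cfg), cfg)
    streams, realised = generate_epoch_streams(truth, cfg, run_lengths=(2, 3))
    runs = find_runs(streams)
    assert set(runs["length"]) <= {2, 3}
    total = runs.groupby(["user_id", "month"])["length"].sum()
    rt = realised.set_index(["user_id", "month"])["hours"]
    merged = pd.concat([total, rt], axis=1).fillna(0)
    assert (merged["length"] == merged["hours"]).all()
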