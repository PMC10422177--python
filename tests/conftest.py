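import numpy as np
import pandas as pd
import pytest

from mhdid.config import CohortWindow, SimConfig


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A small but non-degenerate cohort: both subgroups populated, no
    occupation/multi-category attrition, fully latent-linear outcomes."""
    return SimConfig(
        n_users=60,
        p_used=0.5,
        baseline_log_hours=2.0,
        noise_sd=0.5,
        zero_inflation=0.0,
        exclusion_rates={},
        p_multi_category=0.0,
        seed=123,
    )


@pytest.fixture(scope="session")
def window() -> CohortWindow:
    return CohortWindow()


@pytest.fixture(scope="session")
def small_panel(small_cfg, window):
    from mhdid.benchmarks import simulate_panel

    return simulate_panel(small_cfg, window)


def make_stream(user_id: int, hours: list) -> pd.DataFrame:
    """Epoch-stream frame from a list of at-hospital hour timestamps."""
    ts = pd.to_datetime(hours)
    return pd.DataFrame(
        {"user_id": np.full(len(ts), user_id), "hour": ts, "at_hospital": True}
    )


def make_users(n: int, adoption="2019-05", **overrides) -> pd.DataFrame:
    """Minimal static user table with benign defaults."""
    df = pd.DataFrame(
        {
            "user_id": np.arange(n),
            "adoption_month": adoption,
            "used_flag": np.arange(n) % 2 == 0,
            "occupation_tag": "none",
            "consumption_level": pd.Categorical(
                ["low", "medium", "high"][: max(1, min(3, n))] * (n // 3 + 1),
                categories=["low", "medium", "high"],
            )[:n],
            "city_tier": (np.arange(n) % 4) + 1,
            "installed_app_count": 30 + np.arange(n),
            "multi_category_adopter": False,
        }
    )
    for k, v in overrides.items():
        df[k] = v
    return df
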