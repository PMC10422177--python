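"""Synthetic adopter cohorts with known ground-truth dynamic effects.

The generator emulates the study setting end to end: an adopter-only sample
whose app-installation months are staggered inside a six-month window, a small
"used" subgroup that actually opens the app after installing it, zero-inflated
monthly hospital-hours with user and calendar-month heterogeneity, and dynamic
post-adoption treatment effects on the log-hours scale that apply only to the
used subgroup (the contrast a triple-difference design isolates). Monthly
hours can additionally be realised as hourly at-hospital epoch runs so the
visit-construction stage is testable end to end.

Data-generating process, per user i and month t::

    eta_it = gamma_i + delta_t
             + used_i * m_i * beta_r        (injected dynamic effects, r = event time)
             + pre_r + shared_r             (pre-trend / subgroup-shared shocks, all adopters)
             + eps_it
    hours_it = 0                 with probability zero_inflation
             = max(0, exp(eta_it) - 1)  otherwise (capped at the month's hour count)

so that log(1 + hours) equals eta wherever hours is positive. ``m_i`` is the
product of the configured moderator multipliers. Hours stay continuous here;
they are quantised only when epoch streams are realised.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import SimConfig, hours_in_month
from .errors import ConfigError, DataError

_CONSUMPTION_LEVELS = np.array(["low", "medium", "high"])

# rng stream tags, so each stage draws from an independent, reproducible stream
_USERS, _OUTCOMES, _EPOCHS = 11, 12, 13


def _rng(tag: int, seed: int) -> np.random.Generator:
    return np.random.default_rng([tag, seed])


def generate_users(cfg: SimConfig) -> pd.DataFrame:
    """Draw the static user table: adoption month, use status, moderators.

    Adoption months are uniform over the adoption window; ``used_flag`` is
    Bernoulli(p_used); consumption level, city tier and installed-app count
    follow the configured marginals (app counts are gamma-Poisson so their
    dispersion exceeds the mean, as in real install counts). Occupation tags
    (physician / ride-hailing driver) and the multi-category-adopter flag mark
    users the downstream filters must remove.
    """
    rng = _rng(_USERS, cfg.seed)
    n = cfg.n_users
    adoption = rng.choice(np.asarray(cfg.adoption_months), size=n)
    used = rng.random(n) < cfg.p_used

    occ = np.full(n, "none", dtype=object)
    u = rng.random(n)
    p_phys = float(cfg.exclusion_rates.get("physician", 0.0))
    p_drv = float(cfg.exclusion_rates.get("driver", 0.0))
    occ[u < p_phys] = "physician"
    occ[(u >= p_phys) & (u < p_phys + p_drv)] = "driver"

    consumption = rng.choice(_CONSUMPTION_LEVELS, size=n, p=list(cfg.consumption_probs))
    tier = rng.choice([1, 2, 3, 4], size=n, p=list(cfg.city_tier_probs))
    lam = rng.gamma(cfg.app_count_shape, cfg.app_count_mean / cfg.app_count_shape, size=n)
    app_count = rng.poisson(lam)
    multi = rng.random(n) < cfg.p_multi_category

    return pd.DataFrame(
        {
            "user_id": np.arange(n, dtype=np.int64),
            "adoption_month": adoption,
            "used_flag": used,
            "occupation_tag": occ,
            "consumption_level": pd.Categorical(
                consumption, categories=list(_CONSUMPTION_LEVELS)
            ),
            "city_tier": tier.astype(np.int64),
            "installed_app_count": app_count.astype(np.int64),
            "multi_category_adopter": multi,
        }
    )


def _effect_lookup(effects: Mapping[int, float], n_months: int) -> np.ndarray:
    """Dense lookup over event times -(M-1)..(M-1); index with r + M - 1."""
    out = np.zeros(2 * n_months - 1)
    for r, v in effects.items():
        if abs(r) <= n_months - 1:
            out[r + n_months - 1] = v
    return out


def _moderator_multiplier(users: pd.DataFrame, cfg: SimConfig) -> np.ndarray:
    mult = np.ones(len(users))
    emap = cfg.moderator_effect_map
    if "consumption_level" in emap:
        cm = emap["consumption_level"]
        mult *= users["consumption_level"].astype(str).map(cm).to_numpy(dtype=float)
    if "city_tier" in emap:
        tm = {int(k): float(v) for k, v in emap["city_tier"].items()}
        mult *= users["city_tier"].map(tm).to_numpy(dtype=float)
    if "app_count" in emap:
        slope = float(emap["app_count"])
        counts = users["installed_app_count"].to_numpy(dtype=float)
        sd = counts.std() or 1.0
        mult *= np.clip(1.0 + slope * (counts - counts.mean()) / sd, 0.0, None)
    if np.any(~np.isfinite(mult)):
        raise ConfigError("moderator_effect_map does not cover all observed levels")
    return mult


def generate_outcomes(users: pd.DataFrame, cfg: SimConfig) -> pd.DataFrame:
    """Latent-truth panel: one row per user x calendar month.

    Returns columns ``user_id, month, month_idx, event_time, used_flag,
    log_latent, hours``. ``log_latent`` is the linear predictor eta (before
    zero-inflation and clipping); ``hours`` is the continuous monthly
    hospital-hours outcome after zero-inflation, clipping at zero and at the
    calendar capacity of the month. Physicians and drivers receive extra
    occupational hospital hours so the exclusion rule has something to remove.
    """
    rng = _rng(_OUTCOMES, cfg.seed)
    months = list(cfg.months)
    n_m = len(months)
    n_u = len(users)

    month_pos = {m: i for i, m in enumerate(months)}
    try:
        a_idx = users["adoption_month"].map(month_pos).to_numpy(dtype=np.int64)
    except (TypeError, ValueError) as exc:
        raise DataError("adoption_month outside the months grid") from exc

    gamma = cfg.baseline_log_hours + cfg.user_fe_sd * rng.standard_normal(n_u)
    delta = np.asarray(cfg.month_effects)
    beta = _effect_lookup(cfg.true_dynamic_effects, n_m)
    pre = _effect_lookup(cfg.pretrend_effects, n_m)
    shared = _effect_lookup(cfg.common_dynamic_effects, n_m)
    mult = _moderator_multiplier(users, cfg)
    used = users["used_flag"].to_numpy(dtype=bool)

    # long layout: user-major, month-minor
    uu = np.repeat(np.arange(n_u), n_m)
    tt = np.tile(np.arange(n_m), n_u)
    r = tt - a_idx[uu]
    r_ix = r + n_m - 1

    eta = (
        gamma[uu]
        + delta[tt]
        + used[uu] * mult[uu] * beta[r_ix]
        + pre[r_ix]
        + shared[r_ix]
        + cfg.noise_sd * rng.standard_normal(n_u * n_m)
    )
    caps = np.array([hours_in_month(m) for m in months], dtype=float)
    hours = np.clip(np.expm1(eta), 0.0, caps[tt])
    if cfg.zero_inflation > 0:
        hours[rng.random(n_u * n_m) < cfg.zero_inflation] = 0.0

    occ = users["occupation_tag"].to_numpy()
    occ_extra = np.isin(occ, ["physician", "driver"])
    if occ_extra.any() and cfg.occupation_extra_hours > 0:
        extra = rng.poisson(cfg.occupation_extra_hours, size=n_u * n_m).astype(float)
        hours = np.where(occ_extra[uu], np.minimum(hours + extra, caps[tt]), hours)

    return pd.DataFrame(
        {
            "user_id": users["user_id"].to_numpy()[uu],
            "month": np.asarray(months, dtype=object)[tt],
            "month_idx": tt.astype(np.int64),
            "event_time": r.astype(np.int64),
            "used_flag": used[uu],
            "log_latent": eta,
            "hours": hours,
        }
    )


def _representable(run_lengths: Sequence[int], max_total: int) -> tuple[np.ndarray, np.ndarray]:
    """Totals reachable as sums of the allowed run lengths, with a parent
    length for greedy decomposition."""
    lengths = sorted(set(int(l) for l in run_lengths), reverse=True)
    if not lengths or min(lengths) < 1:
        raise ConfigError("run_lengths must be positive integers")
    reach = np.zeros(max_total + 1, dtype=bool)
    parent = np.zeros(max_total + 1, dtype=np.int64)
    reach[0] = True
    for s in range(1, max_total + 1):
        for l in lengths:  # prefer long runs -> fewer runs, less gap pressure
            if l <= s and reach[s - l]:
                reach[s] = True
                parent[s] = l
                break
    return reach, parent


def _nearest_representable(reach: np.ndarray) -> np.ndarray:
    """Map each integer total to the nearest reachable one (ties go down)."""
    idx = np.flatnonzero(reach)
    grid = np.arange(reach.size)
    pos = np.searchsorted(idx, grid)
    lo = idx[np.clip(pos - 1, 0, idx.size - 1)]
    hi = idx[np.clip(pos, 0, idx.size - 1)]
    return np.where((grid - lo) <= (hi - grid), lo, hi)


def generate_epoch_streams(
    panel_truth: pd.DataFrame,
    cfg: SimConfig,
    run_lengths: Sequence[int] = (2, 3),
    dense: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Realise monthly hours as hourly at-hospital epoch runs.

    Each user-month's target hours are quantised to the nearest total
    representable as a sum of the allowed ``run_lengths`` (e.g. 1 hour becomes
    a 2-hour run under the default {2, 3} mix), decomposed into runs, and the
    runs are placed at random non-adjacent positions on the month's hour grid.
    Returns ``(streams, realised)`` where *streams* holds one row per
    at-hospital epoch (absence means not at hospital; pass ``dense=True`` to
    also emit the not-at-hospital rows) and *realised* records the monthly
    hour totals actually laid down — the ground truth the visit-construction
    stage should reconstruct. With runs of length >= 2 the reconstruction
    under the 2-epoch rule equals *realised* exactly; a ``run_lengths=(1,)``
    mix creates a deliberate mismatch fixture (singleton runs never qualify).

    Raises ``DataError`` if a month cannot physically host its target hours.
    """
    rng = _rng(_EPOCHS, cfg.seed)
    months = list(cfg.months)
    caps = {m: hours_in_month(m) for m in months}
    max_cap = max(caps.values())
    reach, parent = _representable(run_lengths, max_cap)
    nearest = _nearest_representable(reach)

    truth = panel_truth
    target = np.rint(truth["hours"].to_numpy(dtype=float)).astype(np.int64)
    cap_arr = truth["month"].map(caps).to_numpy(dtype=np.int64)
    if np.any(target > cap_arr):
        bad = truth.loc[target > cap_arr].iloc[0]
        raise DataError(
            f"target hours {bad['hours']:.0f} exceed the {caps[bad['month']]}-hour "
            f"capacity of {bad['month']} for user {bad['user_id']}"
        )
    realised_hours = nearest[target]

    month_start = {m: pd.Period(m, "M").start_time for m in months}
    rows_user: list[np.ndarray] = []
    rows_hour: list[np.ndarray] = []
    realised_rows = []

    users_arr = truth["user_id"].to_numpy()
    months_arr = truth["month"].to_numpy()
    for i in np.flatnonzero(realised_hours > 0):
        h = int(realised_hours[i])
        m = months_arr[i]
        cap = caps[m]
        # decompose into allowed run lengths
        runs = []
        s = h
        while s > 0:
            l = int(parent[s])
            runs.append(l)
            s -= l
        n_runs = len(runs)
        slack = cap - h - (n_runs - 1)
        if slack < 0:
            raise DataError(
                f"cannot place {h} hospital hours as {n_runs} separated runs in {m}"
            )
        rng.shuffle(runs)
        gaps = rng.multinomial(slack, np.full(n_runs + 1, 1.0 / (n_runs + 1)))
        offsets = []
        pos = 0
        for j, l in enumerate(runs):
            pos += int(gaps[j]) + (1 if j > 0 else 0)
            offsets.append(np.arange(pos, pos + l))
            pos += l
        hours_idx = np.concatenate(offsets)
        rows_user.append(np.full(h, users_arr[i]))
        rows_hour.append(month_start[m].to_datetime64() + hours_idx * np.timedelta64(1, "h"))

    for i in range(len(truth)):
        realised_rows.append((users_arr[i], months_arr[i], int(realised_hours[i])))

    if rows_user:
        streams = pd.DataFrame(
            {
                "user_id": np.concatenate(rows_user),
                "hour": np.concatenate(rows_hour),
                "at_hospital": True,
            }
        ).sort_values(["user_id", "hour"], ignore_index=True)
    else:
        streams = pd.DataFrame(
            {
                "user_id": np.array([], dtype=np.int64),
                "hour": np.array([], dtype="datetime64[ns]"),
                "at_hospital": np.array([], dtype=bool),
            }
        )
    realised = pd.DataFrame(realised_rows, columns=["user_id", "month", "hours"])
    if dense:
        streams = densify_streams(streams, sorted(set(users_arr)), months)
    return streams, realised


def densify_streams(streams: pd.DataFrame, user_ids: Sequence, months: Sequence[str]) -> pd.DataFrame:
    """Expand a sparse stream to one record per user-hour over the grid."""
    start = pd.Period(months[0], "M").start_time
    end = pd.Period(months[-1], "M").end_time
    grid = pd.date_range(start, end, freq="h")
    full = pd.MultiIndex.from_product([list(user_ids), grid], names=["user_id", "hour"])
    flagged = streams.set_index(["user_id", "hour"])["at_hospital"]
    dense = flagged.reindex(full, fill_value=False).reset_index()
    return dense
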