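"""Estimation-panel construction: event-time coding and outcome transform.

The estimation unit is the user x calendar-month cell. Event time r counts
months since the app-adoption month (negative = leads), the outcome is
log(1 + monthly visit duration) so coefficients read approximately as
percentage changes, and the adoption month itself (r = 0) is the omitted
reference period in all event-study designs.
"""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .config import CohortWindow
from .errors import DataError

log = logging.getLogger(__name__)

LEAD_CAP = "ev_lead_cap"
LAG_CAP = "ev_lag_cap"


def event_col(r: int) -> str:
    return f"ev_m{-r}" if r < 0 else f"ev_p{r}"


def build_panel(
    visits: pd.DataFrame,
    users: pd.DataFrame,
    window: CohortWindow,
    months: Sequence[str],
    outcome: str = "visit_hours",
) -> pd.DataFrame:
    """Assemble one PanelRow per retained user and calendar month.

    Parameters
    ----------
    visits : monthly outcome table with ``user_id``, ``month`` and the chosen
        outcome column (``visit_hours``/``visit_days`` from the visits stage,
        or ``hours`` from the latent-truth generator).
    users : static user table (already filtered for multi-category adopters
        and excluded occupations as appropriate); must carry
        ``adoption_month``, ``used_flag`` and the moderators.
    window : cohort window; users whose adoption month falls outside
        [adoption_first, adoption_last] are dropped.
    months : the ordered calendar grid of the data.

    Returns a DataFrame with ``user_id, month, month_idx, event_time,
    log_outcome, used, post, consumption_level, city_tier,
    app_count_centered`` where ``log_outcome = log(1 + outcome)`` and
    ``post = 1[event_time >= 1]``.
    """
    month_pos = {m: i for i, m in enumerate(months)}
    visits = visits[["user_id", "month", outcome]]
    if users["adoption_month"].isna().any():
        bad = users.loc[users["adoption_month"].isna(), "user_id"].iloc[0]
        raise DataError(f"user {bad} has no adoption month")
    if not users["adoption_month"].isin(month_pos).all():
        bad = users.loc[~users["adoption_month"].isin(month_pos)].iloc[0]
        raise DataError(
            f"user {bad['user_id']} adoption month {bad['adoption_month']} outside data window"
        )
    if not visits["month"].isin(month_pos).all():
        bad = visits.loc[~visits["month"].isin(month_pos), "month"].iloc[0]
        raise DataError(f"calendar month {bad} outside the configured data window")

    cohort = set(window.adoption_months)
    keep = users[users["adoption_month"].isin(cohort)].copy()
    log.info("build_panel: retained %d of %d users in cohort window", len(keep), len(users))

    df = visits.merge(keep, on="user_id", how="inner")
    df["month_idx"] = df["month"].map(month_pos).astype(np.int64)
    df["event_time"] = df["month_idx"] - df["adoption_month"].map(month_pos).astype(np.int64)
    out_vals = df[outcome].to_numpy(dtype=float)
    if np.any(out_vals < 0):
        raise DataError(f"outcome column {outcome!r} has negative values")
    df["log_outcome"] = np.log1p(out_vals)
    df["used"] = df["used_flag"].astype(np.int64)
    df["post"] = (df["event_time"] >= 1).astype(np.int64)
    counts = df["installed_app_count"].to_numpy(dtype=float)
    df["app_count_centered"] = counts - counts.mean()

    cols = [
        "user_id",
        "month",
        "month_idx",
        "event_time",
        "log_outcome",
        "used",
        "post",
        "consumption_level",
        "city_tier",
        "app_count_centered",
    ]
    return df[cols].sort_values(["user_id", "month_idx"], ignore_index=True)


def event_time_dummies(panel: pd.DataFrame, window: CohortWindow) -> pd.DataFrame:
    """Indicator columns for the reported event times plus end caps.

    One column per r in [-report_leads, report_lags] excluding the reference
    period, plus ``ev_lead_cap`` (r <= -(leads+1)) and ``ev_lag_cap``
    (r >= lags+1) so observations far from adoption are binned rather than
    dropped. Together with the implicit reference the indicators partition
    each row: exactly one is active (or none, at the reference period).
    """
    r = panel["event_time"].to_numpy()
    out = pd.DataFrame(index=panel.index)
    terms: dict[str, object] = {}
    for rr in window.reported_event_times:
        out[event_col(rr)] = (r == rr).astype(float)
        terms[event_col(rr)] = rr
    out[LEAD_CAP] = (r <= -(window.report_leads + 1)).astype(float)
    out[LAG_CAP] = (r >= window.report_lags + 1).astype(float)
    terms[LEAD_CAP] = f"<=-{window.report_leads + 1}"
    terms[LAG_CAP] = f">={window.report_lags + 1}"
    out.attrs["event_terms"] = terms
    return out
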