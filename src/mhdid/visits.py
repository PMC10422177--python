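"""Dependent-variable construction: epoch streams -> monthly hospital visits.

A geolocation stream arrives as hourly epochs with an at-hospital flag. To
suppress spurious single-epoch pings (GPS noise, passing by a hospital) a
record only counts toward the outcome when the user stayed for at least
``min_consecutive_epochs`` consecutive hours; the qualifying run then
contributes its *full* length, since the outcome is the duration of hospital
presence, not a visit count. Runs spanning a month boundary are split at the
boundary before thresholding so every hour has an unambiguous month.

Users tagged as physicians or web-based ride-hailing drivers are excluded
outright — they are at hospitals for reasons unrelated to their own health.
"""
from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .config import VisitRule
from .errors import DataError

log = logging.getLogger(__name__)

EXCLUDED_OCCUPATIONS = ("physician", "driver")


def find_runs(stream: pd.DataFrame) -> pd.DataFrame:
    """Maximal runs of consecutive at-hospital epochs, split at month bounds.

    Parameters
    ----------
    stream : DataFrame with columns ``user_id``, ``hour`` (whole-hour
        timestamps) and optionally ``at_hospital`` (rows with False are
        dropped; absent column means every row is an at-hospital epoch).

    Returns
    -------
    DataFrame with one row per run: ``user_id, start, length, month``.

    Raises
    ------
    DataError on duplicate (user, hour) records or off-grid timestamps.
    """
    df = stream
    if "at_hospital" in df.columns:
        df = df[df["at_hospital"].astype(bool)]
    if df.empty:
        return pd.DataFrame(
            {
                "user_id": np.array([], dtype=np.int64),
                "start": np.array([], dtype="datetime64[ns]"),
                "length": np.array([], dtype=np.int64),
                "month": np.array([], dtype=object),
            }
        )
    hours = pd.to_datetime(df["hour"])
    if not (hours == hours.dt.floor("h")).all():
        raise DataError("epoch timestamps must lie on the whole-hour grid")
    df = pd.DataFrame({"user_id": df["user_id"].to_numpy(), "hour": hours.to_numpy()})
    df = df.sort_values(["user_id", "hour"], ignore_index=True)
    if df.duplicated(["user_id", "hour"]).any():
        dup = df[df.duplicated(["user_id", "hour"])].iloc[0]
        raise DataError(f"duplicate epoch for user {dup['user_id']} at {dup['hour']}")

    uid = df["user_id"].to_numpy()
    t = df["hour"].to_numpy()
    period = pd.PeriodIndex(df["hour"], freq="M").astype(str).to_numpy()
    same_user = uid[1:] == uid[:-1]
    consecutive = (t[1:] - t[:-1]) == np.timedelta64(1, "h")
    same_month = period[1:] == period[:-1]
    new_run = np.concatenate([[True], ~(same_user & consecutive & same_month)])
    run_id = np.cumsum(new_run) - 1

    starts = np.flatnonzero(new_run)
    lengths = np.diff(np.append(starts, len(uid)))
    return pd.DataFrame(
        {
            "user_id": uid[starts],
            "start": t[starts],
            "length": lengths.astype(np.int64),
            "month": period[starts],
        }
    )


def exclude_multi_category(users: pd.DataFrame) -> pd.DataFrame:
    """Drop adopters of more than one health-app category.

    Cross-category adopters could enjoy synergistic effects between apps,
    which would confound the single-app contrast, so they are removed before
    any panel construction.
    """
    flagged = users["multi_category_adopter"].astype(bool)
    n_removed = int(flagged.sum())
    log.info("exclude_multi_category: removed %d of %d users", n_removed, len(users))
    out = users.loc[~flagged].reset_index(drop=True)
    if out.empty:
        warnings.warn("all users are multi-category adopters; nothing retained")
    return out


def exclude_occupations(users: pd.DataFrame) -> pd.DataFrame:
    """Drop physicians and web-based ride-hailing drivers."""
    mask = users["occupation_tag"].isin(EXCLUDED_OCCUPATIONS)
    log.info("exclude_occupations: removed %d of %d users", int(mask.sum()), len(users))
    return users.loc[~mask].reset_index(drop=True)


def monthly_duration(
    stream: pd.DataFrame,
    rule: VisitRule,
    users: pd.DataFrame,
    months: Sequence[str],
) -> pd.DataFrame:
    """Monthly visit outcomes per retained user under a consecutive-epoch rule.

    Returns one row per retained (non-physician, non-driver) user and calendar
    month with ``visit_hours`` (sum of lengths of runs >= k) and ``visit_days``
    (distinct days containing at least one hour of a qualifying run).
    User-months without qualifying runs appear with zeros; excluded users
    contribute no rows.
    """
    retained = exclude_occupations(users)
    runs = find_runs(stream)
    runs = runs[runs["user_id"].isin(set(retained["user_id"]))]
    qual = runs[runs["length"] >= rule.min_consecutive_epochs]

    hours = (
        qual.groupby(["user_id", "month"], sort=False)["length"].sum()
        if len(qual)
        else pd.Series(dtype=np.int64)
    )

    # expand qualifying runs to the days they touch (runs never cross months)
    if len(qual):
        start_day = qual["start"].dt.normalize()
        end_day = (qual["start"] + pd.to_timedelta(qual["length"] - 1, unit="h")).dt.normalize()
        n_days = ((end_day - start_day).dt.days + 1).to_numpy()
        day0 = np.repeat(start_day.to_numpy(), n_days)
        step = np.concatenate([np.arange(k) for k in n_days])
        day = day0 + step * np.timedelta64(1, "D")
        touched = pd.DataFrame(
            {
                "user_id": np.repeat(qual["user_id"].to_numpy(), n_days),
                "month": np.repeat(qual["month"].to_numpy(), n_days),
                "day": day,
            }
        ).drop_duplicates()
        days = touched.groupby(["user_id", "month"], sort=False)["day"].count()
    else:
        days = pd.Series(dtype=np.int64)

    grid = pd.MultiIndex.from_product(
        [retained["user_id"].to_numpy(), list(months)], names=["user_id", "month"]
    )
    out = pd.DataFrame(index=grid)
    out["visit_hours"] = hours.reindex(grid, fill_value=0).astype(np.int64)
    out["visit_days"] = days.reindex(grid, fill_value=0).astype(np.int64)
    return out.reset_index()
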