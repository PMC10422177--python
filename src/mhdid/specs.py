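"""Builders for the three estimations: dynamic DD, DDD, and moderation.

* Dynamic DD (event study): log visit duration on event-time indicators with
  user and calendar-month fixed effects — traces period-specific effects
  beta_r around adoption, with the adoption month (r=0) as reference.
* DDD (triple difference): adds the contrast between adopters who used the
  app and adopters who installed but never used it, absorbing user-by-subgroup
  and month-by-subgroup fixed effects; the common event-time indicators are
  kept as controls so any adoption-timed shock shared by both subgroups is
  differenced out of the triple terms.
* Moderation: 3-month-ahead outcome on the post-adoption indicator and its
  interaction with one moderator (consumption level, city tier, or
  mean-centred installed-app count).

Every builder returns a declarative :class:`~mhdid.fe.ModelSpec`; the
``*_design`` helpers additionally materialise the required design columns.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CohortWindow
from .errors import ConfigError, EstimationError
from .fe import FitResult, ModelSpec, ddd_terms
from .panel import event_col, event_time_dummies

DD_FE: tuple = ("user_id", "month_idx")
DDD_FE: tuple = ("user_id", ("month_idx", "used"))

OBSERVABLE_CONTROLS = (
    "cons_medium",
    "cons_high",
    "tier_1",
    "tier_2",
    "tier_3",
    "app_count_centered",
)


def _event_regressors(window: CohortWindow) -> tuple[str, ...]:
    return tuple(event_col(r) for r in window.reported_event_times) + (
        "ev_lead_cap",
        "ev_lag_cap",
    )


def build_dd(window: CohortWindow) -> ModelSpec:
    """Dynamic difference-in-differences: event-time dummies, user + month FE."""
    return ModelSpec(
        outcome="log_outcome",
        regressors=_event_regressors(window),
        fe_dims=DD_FE,
        cluster="user_id",
        label="dd",
    )


def build_ddd(window: CohortWindow) -> ModelSpec:
    """Triple difference: used-interacted event terms plus common event-time
    controls, user(-by-subgroup) and month-by-subgroup FE."""
    ev = _event_regressors(window)
    return ModelSpec(
        outcome="log_outcome",
        regressors=ev + tuple(f"{c}_x_used" for c in ev),
        fe_dims=DDD_FE,
        cluster="user_id",
        label="ddd",
    )


def dd_design(panel: pd.DataFrame, window: CohortWindow) -> tuple[pd.DataFrame, ModelSpec]:
    """Panel with event-time indicator columns attached, plus the DD spec."""
    ev = event_time_dummies(panel, window)
    return pd.concat([panel, ev], axis=1), build_dd(window)


def ddd_design(panel: pd.DataFrame, window: CohortWindow) -> tuple[pd.DataFrame, ModelSpec]:
    """Panel with common + used-interacted event columns, plus the DDD spec.

    Raises ``EstimationError`` when either subgroup (used / never-used) is
    empty — the triple difference needs both.
    """
    ev = event_time_dummies(panel, window)
    triple = ddd_terms(panel, window)  # validates subgroups
    return pd.concat([panel, ev, triple], axis=1), build_ddd(window)


def ddd_effect_terms(window: CohortWindow) -> tuple[str, ...]:
    """The coefficients of interest in the DDD fit (reported event times)."""
    return tuple(f"{event_col(r)}_x_used" for r in window.reported_event_times)


@dataclass(frozen=True)
class ModerationSpec:
    """One moderation regression on the 3-month-ahead outcome.

    ``moderator`` selects which Post x Z interactions enter ("none" gives the
    Post-only model); ``controls_mode`` chooses between observable
    characteristics (which lets the time-invariant moderator main effects be
    reported) and user fixed effects (which absorb them).
    """

    moderator: str = "none"
    horizon: int = 3
    controls_mode: str = "observables"

    def __post_init__(self) -> None:
        if self.moderator not in ("none", "consumption_level", "city_tier", "app_count"):
            raise ConfigError(f"unknown moderator {self.moderator!r}")
        if self.horizon < 0:
            raise ConfigError("horizon must be >= 0")
        if self.controls_mode not in ("observables", "user_fe"):
            raise ConfigError("controls_mode must be 'observables' or 'user_fe'")

    @property
    def interaction_terms(self) -> tuple[str, ...]:
        return {
            "none": (),
            "consumption_level": ("post_x_cons_medium", "post_x_cons_high"),
            "city_tier": ("post_x_tier_1", "post_x_tier_2", "post_x_tier_3"),
            "app_count": ("post_x_app_count",),
        }[self.moderator]


def build_moderation(mspec: ModerationSpec) -> ModelSpec:
    """ModelSpec for one moderation model (design columns via
    :func:`moderation_design`)."""
    if mspec.controls_mode == "observables":
        regressors = ("post",) + OBSERVABLE_CONTROLS + mspec.interaction_terms
        fe: tuple = ("month_idx",)
    else:
        regressors = ("post",) + mspec.interaction_terms
        fe = ("user_id", "month_idx")
    return ModelSpec(
        outcome="log_outcome_fwd",
        regressors=regressors,
        fe_dims=fe,
        cluster="user_id",
        label=f"moderation_{mspec.moderator}_{mspec.controls_mode}",
    )


def moderation_design(
    panel: pd.DataFrame, mspec: ModerationSpec, n_months: int
) -> tuple[pd.DataFrame, ModelSpec]:
    """Attach the horizon-shifted outcome and moderator columns.

    The outcome of row (i, t) becomes the log visit duration of (i, t+horizon);
    rows whose shifted month leaves the data window are dropped, not imputed.
    Categorical moderators expand to dummies with low consumption / tier 4 as
    the reference categories; the app count enters mean-centred.
    """
    if mspec.horizon >= n_months:
        raise ConfigError(
            f"horizon {mspec.horizon} leaves no observable months in a {n_months}-month window"
        )
    df = panel.sort_values(["user_id", "month_idx"]).reset_index(drop=True)
    df["log_outcome_fwd"] = df.groupby("user_id", sort=False)["log_outcome"].shift(
        -mspec.horizon
    )
    df = df.dropna(subset=["log_outcome_fwd"]).reset_index(drop=True)

    cons = df["consumption_level"].astype(str)
    df["cons_medium"] = (cons == "medium").astype(float)
    df["cons_high"] = (cons == "high").astype(float)
    for t in (1, 2, 3):
        df[f"tier_{t}"] = (df["city_tier"] == t).astype(float)
    post = df["post"].to_numpy(dtype=float)
    df["post_x_cons_medium"] = post * df["cons_medium"]
    df["post_x_cons_high"] = post * df["cons_high"]
    for t in (1, 2, 3):
        df[f"post_x_tier_{t}"] = post * df[f"tier_{t}"]
    df["post_x_app_count"] = post * df["app_count_centered"]
    return df, build_moderation(mspec)


@dataclass
class PretrendReport:
    """Joint assessment of the pre-adoption (lead) coefficients."""

    leads: pd.DataFrame
    wald_stat: float
    wald_df: int
    pvalue: float
    alpha: float
    verdict: str = field(init=False)

    def __post_init__(self) -> None:
        if self.pvalue < self.alpha:
            self.verdict = (
                f"pre-trend detected (joint Wald p={self.pvalue:.2g} < {self.alpha}); "
                "the parallel-trends assumption is questionable - prefer the DDD estimates"
            )
        else:
            self.verdict = f"no pre-trend detected (joint Wald p={self.pvalue:.2g})"

    def to_dict(self) -> dict:
        return {
            "leads": self.leads.to_dict(orient="records"),
            "wald_stat": self.wald_stat,
            "wald_df": self.wald_df,
            "pvalue": self.pvalue,
            "alpha": self.alpha,
            "verdict": self.verdict,
        }


def pretrend_report(
    fit_result: FitResult, window: CohortWindow, alpha: float = 0.05
) -> PretrendReport:
    """Lead-coefficient table and joint Wald test of H0: all leads are zero.

    Significant leads mean treated and control cohorts were already diverging
    before adoption — the motivation for preferring the triple difference.
    """
    lead_rs = [r for r in window.reported_event_times if r < 0]
    lead_terms = [event_col(r) for r in lead_rs]
    lead_terms = [t for t in lead_terms if t in fit_result.params.index]
    if not lead_terms:
        raise EstimationError("fit contains no lead (pre-adoption) terms")
    stat, df, p = fit_result.wald(lead_terms)
    table = fit_result.to_frame()
    table = table[table["term"].isin(lead_terms)].reset_index(drop=True)
    return PretrendReport(leads=table, wald_stat=stat, wald_df=df, pvalue=p, alpha=alpha)
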