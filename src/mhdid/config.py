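"""Configuration objects shared across the pipeline.

Calendar months are handled as ``"YYYY-MM"`` strings on a fixed ordered grid
(default Jan-Dec 2019, the study window); event time is the plain integer
difference of grid positions.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .errors import ConfigError

DEFAULT_MONTHS: tuple[str, ...] = tuple(
    str(p) for p in pd.period_range("2019-01", "2019-12", freq="M")
)


def month_range(first: str, last: str) -> tuple[str, ...]:
    """Inclusive list of "YYYY-MM" months from *first* to *last*."""
    return tuple(str(p) for p in pd.period_range(first, last, freq="M"))


def hours_in_month(month: str) -> int:
    return int(pd.Period(month, freq="M").days_in_month) * 24


def default_month_effects(n_months: int) -> tuple[float, ...]:
    # mild seasonal pattern in hospital load; amplitude is small relative to
    # user heterogeneity so it never dominates the panel variance
    return tuple(0.10 * math.sin(2.0 * math.pi * t / max(n_months, 1)) for t in range(n_months))


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must lie in [0, 1], got {value!r}")


def _check_effect_keys(name: str, effects: Mapping[int, float], sign: int | None = None) -> None:
    for r in effects:
        if not isinstance(r, int) or r == 0:
            raise ConfigError(
                f"{name} keys must be nonzero integers (r=0 is the reference period), got {r!r}"
            )
        if sign is not None and (r > 0) != (sign > 0):
            raise ConfigError(f"{name} keys must have sign {sign:+d}, got {r}")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic adopter cohort and outcome process.

    The generator emulates an adopter-only panel: every simulated user installs
    the focal health-and-fitness app at some month inside ``adoption_window``;
    a fraction ``p_used`` actually uses it afterwards, and the injected dynamic
    treatment effects apply only to that used subgroup, which is exactly the
    contrast the triple-difference design identifies.
    """

    n_users: int = 5000
    months: tuple[str, ...] = DEFAULT_MONTHS
    adoption_window: tuple[str, str] = ("2019-04", "2019-09")
    #: share of adopters who ever use the app (observed split 21,444 / 267,651)
    p_used: float = 0.0801
    #: event-time -> effect on the log-hours scale, used subgroup only
    true_dynamic_effects: Mapping[int, float] = field(
        default_factory=lambda: {1: -0.058, 2: -0.131, 3: -0.184}
    )
    #: event-time (r<0) -> effect shared by all adopters (parallel-trends violation)
    pretrend_effects: Mapping[int, float] = field(default_factory=dict)
    #: event-time -> shock shared by both subgroups (used and never-used alike);
    #: biases DD but is differenced out by DDD
    common_dynamic_effects: Mapping[int, float] = field(default_factory=dict)
    baseline_log_hours: float = 1.0
    user_fe_sd: float = 1.0
    month_fe: tuple[float, ...] | None = None
    noise_sd: float = 0.8
    #: probability a user-month has no hospital contact at all
    zero_inflation: float = 0.6
    #: optional moderator multipliers on the used-subgroup dynamic effects:
    #: {"consumption_level": {"low": .., "medium": .., "high": ..},
    #:  "city_tier": {1: .., 2: .., 3: .., 4: ..},
    #:  "app_count": slope per SD of installed-app count}
    moderator_effect_map: Mapping[str, object] = field(default_factory=dict)
    consumption_probs: tuple[float, float, float] = (0.40, 0.40, 0.20)
    city_tier_probs: tuple[float, float, float, float] = (0.20, 0.30, 0.30, 0.20)
    app_count_mean: float = 35.65
    app_count_shape: float = 1.5
    exclusion_rates: Mapping[str, float] = field(
        default_factory=lambda: {"physician": 0.005, "driver": 0.005}
    )
    p_multi_category: float = 0.05
    #: extra at-hospital hours per month injected for physicians/drivers, so the
    #: occupation exclusion is observable downstream
    occupation_extra_hours: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users < 1:
            raise ConfigError("n_users must be >= 1")
        months = set(self.months)
        first, last = self.adoption_window
        window = month_range(first, last)
        if not set(window) <= months:
            raise ConfigError(
                f"adoption_window {self.adoption_window} not contained in months grid"
            )
        for name in ("p_used", "zero_inflation", "p_multi_category"):
            _check_prob(name, getattr(self, name))
        for occ, rate in self.exclusion_rates.items():
            _check_prob(f"exclusion_rates[{occ}]", rate)
        if abs(sum(self.consumption_probs) - 1.0) > 1e-9:
            raise ConfigError("consumption_probs must sum to 1")
        if abs(sum(self.city_tier_probs) - 1.0) > 1e-9:
            raise ConfigError("city_tier_probs must sum to 1")
        _check_effect_keys("true_dynamic_effects", self.true_dynamic_effects)
        _check_effect_keys("pretrend_effects", self.pretrend_effects, sign=-1)
        _check_effect_keys("common_dynamic_effects", self.common_dynamic_effects)
        if self.month_fe is not None and len(self.month_fe) != len(self.months):
            raise ConfigError("month_fe length must match months grid")
        if self.noise_sd < 0 or self.user_fe_sd < 0:
            raise ConfigError("dispersions must be nonnegative")

    @property
    def adoption_months(self) -> tuple[str, ...]:
        return month_range(*self.adoption_window)

    @property
    def month_effects(self) -> tuple[float, ...]:
        if self.month_fe is not None:
            return tuple(self.month_fe)
        return default_month_effects(len(self.months))

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["true_dynamic_effects"] = {int(k): float(v) for k, v in self.true_dynamic_effects.items()}
        d["pretrend_effects"] = {int(k): float(v) for k, v in self.pretrend_effects.items()}
        d["common_dynamic_effects"] = {
            int(k): float(v) for k, v in self.common_dynamic_effects.items()
        }
        d["months"] = list(self.months)
        d["adoption_window"] = list(self.adoption_window)
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "months" in d:
            d["months"] = tuple(d["months"])
        if "adoption_window" in d:
            d["adoption_window"] = tuple(d["adoption_window"])
        if d.get("month_fe") is not None:
            d["month_fe"] = tuple(d["month_fe"])
        for key in ("consumption_probs", "city_tier_probs"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("true_dynamic_effects", "pretrend_effects", "common_dynamic_effects"):
            if key in d and d[key] is not None:
                d[key] = {int(k): float(v) for k, v in d[key].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, source) -> "SimConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        return cls.from_dict(data)


@dataclass(frozen=True)
class VisitRule:
    """How hourly at-hospital epochs are turned into a monthly outcome.

    ``min_consecutive_epochs`` is the qualifying run length k: a maximal run of
    consecutive at-hospital epochs contributes its full length to the monthly
    duration iff its length is >= k. The baseline reading of "more than an
    hour" is k=2; k=3 and k=4 are the sensitivity variants, and k=1 recovers
    the raw hour count.
    """

    min_consecutive_epochs: int = 2
    measure: str = "hours"  # "hours" or "days"

    def __post_init__(self) -> None:
        if self.min_consecutive_epochs < 1:
            raise ConfigError("min_consecutive_epochs must be >= 1")
        if self.measure not in ("hours", "days"):
            raise ConfigError(f"measure must be 'hours' or 'days', got {self.measure!r}")

    @property
    def outcome_column(self) -> str:
        return "visit_hours" if self.measure == "hours" else "visit_days"


@dataclass(frozen=True)
class CohortWindow:
    """Adoption cohorts to retain and the event-time range to report."""

    adoption_first: str = "2019-04"
    adoption_last: str = "2019-09"
    report_leads: int = 2
    report_lags: int = 3
    reference_period: int = 0

    def __post_init__(self) -> None:
        if self.report_leads < 1 or self.report_lags < 1:
            raise ConfigError("report_leads and report_lags must be >= 1")
        if pd.Period(self.adoption_first, "M") > pd.Period(self.adoption_last, "M"):
            raise ConfigError("adoption_first must not be after adoption_last")

    @property
    def adoption_months(self) -> tuple[str, ...]:
        return month_range(self.adoption_first, self.adoption_last)

    @property
    def reported_event_times(self) -> tuple[int, ...]:
        rng = list(range(-self.report_leads, self.report_lags + 1))
        return tuple(r for r in rng if r != self.reference_period)


SHORTENED_WINDOW = CohortWindow(adoption_first="2019-05", adoption_last="2019-08")


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline run: simulation, visit rules, windows, models."""

    sim: SimConfig = field(default_factory=SimConfig)
    visit_rule_hours: tuple[int, ...] = (2, 3, 4)
    include_day_measure: bool = True
    windows: Mapping[str, CohortWindow] = field(
        default_factory=lambda: {"main": CohortWindow(), "shortened": SHORTENED_WINDOW}
    )
    models: tuple[str, ...] = ("dd", "ddd")
    moderators: tuple[str, ...] = ("none", "consumption_level", "city_tier", "app_count")
    realize_epochs: bool = False
    out_dir: str = "mhdid_run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.models and not self.moderators:
            raise ConfigError("at least one model must be requested")
        for m in self.models:
            if m not in ("dd", "ddd"):
                raise ConfigError(f"unknown model {m!r}")

    def to_dict(self) -> dict:
        return {
            "sim": self.sim.to_dict(),
            "visit_rule_hours": list(self.visit_rule_hours),
            "include_day_measure": self.include_day_measure,
            "windows": {k: dataclasses.asdict(w) for k, w in self.windows.items()},
            "models": list(self.models),
            "moderators": list(self.moderators),
            "realize_epochs": self.realize_epochs,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "log_level": self.log_level,
        }

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimConfig.from_dict(d["sim"])
        if "windows" in d:
            d["windows"] = {k: CohortWindow(**w) for k, w in d["windows"].items()}
        for key in ("visit_rule_hours", "models", "moderators"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        return cls.from_dict(data)
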