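"""End-to-end orchestration: simulate -> visits -> panel -> fits -> exports.

``run_all`` executes the configured matrix of visit rules x cohort windows x
{DD, DDD} plus the moderation battery, writes tidy coefficient tables, a
pre-trend report, an event-study export and a manifest, and logs stage-level
row counts and filter attrition as JSON lines. All randomness flows from the
single run seed, so identical configs produce byte-identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .config import CohortWindow, RunConfig, VisitRule
from .errors import MhdidError
from .fe import FitResult, fit
from .io import write_table
from .panel import build_panel, event_col
from .specs import (
    ModerationSpec,
    dd_design,
    ddd_design,
    ddd_effect_terms,
    moderation_design,
    pretrend_report,
)
from .synth import generate_epoch_streams, generate_outcomes, generate_users
from .visits import exclude_multi_category, exclude_occupations, monthly_duration

log = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _StageLog:
    """JSON-lines structured log of pipeline stages."""

    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def event(self, stage: str, **fields) -> None:
        rec = {"stage": stage, **fields}
        with self.path.open("a") as fh:
            fh.write(json.dumps(rec) + "\n")
        log.info("%s: %s", stage, fields)


def eventstudy_export(fits: Mapping[str, FitResult], window: CohortWindow) -> pd.DataFrame:
    """Plot-ready long table of dynamic effects per model.

    One row per reported event time and model with estimate and 95% CI, plus
    the reference period (r=0, estimate 0) so event-study figures close at
    the omitted category. DD effects come from the event-time terms, DDD
    effects from the used-interacted triple terms.
    """
    rows = []
    for name, res in fits.items():
        is_ddd = res.label.startswith("ddd") or name.startswith("ddd")
        terms = (
            ddd_effect_terms(window)
            if is_ddd
            else tuple(event_col(r) for r in window.reported_event_times)
        )
        for r, term in zip(window.reported_event_times, terms):
            if term not in res.params.index:
                continue
            rows.append(
                {
                    "model": name,
                    "event_time": r,
                    "estimate": float(res.params[term]),
                    "ci_low": float(res.ci_low[term]),
                    "ci_high": float(res.ci_high[term]),
                }
            )
        rows.append(
            {
                "model": name,
                "event_time": window.reference_period,
                "estimate": 0.0,
                "ci_low": 0.0,
                "ci_high": 0.0,
            }
        )
    return pd.DataFrame(rows).sort_values(["model", "event_time"], ignore_index=True)


def run_all(cfg: RunConfig) -> dict:
    """Execute the full configured run; returns (and writes) the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    slog = _StageLog(out / "run_log.jsonl")
    manifest: dict = {
        "mhdid_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": cfg.to_dict(),
        "stages": {},
        "outputs": {},
        "valid": False,
    }
    stage = "init"
    try:
        stage = "simulate"
        sim = cfg.sim.replace(seed=cfg.seed)
        months = list(sim.months)
        users = generate_users(sim)
        truth = generate_outcomes(users, sim)
        slog.event(stage, n_users=len(users), n_truth_rows=len(truth))
        manifest["stages"][stage] = {"n_users": len(users), "n_truth_rows": len(truth)}

        stage = "filter"
        users_f = exclude_multi_category(users)
        slog.event(
            stage,
            multi_category_removed=len(users) - len(users_f),
            occupation_tagged=int(users_f["occupation_tag"].ne("none").sum()),
        )
        manifest["stages"][stage] = {"retained_users": len(users_f)}

        # (measure, rule_k) combinations -> monthly outcome table + column
        stage = "visits"
        measures: list[tuple[str, int | None, pd.DataFrame, str]] = []
        if cfg.realize_epochs:
            truth_f = truth[truth["user_id"].isin(set(users_f["user_id"]))]
            streams, realised = generate_epoch_streams(truth_f, sim)
            slog.event(stage, n_epochs=len(streams))
            for k in cfg.visit_rule_hours:
                vt = monthly_duration(streams, VisitRule(k, "hours"), users_f, months)
                measures.append((f"hours_k{k}", k, vt, "visit_hours"))
            if cfg.include_day_measure:
                k0 = cfg.visit_rule_hours[0]
                vt = monthly_duration(streams, VisitRule(k0, "days"), users_f, months)
                measures.append((f"days_k{k0}", k0, vt, "visit_days"))
        else:
            users_kept = exclude_occupations(users_f)
            truth_kept = truth[truth["user_id"].isin(set(users_kept["user_id"]))]
            measures.append(("hours_latent", None, truth_kept, "hours"))
            slog.event(stage, note="latent hours used directly (no epoch realisation)")
        manifest["stages"][stage] = {"measures": [m[0] for m in measures]}

        stage = "fit"
        fits_main: dict[str, FitResult] = {}
        baseline_dd: FitResult | None = None
        for wname, window in cfg.windows.items():
            for mname, _k, vtable, ocol in measures:
                panel = build_panel(vtable, users_f, window, months, outcome=ocol)
                slog.event(
                    "panel",
                    window=wname,
                    measure=mname,
                    rows=len(panel),
                    users=int(panel["user_id"].nunique()),
                )
                for model in cfg.models:
                    if model == "dd":
                        design, spec = dd_design(panel, window)
                    else:
                        design, spec = ddd_design(panel, window)
                    res = fit(spec, design)
                    tag = f"{model}_{mname}_{wname}"
                    write_table(res.to_frame(), out / f"coef_{tag}.csv")
                    manifest["outputs"][f"coef_{tag}.csv"] = None
                    slog.event("fit", model=tag, n_obs=res.n_obs, n_clusters=res.n_clusters)
                    if wname == "main" and mname in ("hours_k2", "hours_latent"):
                        fits_main[model] = res
                        if model == "dd":
                            baseline_dd = res

        stage = "pretrend"
        if baseline_dd is not None:
            report = pretrend_report(baseline_dd, cfg.windows["main"])
            (out / "pretrend.json").write_text(json.dumps(report.to_dict(), indent=2))
            manifest["outputs"]["pretrend.json"] = None
            slog.event(stage, pvalue=report.pvalue, verdict=report.verdict)

        stage = "moderation"
        if cfg.moderators:
            main_window = cfg.windows["main"]
            mname, _k, vtable, ocol = measures[0]
            panel = build_panel(vtable, users_f, main_window, months, outcome=ocol)
            for moderator in cfg.moderators:
                mspec = ModerationSpec(moderator=moderator)
                design, spec = moderation_design(panel, mspec, len(months))
                res = fit(spec, design)
                write_table(res.to_frame(), out / f"coef_{spec.label}.csv")
                manifest["outputs"][f"coef_{spec.label}.csv"] = None
                slog.event(stage, moderator=moderator, n_obs=res.n_obs)

        stage = "export"
        if fits_main:
            export = eventstudy_export(fits_main, cfg.windows["main"])
            write_table(export, out / "eventstudy.csv")
            manifest["outputs"]["eventstudy.csv"] = None

        for fname in manifest["outputs"]:
            manifest["outputs"][fname] = _sha256(out / fname)
        manifest["valid"] = True
    except Exception as exc:
        manifest["error"] = {"stage": stage, "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise MhdidError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
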