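"""Dynamic difference-in-differences event study with a pre-trend check.

Fits log visit duration on event-time indicators with user and month fixed
effects; the adoption month (r=0) is the omitted reference.
"""
from mhdid import CohortWindow, fit, pretrend_report
from mhdid.benchmarks import recovery_config, simulate_panel
from mhdid.specs import dd_design

window = CohortWindow()  # Apr-Sep adopters, leads 2 / lags 3, reference r=0
cfg = recovery_config(seed=11, n_users=5000).replace(pretrend_effects={-1: -0.02})
panel = simulate_panel(cfg, window)

design, spec = dd_design(panel, window)
res = fit(spec, design)
print(res.summary())
report = pretrend_report(res, window)
print(f"\njoint lead Wald: stat={report.wald_stat:.1f}, df={report.wald_df}, "
      f"p={report.pvalue:.2g}")
print(report.verdict)
print("-> the injected -0.02 cohort pre-trend is picked up by the leads; the DD")
print("   lags are diluted (only ~30% of adopters actually used the app), which")
print("   is exactly why the triple difference is the preferred estimate")
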