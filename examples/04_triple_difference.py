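"""Triple difference: recovering injected dynamic effects.

The DDD contrasts adopters who used the app against adopters who installed
but never used it, absorbing user and month-by-subgroup fixed effects. The
generator's injected truth applies only to the used subgroup, so the DDD
terms should recover it.
"""
from mhdid import CohortWindow, fit
from mhdid.benchmarks import RECOVERY_EFFECTS, recovery_config, simulate_panel
from mhdid.specs import ddd_design, ddd_effect_terms

window = CohortWindow()
panel = simulate_panel(recovery_config(seed=21, n_users=5000), window)
design, spec = ddd_design(panel, window)
res = fit(spec, design)

print(f"{'event time':>10} {'injected':>9} {'estimated':>10} {'95% CI':>20}")
for r, term in zip(window.reported_event_times, ddd_effect_terms(window)):
    truth = RECOVERY_EFFECTS.get(r, 0.0)
    print(f"{r:>10} {truth:>9.3f} {res.params[term]:>10.3f} "
          f"[{res.ci_low[term]:>7.3f}, {res.ci_high[term]:>7.3f}]")
print("-> post-adoption coefficients track the injected truth (a -0.131")
print("   coefficient reads as a ~13.1% drop in visit duration 2 months after")
print("   adoption); pre-adoption terms stay near zero")
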