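# Methods

## Setting and estimands

The package analyses a staggered-adoption panel of mobile-app users observed
over a fixed calendar grid (default Jan–Dec 2019). Every user installs the
focal health-and-fitness app in some month of an adoption window (default
Apr–Sep), so identification comes from *when* a user adopted, not *whether*:
for a cohort adopting in month *a*, users adopting in other months provide
the counterfactual. The outcome is the monthly duration of hospital visits,
reconstructed from hourly at-hospital geolocation epochs, analysed as
log(1 + hours) so coefficients read approximately as percentage changes.

Three estimations are provided:

1. **Dynamic DD (event study).** Event-time indicators `1[t − a_i = r]` for
   r in [−leads, lags] \ {0}, with observations beyond that range binned
   into lead/lag end caps rather than dropped, plus user and calendar-month
   fixed effects. The adoption month r = 0 is the omitted reference: the
   reported window (leads 2, lags 3) mirrors the convention of reporting
   r ∈ {−2, −1, 1, 2, 3} with no r = 0 row. Lead coefficients are the
   parallel-trends diagnostic; a joint Wald test on the leads (χ² with one
   degree of freedom per lead) yields the pre-trend verdict.
2. **Triple difference (DDD).** Adopters split into a *used* subgroup (ever
   opened the app after installing) and a *never-used* baseline. The design
   interacts the event-time indicators with `Used_i` and absorbs
   user(-by-subgroup) and month-by-subgroup fixed effects. The
   **common event-time indicators are retained as controls**: this is a
   deliberate design choice, because only then does a shock shared by both
   subgroups — even one coinciding with adoption timing — lie in the span
   of the controls and drop out of the triple terms exactly (the property
   the immunity test asserts at machine precision). Since users are nested
   in subgroups, user-by-subgroup fixed effects coincide with user fixed
   effects.
3. **Moderation.** The outcome at t + h (default horizon h = 3 months,
   long enough for an exercise habit to produce measurable health effects)
   is regressed on the post-adoption indicator `Post_it = 1[r ≥ 1]` and its
   interaction with one moderator: consumption level (low/medium/high,
   reference low), city tier (1–4, reference tier 4), or the mean-centred
   installed-app count. Rows whose shifted month leaves the data window are
   dropped, not imputed. Two control modes exist because they answer
   different questions: `observables` (month fixed effects plus the full set
   of observable characteristics) lets the time-invariant moderator main
   effects be reported; `user_fe` absorbs them and identifies only the
   interactions. Neither is asserted as canonical — reported main effects of
   time-invariant moderators are inconsistent with user fixed effects, so
   the package implements both and leaves the choice to the caller.

## Outcome construction

Epoch streams carry one record per at-hospital hour (absence means not at
hospital). Maximal runs of consecutive flagged hours are found by a single
vectorised scan; runs spanning a month boundary are split at the boundary so
each hour has an unambiguous month (the alternative — assigning a boundary
run to its start month — is not locally computable per month and was
rejected). A run qualifies when its length ≥ k (default k = 2, reading
"stayed more than an hour" as ≥ 2 whole epochs; k = 3, 4 are sensitivity
variants and k = 1 recovers the raw hour count). A qualifying run
contributes its **full length**, because the estimand is duration of
hospital presence, not visit frequency. The day-count variant counts
distinct days touched by qualifying runs, keeping the two measures
consistent. Visit hours are therefore monotone decreasing in k — a property
test asserts this, along with agreement with a brute-force plain-Python
scan. Physicians and web-based ride-hailing drivers are excluded outright
(their hospital presence is occupational), as are adopters of more than one
app category (cross-category synergies would contaminate the single-app
contrast).

## The synthetic-data generator

The generator emulates the study conditions end to end. Per user i, month t:

    η_it = γ_i + δ_t + Used_i · m_i · β_r + pre_r + shared_r + ε_it
    hours_it = 0                       with probability zero_inflation,
             = min(max(0, exp(η_it) − 1), month capacity)   otherwise,

so log(1 + hours) equals η wherever hours is positive. Defaults and
rationale:

| parameter | default | why |
|---|---|---|
| `n_users` | 5,000 | desk-scale stand-in for the platform's ~2.7×10⁵ users |
| `p_used` | 0.0801 | observed used/installed split (21,444 of 267,651) |
| `true_dynamic_effects` | {1: −0.058, 2: −0.131, 3: −0.184} | realistic effect sizes on the log scale, applied to the used subgroup only — precisely the contrast the DDD isolates |
| `baseline_log_hours` | 1.0 | with `zero_inflation` 0.6 gives ≈2.2 mean monthly hours, matching the descriptive scale of real visit data |
| `user_fe_sd` / `noise_sd` | 1.0 / 0.8 | user heterogeneity dominates idiosyncratic noise, as in utilisation panels |
| `month_fe` | 0.1·sin seasonal | mild common seasonality, small next to user effects |
| `zero_inflation` | 0.6 | most user-months have no hospital contact |
| consumption shares | 0.40/0.40/0.20 | the platform's reported low/medium/high split |
| app count | gamma-Poisson, mean 35.65, shape 1.5 | matches reported mean 35.65 and SD ≈ 30 (overdispersed) |
| adoption months | uniform over window | the empirical adoption-month distribution is unreported; uniform is the maximum-entropy choice |
| occupation tags | 0.5% + 0.5%, +40 h/month | makes the exclusion rule observable in tests |

`pretrend_effects` apply to **all** adopters (a cohort-level trends
violation, which is what lead coefficients detect); `common_dynamic_effects`
are event-time shocks shared by both subgroups, existing so the DDD's
immunity claim is testable. Moderator multipliers scale the used-subgroup
effects multiplicatively and default to off.

**Epoch realisation.** Monthly hours are quantised to the nearest total
representable as a sum of the configured run lengths (default {2, 3}; e.g.
1 hour becomes one 2-hour run), decomposed greedily into runs, and placed at
random non-adjacent positions in the month. The realiser reports the hours
it actually laid down as the ground truth, so the round-trip check
(reconstruction under k = 2 equals truth) is exact by construction whenever
all runs have length ≥ 2; a `run_lengths=(1,)` mix produces streams whose
k = 2 reconstruction is deliberately zero, exercising the failure mode.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: endogenous adoption timing (adoption is
independent of γ_i by construction, so the generator cannot produce the
confounding that motivates the DDD in the field; it can only verify that
the estimator recovers truth when its assumptions hold), serial correlation
of ε within user beyond the user effect, measurement gaps in the geolocation
stream, true GPS noise (streams arrive pre-flagged), and any behavioural
model of app use intensity.

## Estimation engine

Fixed effects are absorbed by alternating projections: sweeps over the FE
dimensions subtracting cell means until the largest absolute cell mean falls
below `demean_tol` (default 1e−8; max 100 sweeps, error with diagnostics on
non-convergence). One dimension converges in a single sweep; balanced
two-way panels in one or two. Regressors absorbed to numerical zero by the
fixed effects raise a collinearity error naming the column, and rank
deficiency is detected by pivoted QR, again naming offenders.

Inference is the CR1 cluster-robust sandwich,
c·(X′X)⁻¹(Σ_g X_g′e_g e_g′X_g)(X′X)⁻¹ with
c = G/(G−1)·(N−1)/(N−K), clustered by user. K counts the regressors plus
the absorbed fixed-effect levels exactly: L for one dimension,
L₁ + L₂ − (connected components of the bipartite level graph) for two —
this matters in the DDD, where the month-by-subgroup graph has two
components and naive level counting would overstate K by one. Confidence
intervals use ±1.96 normal critical values; with thousands of clusters the
t correction is immaterial. The engine is pinned to an explicit
dummy-variable OLS + hand-built sandwich oracle (and cross-checked against
statsmodels) at 1e−8 on small panels.

## Calibration designs (benchmarks)

The Monte-Carlo designs in `mhdid.benchmarks` fix the generator where a
question needs to be well posed, with parameters chosen by a-priori power
analysis:

- **Recovery / null / pre-trend designs** use `baseline_log_hours` = 3.0,
  `noise_sd` = 0.5 and `zero_inflation` = 0. An independent Bernoulli zero
  mask multiplies the expectation of any log-scale outcome by (1 − p) and
  therefore attenuates *every* estimator's estimand relative to the injected
  latent effect — that is a property of the estimand under masking, not an
  estimator defect — so a calibration study of estimator bias must switch
  the mask off. The high baseline keeps the mass at the log(1+·) kink below
  ~0.4%, bounding the clipping attenuation of the largest injected effect
  by ≈0.0007. Recovery uses 5,000 users and p_used = 0.3 (a subgroup large
  enough for per-replication information; the realistic 8% share would only
  inflate Monte-Carlo noise without changing the bias question).
- **Pre-trend power** uses 20,000 users and a −0.02 lead at r = −1 (design
  SE per lead ≈ 0.005, so the joint Wald test has power well above 90%).
- **Moderation ordering** uses 4,000 users, p_used = 1, persistent post
  effects (−0.25 for r = 1..8, because a horizon-3 outcome sees event times
  r + 3 and effects stopping at r = 3 would leave no signal) and consumption
  multipliers {0.25, 1.0, 2.0}, giving an expected high-minus-medium
  interaction contrast of ≈0.13 against a design SE of ≈0.04.

## Numerical and degenerate-input conventions

- Seeded `numpy` Generator streams, one per stage (users / outcomes /
  epochs), so adding a stage never perturbs another's draws; identical
  configs give bit-identical outputs, and the pipeline manifest records
  SHA-256 hashes of every artifact.
- Latent hours are continuous; integers appear only at epoch realisation.
  Hours are capped at the month's calendar capacity (a physical constraint;
  the affected mass is negligible at default scales).
- Ties in epoch-run quantisation go to the lower representable total.
- Empty subgroups, duplicate epochs, off-grid timestamps, missing adoption
  months, horizons exceeding the window, and <2 clusters are hard errors,
  not warnings.
- R² is reported both overall (against the raw outcome) and within
  (against the demeaned outcome).

## Known limitations

- Plain two-way-FE event-study estimates are reported; under effects that
  are heterogeneous *across cohorts*, TWFE weights can be negative
  (Callaway–Sant'Anna / Sun–Abraham critique). The generator injects
  cohort-homogeneous effects, so the benchmark designs are immune; the
  engine's spec layer is the natural extension point for interaction-
  weighted estimators.
- The end-cap binning keeps far-from-adoption observations; trimming to the
  reported event-time window is a configuration away (`CohortWindow`) but
  not the default.
- The log(1 + hours) scale makes coefficients approximate, not exact,
  percentage effects, and under heavy zero inflation the estimand is an
  attenuated version of the latent effect (see above).
- The moderation design inherits the ambiguity about user fixed effects
  versus observable controls; both modes are provided, neither endorsed.
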