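# Methods

## The model

`ptgtwin` represents the parathyroid gland (PTG) of one hemodialysis
patient by two cell populations — quiescent cells `q`, which proliferate
and undergo apoptosis over days to months, and secretory-active cells `a`
— together with a stored intraglandular PTH pool `s` (pg) and the plasma
intact-PTH concentration `c` (pg/ml). Three response functions couple the
gland to its milieu:

* **Calcium sensing.** Activation follows a descending Hill sigmoid,
  `φ(Ca) = 1 / (1 + (Ca/Ca*)^h)`, where `Ca*` is the patient's ionized-
  calcium set-point (half-maximal activation, exactly `φ(Ca*) = 1/2`) and
  `h` the population steepness. This stands in for CaSR signalling: low
  ionized calcium activates secretion within minutes.
* **Phosphate.** Hormone production is modulated by
  `ψ = clip(1 + α_p (P − P*)/P*, 0.2, 3)` around the patient's phosphate
  set-point `P*`.
* **Calcitriol.** Production is suppressed multiplicatively by
  `m_D = 1 − ε_d · calcitriol` under active vitamin-D therapy (binary
  flag).

The state equations (per minute; `g = q + a`):

```
ds/dt = p_rate · g · ψ · m_D  −  d0 (1−φ) s  −  σ_max φ (a/g) s
dc/dt = σ_max φ (a/g) s / V_d  −  k_cl c
da/dt = k_act φ q  −  k_deact (1−φ) a
dq/dt = −k_act φ q + k_deact (1−φ) a  [+ (λ_max φ − μ) q   slow term]
```

Chronic adaptation is expressed through the same structure: low calcium
(high `φ`) lowers intracellular degradation `d0(1−φ)`, shifts cells into
the active pool, and drives proliferation `λ_max φ` of quiescent cells,
so production rises in proportion to gland mass. The three response
functions are pluggable (`ResponseFunctions`) so alternative functional
forms can be substituted without touching the state equations.

### Timescale split

Fast (minutes, gland mass conserved) and slow (days) dynamics are
integrated separately:

* `integrate_fast` — adaptive Runge–Kutta over one dialysis session,
  sampled at 1-minute resolution (tolerances rel 1e−6 / abs 1e−9).
* `advance_slow` — for each day the fast subsystem is placed in its
  closed-form quasi-steady state at that day's inputs and current gland
  mass; gland mass is then advanced by an exact exponential update of
  `dg/dt = (λ_max φ − μ)(1 − f_active) g`. The fast relaxation times
  (seconds to ~20 min) are far below one day, and a full stiff solve of
  the complete system agrees with the quasi-steady engine to well under
  2% on daily iPTH (enforced by test).

Time stamps carry an explicit unit tag (`"min"` / `"day"`); mixing units
is a hard error. State variables are non-negative by construction and
along trajectories (enforced by tests on random parameter draws).

### Population constants

| constant | value | meaning |
| --- | --- | --- |
| `h` | 7 | Hill steepness of calcium sensing |
| `σ_max` | 0.5 /min | maximal secretion rate of stored PTH |
| `k_act`, `k_deact` | 0.05 /min | quiescent↔active transitions (equal rates make the active fraction equal `φ`) |
| `k_cl` | 0.25 /min | plasma clearance (≈2.8 min half-life) |
| `V_d` | 3500 ml | PTH distribution volume |
| `λ_max` | 0.004 /day | maximal proliferation rate |
| `μ` | `λ_max/2` | apoptosis rate — balance calibration (below) |
| `α_p` | 1.0 | phosphate sensitivity |
| `ε_d` | 0.3 | calcitriol production suppression |

All constants live in `defaults.yaml`, not in code. The **balance
calibration** pins `μ = λ_max · φ(Ca*) = λ_max/2`, so a patient sitting
at their set-points has zero net gland growth: the healthy reference is a
fixed point, and sustained hypo-/hypercalcemia produce growth/involution.

## Individualization

Six patient-level quantities are estimated from the 6-month
pre-assessment window (closed interval, assessment day excluded):
`Ca*`, `P*`, gland size, `d0`, the production scale `p_rate`, and plasma
clearance `k_cl`. Inputs are piecewise-constant-forward daily calcium and
phosphate built from the drawn labs; the observables are the iPTH draws.
Residuals are taken on log iPTH (levels span 37–900 pg/ml and errors are
plausibly multiplicative). Minimum data: 3 iPTH, 3 iCa, 2 phosphate draws
in-window; calcimimetic-exposed patients are refused outright (the model
carries no CaSR-agonist pharmacodynamics).

**Anchoring.** `p_rate` is reparameterized so that the model's steady
state at the patient's own set-points equals the earliest in-window iPTH;
the optimizer adjusts a bounded multiplicative offset (0.5–1.5) around
that anchor. This removes the dominant scale degeneracy.

**Identifiability.** Exact structure of the quasi-steady observable
forces three documented reductions:

* `k_cl` cancels exactly between the anchor and the clearance term —
  longitudinal labs carry *no* information about it. It is held at the
  population value and reported as `fixed_population`.
* Gland size cancels out of the anchored observable, so it is determined
  by the vintage prior alone: mean `1 + 0.3 · vintage_years`, sd 50% of
  the mean. Longer dialysis vintage means more cumulative hyperplastic
  stimulus.
* With `α_p = 1` the phosphate modifier is `P/P*` — linear through the
  origin — so production is identified only as the combination
  `p_rate · gland_size / P*`. Recovery of the production scale is
  therefore assessed on this combination.

**MAP estimation.** With ~6 draws per analyte per window, the likelihood
alone cannot pin every remaining parameter, so the fit is a maximum-a-
posteriori estimate with population-scale priors: `Ca* ~ N(1.15, 0.05)`
(the set-point is tightly regulated across patients),
`P* ~ N(1.5, 0.3)`, lognormal sds of 0.5 on `d0` and the anchor offset,
and the vintage prior on gland size. Prior terms are weighted by the
observation-noise scale, which is re-estimated from the stage-one
residuals (two-stage empirical-Bayes weighting): densely sampled,
low-noise records therefore overwhelm the priors, while sparse noisy
records shrink gracefully toward the population.

**Optimization.** Bounded trust-region least squares from 8 Latin-
hypercube starts (fixed seed; deterministic, bit-identical refits), best
final loss wins, ties broken by distance to the prior means. Bounds:
`Ca*` ∈ [0.9, 1.5], `P*` ∈ [0.8, 2.8], gland ∈ [0.25, 6], `d0` within
±50% of the reference, offset ∈ [0.5, 1.5]. A per-parameter
identifiability flag is reported (e.g. the set-point is flagged
unidentifiable when the window's calcium draws have < 0.005 mmol/l
spread — no excitation, no identification).

## Prediction

**Sessions.** Measured intradialytic iCa is interpolated piecewise-
linearly between draws (constant beyond the last); the fast model is
integrated over the treatment from the steady state at the session-start
iCa, the latest phosphate on file, and the fitted gland mass at the
assessment date. Predicted pre/post iPTH are the simulated values at
start and end; the peridialytic change is post − pre (absolute and % of
pre). Initializing instead from a carried-over long-term state is
available through the `initial` argument.

**Six-month engine.** Daily inputs are either forward-filled from the
patient's actual post-index labs (validation mode; forward-fill is
deliberate — linear interpolation would anticipate future draws) or
constant scenario levels: the targeted electrolyte at
`baseline · (1 + fraction)` (±10% iCa, ±25% phosphate) with the other
pinned at its index baseline. The engine is `advance_slow` started from
the fitted gland mass at the index date. Because labs rarely fall on the
exact follow-up day, the headline prediction is the **median of the
predicted daily values within ±3 days of the reference measurement**
(even counts: mean of the middle pair).

## Agreement statistics

Pearson r (two-sided t-test) and tie-corrected Kendall tau-b
(normal-approximation p) via scipy; both are cross-checked against
brute-force definitional implementations in the test suite. Bland–Altman
agreement uses differences oriented measured − predicted, limits of
agreement mean ± 1.96 sample sd, and a proportional-bias test
(correlation of difference with pair mean; its type-I error under a
simulated null is verified at the nominal 5% level). All p-values are
two-sided, no multiplicity correction, significance 0.05.

Eligibility proceeds in two stages: calcimimetic exposure before the
assessment excludes a patient from individualization; any calcimimetic
start, kidney transplantation, facility transfer or death within 180 days
after the assessment additionally excludes them from long-term
validation. Every exclusion carries a reason code; the filter is
idempotent and order-independent.

## Synthetic cohorts

The generator emulates a small maintenance-HD population under routine
care, with all conditions fixed in `SyntheticCohortSpec`:

* n = 26 patients; monthly labs (30 ± 5 days jitter) over ±180 days
  around the assessment; 240-minute sessions.
* Vintage lognormal with median 218 days (log-sd 1.0); calcitriol
  Bernoulli(1/2); set-points truncated-normal 1.15 ± 0.05 on [1.0, 1.3];
  `P*` ~ N(1.5, 0.15); `d0` lognormal (log-sd 0.2) around 0.1/min; gland
  size vintage-linked with lognormal noise (log-sd 0.15). Baseline iPTH
  is drawn lognormally around a median of 326 pg/ml (log-sd 0.5, clipped
  to [50, 900]) and `p_rate` is set through the anchor identity so each
  patient's steady state reproduces it. Clearance is undispersed — it is
  structurally unidentifiable from longitudinal labs (above), and
  clearance in anuric patients is not a major axis of heterogeneity.
* Latent daily iCa and phosphate follow bounded reflecting random walks
  (steps 0.004 and 0.010 per day), so genuine 6-month trends exist for
  the slow engine to exploit; true daily iPTH comes from `advance_slow`
  on the latent paths. Observed labs add noise: iCa ± 0.02 mmol/l,
  phosphate 8% CV, iPTH 10% CV (multiplicative lognormal).
* Study sessions: blood iCa approaches the dialysate-side ionized level
  `ca_d ~ N(1.50, 0.05)` exponentially with time constant τ ~ U(240,
  420) min, sampled hourly. τ was calibrated so the cohort reproduces the
  observed intradialytic kinetics (pre-HD median ≈ 1.17, rise ≈ 0.17–0.19
  mmol/l over 240 min); a fast τ would drive blood calcium implausibly
  close to the dialysate level. The session's pre-HD iCa is the patient's
  own ambient calcium that morning plus a small peridialytic offset
  (± 0.02), and the session's true pre/post iPTH are simulated at the
  patient's true parameters and true gland mass on the session day.
* A ground-truth sidecar (true parameters, latent paths, daily true
  iPTH) is written next to the observables and never read by the
  pipeline. Optional dropout events (transplant, calcimimetic start,
  transfer, death) exercise the eligibility filter.

**What the generator does not emulate:** assay drift and censoring,
intra-day calcium excursions between sessions, ultrafiltration and
hemoconcentration within sessions, drug changes other than a static
calcitriol flag, and dialysate-side mass-balance measurement. Passing
tests therefore demonstrate internal consistency of the method under
realistic sampling and noise — not clinical performance on real
patients.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline on
26-patient cohorts (one noisy at study conditions, one dense noise-free
for identifiability), 20-draw oracle comparisons, and 500-replicate null
simulations. Every stochastic component is driven by an explicit seed;
identical (bundle, config, seed) reproduce outputs bit-identically.

## Known limitations

* The short-term validation correlation on synthetic cohorts is
  information-limited: with monthly draws and 10% iPTH noise the
  set-point posterior is dominated by the population prior (median
  absolute error ≈ 2–4%), and the steep Hill curve (h = 7) amplifies the
  residual error into the predicted session drop. Across generator seeds
  the cohort correlation between true and predicted peridialytic change
  ranges ≈ 0.86–0.97.
* `k_cl` being unidentifiable from labs, session simulations inherit the
  population clearance; intradialytic decay-curve data (not part of the
  fitting record) would identify it.
* The paper-facing quantities (limits of agreement, cohort medians) are
  functions of the clinical dataset; on synthetic cohorts they
  characterize the generator, not the clinic.
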