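# Methods

## Trial model

One replication simulates a two-arm (1:1 block-randomized) trial of
`n_total` patients enrolled uniformly over `enroll_duration` months.
Subgroup membership is Bernoulli with the design prevalence.  For each
endpoint (PFS, OS) the event time is exponential with rate log(2)/median in
the control arm, multiplied by the endpoint × stratum hazard ratio in the
experimental arm; the subgroup and its complement have separate control
medians and hazard ratios.  Dropout is exponential with monthly rate
−log(1 − annual_rate)/12, reading the stated yearly dropout rates as annual
probabilities.  All analyses censor each patient at
min(event, dropout, cutoff − enrollment).

The two endpoints' event processes are generated **independently per
patient**: PFS ≤ OS orderings are not enforced and there is no shared
frailty.  This is deliberate (see *Limitations*): it makes the stage-1 PFS
futility gate uninformative about OS by construction, which is the main
reason simulated OS power for the adaptive designs sits a few points below
published values generated with a dependent progression/survival process,
while the classical GSD comparator (no gate) matches them closely.

## Stage-1 futility and its calibration

The gate compares Cox partial-likelihood estimates of the PFS hazard ratio
in F and S against thresholds θ^F, θ^S (strict `HR < θ` passes).  θ is
calibrated from log(HR) ~ N(log HR_alt, 4/d) so a truly effective treatment
(HR_alt = 0.7) fails with probability γ = 0.05.  The stage-1 analysis time
is not part of the published parameter tables; we define it as the calendar
time at which the trial reaches the PFS event counts that *imply* the
printed thresholds, d = ⌈(2 z₁₋γ / log(θ/HR_alt))²⌉ — 288 (F) and 172 (S)
events for setting 1; 374 and 288 for settings 2–3.  This is the unique
reading under the design's own normal approximation; it puts roughly 70–80%
of enrollment (and of stage-wise events) in stage 1, consistent with the
published event-driven weights behaving like (√0.8, √0.2).  Patients
enrolled up to that time form the stage-1 cohort; their later follow-up
accrues to the stage-1 p-values.  The futility rule is non-binding in the
usual regulatory sense; the simulator always enforces it, and a test
verifies that disabling it can only increase rejection rates.

Under S-only continuation, stage 2 enrolls subgroup patients only (the
complement patients already enrolled stay on follow-up and contribute to
the stage-1 intersection p-values); under F-only continuation the full
population continues and the subgroup is not tested further.

## Analysis schedule and event targets

Stage 2 has two interim analyses and a final analysis.  PFS is final at
IA2; OS at FA.  Boundaries for each hypothesis use its *design* information
fractions — F: PFS (0.90, 1), OS (0.69, 0.92, 1); S: PFS (0.89, 1),
OS (0.66, 0.91, 1) — with the one-sided Lan–DeMets O'Brien–Fleming
approximation f(t) = 2(1 − Φ(Φ⁻¹(1 − α/2)/√t)).

The planned final analysis is set at `enroll_duration + 24` months.  The
24-month post-accrual follow-up is a design choice made once: it is a
typical oncology OS horizon and, under the exponential/accrual model, gives
every one of the four hypotheses at least ~85% marginal power at its
initial GSD alpha — the stated sample-size basis of the packaged settings.
Design final event counts are the model-expected events at that time
(closed form under exponential events/dropout and uniform accrual);
per-analysis targets are those counts times the information fractions.
Each stage-2 analysis is triggered when the continued analysis population
(F, or S under S-only continuation) reaches its OS event target; PFS is
tested at the same calendar cutoffs, where its observed information lands
near the design fractions automatically.  If a target is unreachable the
analysis runs at end of follow-up and the outcome is flagged.

## Testing machinery

* **Stagewise p-values.**  One-sided log-rank tests (unweighted,
  hypergeometric tie-corrected variance), oriented so experimental benefit
  gives z > 0, computed separately for the stage-1 and stage-2 cohorts of
  each population at every cutoff.  Snapshots with no events or one arm
  contribute p = 1 (conservative).
* **Combination.**  z = w₁Φ⁻¹(1−p₁) + w₂Φ⁻¹(1−p₂) with pre-specified
  weights per endpoint (eight packaged configurations; the event-driven set
  recomputes weights from observed stage event counts and is reference-only
  since it cannot be pre-specified).  p-values are clamped to
  [1e-16, 1−1e-16] before inversion.
* **Closed testing.**  An elementary hypothesis is rejected at analysis k
  iff its combined z meets its boundary *and* the two-population
  intersection (Hochberg p-value with equal weights, minimum component
  boundary) has been rejected at this or an earlier analysis.  The stage-2
  component of the intersection follows the continuation scenario: the
  continued population's p-value, or the Hochberg combination of both when
  both continue.  Rejections are permanent; a boundary attained counts as a
  rejection (z ≥ c).
* **Gate (gGSD).**  Under two-population continuation, F hypotheses are
  tested — with their own full-α budget — only from the analysis at which
  the first S rejection occurs.
* **Alpha reallocation.**  A rejected hypothesis's current α moves to the
  other endpoint of its population; for GSD/AD, an exhausted population
  passes its α to the other population's PFS (or OS if PFS is past its
  final look or rejected).  The published tables require this
  cross-population transfer: with α^{F,OS} = 0.025% in setting 2, the
  printed joint power is only attainable when the subgroup's α migrates to
  F after both subgroup rejections.  Within gGSD, reallocation never
  crosses populations.  Receiving hypotheses get boundaries recomputed at
  the new α over their full design fractions, applied prospectively;
  unplaceable α is dropped (conservative).
* **GSD comparator.**  No futility, no combination: pooled-cohort log-rank
  tests against the same style of boundaries, graphical reallocation only.
* **Stopping.**  GSD stops early iff all four hypotheses are rejected;
  AD/gGSD stop at futility when both populations fail the gate, and stop
  early iff every hypothesis tested so far is rejected; otherwise the trial
  runs to FA.

## Boundary computation

Group-sequential z boundaries solve, look by look, for the incremental
crossing probability equal to the spending increment under the canonical
joint normal (corr = √(t_i/t_j)).  The recursion propagates the
sub-density of non-crossed sample paths on the score scale over an 801-node
trapezoid grid spanning ±8 SD, solving each boundary by bisection; total
crossing probabilities match the spending function to better than 1e-6 and
brute-force multivariate-normal crossing probabilities to 1e-4 (tested).
Boundaries are cached by (fractions, α).  Probabilities below 1e-16 map to
a z-cap of 8.5.

## Summaries and conventions

`power_S` / `power_SF` report the probability of rejecting the OS
hypothesis in S (and in both populations) — the definition consistent with
the published comparator values, where OS is the confirmatory endpoint;
`power_S_any` / `power_SF_any` count at least one rejected endpoint per
population.  Subgroup power conditions on S passing the futility gate
(published denominator); unconditional variants are also reported.  FWER is
the fraction of replications rejecting any elementary hypothesis under the
global null (every hazard ratio forced to 1, making settings 2 and 3
coincide).  Replication seeds are deterministic spawns of the master seed;
identical configuration and seed give byte-identical summaries.

## What the generator does and does not emulate

It emulates: uniform accrual, subgroup mixture structure, proportional
hazards with stratum-specific baselines, annual dropout, event-driven
analysis timing, and the seamless stage-1/stage-2 cohort split.  It does
not emulate: PFS–OS dependence within patient, non-proportional hazards or
delayed effects, accrual pauses during the futility review, cure fractions,
or stratified randomization.  Passing tests therefore certify the decision
machinery and its error control under a clean proportional-hazards world,
not the operating characteristics of any real trial.

## Numerical and degenerate-input choices

Cox estimation is Newton iteration on the single binary covariate with
Breslow ties (damped steps, |β| ≤ 15); monotone likelihood returns a
flagged sentinel (HR 0 or ∞) that simply fails the futility gate, and
non-convergence falls back to the flagged one-step efficient-score estimate
exp((O−E)/V).  Log-rank snapshots with zero events or a single arm raise a
typed no-information error that callers convert to p = 1.  Ties in event
times use exact risk-set decrements with the (n−d)/(n−1) variance
correction.  Event-driven weights default to (√0.5, √0.5) in the (never
observed at realistic sizes) case of zero events in both stages.

## Known limitations

* The stage-1 split and the planned study duration are back-solved from the
  printed futility thresholds and the stated power basis, not printed
  values; adaptive-design power is sensitive to the stage split when
  stage-2-heavy combination weights are used.
* Independent endpoint generation removes the futility-conditioning power
  gain a dependent progression/survival process would give the adaptive
  designs (~2–4 points on subgroup OS power in our measurements).
* Boundaries use design information fractions; observed fractions drift
  around them, which is standard practice but differs from recomputing
  boundaries at observed information.
* Two populations and one subgroup level only; no multi-arm extension.
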