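# Methods

This note documents the model implemented in `hfcea`: its structure,
parameters, accounting conventions, the synthetic-data generator, and the
design choices made where the published description left the design open.

## Model structure

A closed cohort of HFrEF patients aged 66 at entry is simulated over
quarterly (3-month) cycles, 40 cycles by default. Six states are tracked:
NYHA classes I–IV (alive) and two absorbing death states. Death is split by
cause — cardiovascular (CV) versus non-cardiovascular — purely for
accounting: it lets the model report cause-specific cumulative mortality for
validation against trial outcomes; "dead" occupancy is the sum of the two.

Per cycle, the 6×6 transition matrix for an arm at attained age *a* is
assembled as:

* `P(NYHA_i → DEAD_CV) = p_cv` — the arm-level per-cycle CV death
  probability;
* `P(NYHA_i → DEAD_NONCV) = p_ncv(a)` — the age-banded background
  probability;
* `P(NYHA_i → NYHA_j) = (1 − p_cv − p_ncv) · M[i][j]` — the NYHA class
  matrix applied to survivors;
* death rows are identity.

Competing risks are combined additively and NYHA redistribution applies only
to survivors. The source publication gives no within-cycle ordering; with
per-cycle death probabilities of ~2% the difference between additive and
multiplicative composition is below 4·10⁻⁴ per cycle, and the additive rule
is the simplest construction that keeps every row exactly stochastic. It is
the only supported convention.

Hospitalization for HF is an *event* overlaid on the state process: it does
not shift NYHA occupancy. The at-risk population in cycle *k* is the alive
fraction at the start of the cycle; expected hospitalizations are
`alive_start(k) · p_hosp`, and expected readmissions are a fixed fraction
0.1189 of hospitalizations within the same cycle, applied once (not
recursively). A death in the same cycle does not retroactively remove a
patient from the hospitalization risk set.

Age bands for non-CV mortality switch at exact cycle boundaries based on the
attained age (bands `[65,70)`, `[70,75)`, `[75,80)` per cycle). For horizons
that outlive the last band (beyond age ~80, e.g. the 15- and 20-year
scenarios) the last band's probability is carried forward — a documented
extrapolation, conservative in that late-life background mortality is
understated.

## Key parameters

| Parameter | Default | Units / notes |
|---|---|---|
| CV death per cycle | 0.01650 / 0.01994 / 0.01956 / 0.02120 | dapagliflozin, control 1, empagliflozin, control 2 |
| HF hospitalization per cycle | 0.01668 / 0.02344 / 0.02619 / 0.03719 | same order |
| Readmission per hospitalization | 0.1189 | within the same cycle |
| Non-CV death per cycle | 0.2430% / 0.3042% / 0.4185% | ages 65–69 / 70–74 / 75–79 |
| Utilities per cycle | 0.2035 / 0.18 / 0.1475 / 0.127 | NYHA I–IV, QALY per 3-month cycle |
| Event disutility | −0.1 | one-off QALY toll per hospitalization or readmission |
| Standard treatment | $118.95 / cycle | 2020 USD (inflated from $102.75 at 5%/y over 3 y) |
| Drug cost | $60.93 / $59.25 per cycle | dapagliflozin / empagliflozin |
| Hospitalization event | $1,785.36 | municipal-hospital level; $964.07–3,209.47 across levels |
| Discount rate | 5% / year | sensitivity range 0–8% |
| WTP threshold | $11,008.07 / QALY | 1× 2019 Chinese GDP per capita |

The per-cycle event probabilities are stored at the published 5-decimal
precision; they reproduce from the source trials' cumulative proportions
(9.6/11.5/10.0/10.8% CV death; 9.7/13.4/13.2/18.3% hospitalization over
18.2/16-month follow-ups) via the constant-hazard conversion to within
5·10⁻⁶, which the test suite asserts.

Two probability interpretations are configurable. The age-banded non-CV
probabilities are read as per-cycle values, consistent with every other
probability row of the input table; `noncv_mortality_is_annual: true`
re-reads them as annual probabilities rescaled to a cycle under a constant
hazard. Trial-matched pairing is fixed: dapagliflozin is compared only to
its own trial's control arm, empagliflozin to its own.

## Accounting conventions

* **Half-cycle correction** (default on): state-occupancy cost and QALY
  terms use the mean of start- and end-of-cycle occupancy, so a patient who
  dies contributes half a cycle of person-time in the cycle of death. Event
  terms are counted in full in the cycle they occur.
* **Discounting**: factor `1.05^(−t)` with `t` the mid-cycle time
  `(k+0.5)·0.25` years by default (`discount_convention: start_of_cycle`
  uses cycle-start times). The ICER is invariant to this choice, since it
  rescales costs and QALYs by a common factor.
* **Event disutility tolls are undiscounted by default**
  (`discount_event_disutility: false`). This is the single convention choice
  that was fixed empirically: with the tolls discounted like every other
  QALY term, the model's incremental QALYs under-shoot the published
  incrementals by 1–4% and the empagliflozin ICER lands ~8.7% above the
  published value; with undiscounted tolls the incremental QALYs match the
  published incrementals to four decimals (0.2277 and 0.1254 vs implied
  0.22799 and 0.12535) and both ICERs land within 5% of the published
  base-case figures (+1.1% and +4.2%). The flag restores the fully
  discounted variant.
* **Dominance**: an ICER is reported as a number only when ΔQALY > 0 and
  ΔCost > 0; otherwise a tag (dominant / dominated / no difference /
  cheaper-but-less-effective) is attached and the net monetary benefit
  carries the verdict. Cost-effectiveness categories follow the WHO
  GDP-multiple convention at 1× and 3× GDP per capita.

A note on the published ICER table: the published base-case ICERs are
exactly the ratios of the *rounded* incrementals (e.g. 1,274.43/0.23 =
5,541.00), while the scenario table's 10-year rows hold the unrounded ratios
(5,589.93 and 7,204.65). This model's base case reproduces the unrounded
ratios to within 0.5%.

Median survival is read off the cohort survival curve as the first
cycle-boundary time at which the alive fraction is ≤ 0.5 (a censored result
beyond the horizon is reported as such, not an error). Under this rule the
model gives 9.00/7.75 years for the dapagliflozin pair where the source
reports 8.75/7.50 — one cycle later. Because the model's occupancy dynamics
otherwise match the published incrementals to four decimals, the discrepancy
is attributed to an unreported curve read-off convention in the source; no
single alternative rule (interpolated crossing, floor/ceiling to the grid,
cycle-averaged curve) reproduces all four published medians simultaneously,
so the transparent boundary rule is kept.

## Sensitivity analyses

**One-way (tornado).** Each declared parameter is set to its low and high
bound with everything else at base case; entries are ordered by the absolute
ICER spread. A perturbation that violates a model invariant is flagged
invalid rather than clamped. The base parameter set is never mutated.

**Scenarios.** Named override sets rerun the deterministic model:
hospitalization cost at five hospital levels ($964.07–$3,209.47) and time
horizons of 5/10/15/20 years. The diabetes-status scenario ships as a
template only — the subgroup transition probabilities were not published, so
the user must supply them as overrides.

**Probabilistic.** Every uncertain scalar is sampled independently per draw:
Beta for probabilities and utilities (the event disutility is fitted on its
magnitude and negated), Gamma for costs, and each NYHA matrix row jointly
from a Dirichlet with concentration `row × 1000` (structural zeros
preserved; switchable off via `sample_nyha_matrix`). Published ranges are
read as 95% confidence intervals: `sd = (high − low)/(2·1.96)`, then
method-of-moments. The fitted mean equals the input mean to 1e−9 and the
95% central interval of the fitted Beta recovers the declared range (both
asserted in tests). Draws with ΔE ≤ 0 are retained; acceptability curves are
computed pointwise as the fraction of draws with positive net monetary
benefit, so no draws are discarded. The whole PSA is driven by one seeded
PCG64 generator and is reproducible bit-for-bit.

Under this 95%-CI reading the 1,000-draw PSA yields a probability of
cost-effectiveness at the $11,008.07 threshold of ~92–94% (dapagliflozin
pair) and ~72% (empagliflozin pair), compared with published values of 70.5%
and 55.2%. The published description does not state how ranges were mapped
to distribution parameters; reproducing the published probabilities would
require roughly twice the standard deviation (ranges read as mean ± 1 sd).
The documented, conventional 95%-CI rule is kept rather than fitting the
width to the published probabilities; users can explore wider uncertainty by
supplying wider ranges in the config.

Known quirk retained verbatim from the inputs: the standard-treatment cost
range ($118.95–556.21, labelled 95% CI) has its mean at the lower bound —
the upper bound reflects substitution of sacubitril/valsartan. The Gamma fit
uses the implied (large) sd; the resulting right-skewed draws affect both
arms identically and largely cancel in the incrementals.

## Patient-level microsimulation (synthetic data)

`hfcea.microsim` simulates individual patients under *exactly* the per-cycle
law the cohort engine uses — same matrices, same event probabilities, at most
one hospitalization and one readmission per patient per cycle. It serves
three roles: an independent oracle for the cohort engine (empirical
occupancies, event totals, and per-patient discounted costs/QALYs are
checked against the deterministic expectations within 3 Monte-Carlo standard
errors at n = 200,000 per arm in the acceptance suite); a generator of
patient-history datasets for external inspection; and a trial synthesizer —
patients exposed to a constant per-cycle event probability over a follow-up
window yield the cumulative event proportion a trial would report, closing a
parameter-recovery loop on the constant-hazard conversion for all eight
trial-derived probabilities.

What the generator does *not* emulate: patient-level covariates,
NYHA-dependent or time-varying treatment effects, treatment discontinuation,
correlated risks, or overdispersed hospitalization counts. Passing oracle
tests therefore demonstrates internal consistency of the two engines under
the stated model, not fidelity of that model to real-world HFrEF cohorts.
Follow-up windows that are not whole multiples of a cycle (18.2 months) are
rounded to the nearest cycle by the trial synthesizer, and the recovery
tests use the rounded window as their truth.

## Numerical choices and degenerate inputs

* Matrix rows are validated to sum to 1 within 1e−9 (inputs) and assembled
  rows within 1e−12; occupancy conservation is asserted at 1e−9 per cycle.
* Degenerate uncertainty ranges (low = high) are treated as fixed parameters
  in the PSA and yield zero tornado spread; a Beta fit whose implied
  variance is unattainable raises rather than silently truncating.
* A trial event proportion of 1 (infinite hazard) and annual probabilities
  of 1 are rejected as domain errors; an event proportion of 0 maps to
  probability 0.
* Horizons must be whole multiples of the cycle length; a zero-cycle horizon
  produces a single-boundary trace with no events.
* The microsimulation encodes states as small integers and draws transitions
  by inverse-CDF against row cumulative sums (final entry pinned to 1 to
  absorb round-off), keeping trajectories reproducible across platforms.

## Problem sizes

Default analyses use the published sizes: 40 quarterly cycles, 1,000 PSA
draws. Oracle comparisons run 200,000 simulated patients per arm and the
parameter-recovery trials 100,000 patients per arm — sizes chosen so that
3-standard-error bands are a factor of a few tighter than the effects being
verified; all complete in seconds on a single CPU.

## Limitations

Beyond the generator's simplifications above: adverse-event costs and
disutilities are excluded; non-HF hospitalizations are excluded; treatment
effects are constant over the horizon; hospitalization risk is arm-level
(not NYHA-specific); and background mortality beyond age 79 extrapolates the
last age band. The diabetes subgroup analysis requires user-supplied inputs.
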