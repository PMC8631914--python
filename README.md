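# hfcea

Markov cohort cost-utility model of adding SGLT2 inhibitors (dapagliflozin or
empagliflozin, 10 mg once daily) to standard therapy for Chinese patients with
heart failure and reduced ejection fraction (HFrEF), from the perspective of
the Chinese healthcare system.

The package is aimed at health-economics practitioners who want a tested,
scriptable implementation of this analysis: the deterministic base case,
one-way and scenario sensitivity analyses, a seeded probabilistic sensitivity
analysis (PSA) with cost-effectiveness acceptability curves, and a
patient-level microsimulation that serves as an independent oracle for the
cohort engine.

## The model

A cohort of 66-year-old HFrEF patients is followed over 40 quarterly cycles
(10 years) through six states: NYHA functional classes I–IV plus two absorbing
death states (cardiovascular and non-cardiovascular). Each cycle, arm-level
probabilities of CV death and the age-banded probability of non-CV death apply
first; survivors redistribute among NYHA classes via a fixed 4×4 quarterly
transition matrix. HF hospitalization is an event overlaid on the state
process (probability per cycle among patients alive at cycle start), and each
hospitalization carries a fixed readmission probability (0.1189) within the
same cycle.

Per-cycle event probabilities are derived from cumulative trial event
proportions by the constant-hazard (DEALE) conversion

    r = −ln(S)/t,   P = 1 − e^(−r)

with S the event-free fraction over t cycles of follow-up — e.g. 9.6% CV
mortality over 18.2 months → P = 0.01650 per quarter.

Costs (2020 USD, converted at 6.44 CNY/USD) accrue as per-cycle standard
treatment ($118.95) plus drug cost for the intervention arms, plus $1,785.36
per hospitalization or readmission event. Utilities are per-cycle QALY
weights by NYHA class (0.2035/0.18/0.1475/0.127) with a one-off −0.1 QALY
toll per event. State terms use half-cycle-corrected occupancy and are
discounted at 5%/year at mid-cycle times; the event QALY tolls enter
undiscounted by default (the convention that reproduces the published
results; see `docs/methods.md`). Strategies are compared by the incremental
cost-effectiveness ratio ΔC/ΔE against a willingness-to-pay threshold of 1×
2019 Chinese GDP per capita ($11,008.07/QALY).

## Worked example

```python
from hfcea import MarkovCEA

res = MarkovCEA.paper_defaults(pair="dapa").fit()
print(res.summary())
```

prints

```
                    Markov cohort cost-utility analysis
============================================================================
Pair: dapagliflozin vs control1    Horizon: 10 y (40 cycles)    Discount: 5%
----------------------------------------------------------------------------
strategy          total cost ($)   total QALYs
dapagliflozin           4,855.77          3.87
control1                3,579.56          3.64
----------------------------------------------------------------------------
Incremental cost: $1,276.21    Incremental QALYs: 0.23
ICER: 5,603.90 $/QALY    category: very_cost_effective
NMB at WTP $11,008.07/QALY: $1,230.72
----------------------------------------------------------------------------
dapagliflozin    median survival 9.00 y; at 18 mo: all-cause death 10.8%, CV death 9.44%, HF hosp. 9.5%
control1         median survival 7.75 y; at 18 mo: all-cause death 12.7%, CV death 11.31%, HF hosp. 13.3%
============================================================================
```

Adding dapagliflozin costs $1,276 more per patient over ten years but yields
0.23 extra quality-adjusted life years, an ICER of ~$5,604/QALY — under half
the GDP-per-capita threshold, hence "very cost-effective" by the WHO
convention. The validation block shows the model's predicted 18-month
mortality and hospitalization against the source trial's figures.

Sensitivity analyses hang off the results object:

```python
res.owsa()                        # tornado entries, widest spread first
res.scenario("horizon_20")        # ICER 4,135.35 at a 20-year horizon
psa = res.psa(n_draws=1000, seed=1)
psa.probability_ce(11008.07)      # probability cost-effective at the WTP
res.plot_ceac(psa=psa)            # acceptability curve
```

The same surfaces are available from the shell:

```bash
hfcea base-case --pair dapa --out out/
hfcea scenario --label horizon_20 --out out/
hfcea psa --n-draws 1000 --seed 1 --out out/
hfcea simulate --n 10000 --seed 1 --out out/   # patient-level microsimulation
```

Every command writes CSV/JSON outputs plus a `manifest.json` recording the
config, seed and outputs needed to reproduce the run.

## Configuration

All inputs (arm probabilities, NYHA matrix, mortality bands, utilities, costs,
run settings, uncertainty ranges) live in a YAML document; the bundled
defaults at `src/hfcea/data/defaults.yaml` double as the schema reference.
A user config passed via `--config` (or `MarkovCEA.from_config`) may override
any subset of fields — probabilities as decimals, money in USD — and is
validated on load (row sums, probability bounds, horizon divisibility), with
errors naming the offending path.

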