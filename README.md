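# stroke-cea

A decision-analytic model of pre-hospital stroke identification in
Australian women: a 3-month decision tree (emergency-service identification
→ thrombolysis within 60 minutes vs usual care → adverse events → 90-day
modified Rankin Scale outcomes) chained to a 50-year annual-cycle Markov
cohort model with recurrent stroke, background mortality, QALY weighting,
cost accrual and 5% discounting.

It compares two arms that differ in a single input — the probability that
emergency medical staff correctly identify a stroke (0.35, the accuracy men
receive, vs 0.29, the status quo for women under 70) — and reports the
per-person and population-level differences in life years, QALYs and
societal costs (2022 AUD), with one-way (tornado) and probabilistic
sensitivity analyses.  It is written for health economists and stroke
services researchers who want a transparent, scriptable re-implementation
of this class of cost-effectiveness model.

## The model in brief

For identification accuracy $p$, the 90-day state vector is the mixture

$$\pi_{90} = p\,q\,[(1-a)\,D_{\text{IVT}} + a\,D_{\text{AE}}] + (1 - p\,q)\,D_{\text{UC}}$$

with $q = 0.41$ the probability of thrombolysis within 60 minutes, $a=0.02$
the adverse-event probability and $D$ the published 90-day mRS rows.
$\pi_{90}$ seeds a Markov chain over mRS 0–5 + dead in which each alive
state faces recurrence (0.10 in year 1, 0.02 after; case fatality 0.0866,
survivors move to an equally likely worse state), else age-indexed
background mortality $q_x$, else stays put.  Discounted accrual:

$$\text{QALY} = \sum_{t=1}^{50} 1.05^{-(t-1)} \, \bar\pi_t \cdot u_t,$$

where $\bar\pi_t$ is the (half-cycle-corrected) occupancy and $u_t$ the
year-1 or chronic utility vector; costs accrue analogously from per-state
medical/non-medical/indirect triples plus one-off thrombolysis, first-year
death and recurrence costs.  See `docs/methods.md` for every convention.

## Worked example

```python
from stroke_cea import default_parameter_set, default_lifetable, run_base_case

params = default_parameter_set()      # the published input tables
lifetable = default_lifetable()       # bundled synthetic female life table
comp = run_base_case(params, lifetable)
print(comp.summary())
```

prints

```
Two-arm comparison (per person, discounted)
----------------------------------------------------
                  life years     QALYs    cost (AUD)
hypothetical         13.0554    6.6852       384,862
status quo           13.0549    6.6482       387,627
difference            0.0004    0.0370        -2,765
```

Reading: identifying women with men's accuracy leaves survival essentially
unchanged (mortality after the first year is the same in every alive state,
so the arms' survival curves nearly coincide) but shifts survivors toward
milder disability states, which is worth **0.037 QALYs gained and 2 765 AUD
saved per woman** over 50 years.  Scaled to the 1 798 women nationally who
have an ischaemic stroke and are likely to receive timely thrombolysis each
year (`national_multiplier(7471, 0.83, 0.29)` → 6 201 ischaemic strokes →
1 798 women), that is roughly 66 QALYs and 5.0 million AUD per year.  The
bundled life table is synthetic (life expectancy 28.8 years at age 57.8);
pass an official `age,sex,qx` CSV for registry-exact levels — between-arm
differences are insensitive to this choice.

The command-line interface exposes the same pipeline:

```bash
stroke-cea base-case --out out/base
stroke-cea owsa      --out out/owsa            # tornado table, sorted
stroke-cea psa       --out out/psa -n 10000 --seed 7 --wtp 50000
stroke-cea make-fixtures --out out/fixtures    # life table + editable config
```

Every run writes CSV/JSON results plus a manifest recording inputs, seeds
and convention switches; identical inputs and seeds give byte-identical
result files.

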