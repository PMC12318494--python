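# Methods

## The question the model answers

Emergency medical services identify stroke less accurately in women under 70
than in men (28.9% vs 35.0% in the linked ambulance/hospital data the input
tables derive from).  Because accurate pre-hospital identification is the
gate to priority transport and thrombolysis within the 60-minute
door-to-needle window, the gap translates into worse 90-day outcomes for
women.  The model quantifies what Australian women would gain — in life
years, quality-adjusted life years (QALYs) and societal costs — if they were
identified with the accuracy currently achieved for men, all else equal.

## Model structure

**Short-term decision tree (3 months).**  A cohort of women enters at the
moment of an ischaemic stroke.  With probability `p_accurate` the stroke is
identified in the pre-hospital setting; only then can intravenous
thrombolysis (IVT) be delivered within 60 minutes of hospital arrival
(probability 0.41).  Thrombolysed patients suffer an adverse event with
probability 0.02, in which case the adverse-event 90-day outcome row
*replaces* the thrombolysis row.  Accurately identified patients who miss
the window, and all misidentified patients, receive usual care.  Each branch
ends in a 90-day distribution over the modified Rankin Scale (mRS 0–5 alive,
6 dead); the tree's output is the path-weighted mixture.  The two arms
differ *only* in `p_accurate`: 0.35 (hypothetical) vs 0.29 (status quo).

**Long-term Markov model (50 annual cycles).**  The 90-day vector seeds a
cohort model over the seven mRS states.  Each cycle an alive patient
experiences exactly one of: recurrent stroke (probability 0.10 in year 1,
0.02 thereafter), death from background mortality, or no event.  A recurrent
stroke is fatal with probability 0.0866; survivors move to one of the
strictly-worse alive states with equal probability (from mRS 5, where no
worse alive state exists, survivors remain in mRS 5).  Recurrence is
resolved first; background mortality applies to the non-recurrent mass only.
Background mortality is the age-indexed female annual death probability
`qx`, looked up at the floored attained age (the cohort starts at 57.8 years
and ages one year per cycle); beyond the terminal table age `qx` is clamped
to 1.

**Year-1 mortality reconciliation.**  The inputs give both a 90-day death
mass (inside the tree) and a 12-month all-cause death probability of 0.12
without stating how they compose.  We treat 0.12 as the *total* first-year
death probability: cycle 1 replaces background mortality with the residual
conditional risk `max(0, (0.12 − d90)/(1 − d90))` applied to 90-day
survivors, which avoids double-counting the tree deaths.  This is one
defensible reading; the alternative (adding 0.12 on top of the tree deaths)
changes per-person levels by well under 1% and changes no conclusion.

## Accrual conventions

* **Discounting** at 5% per annum; cycle 1 undiscounted, cycle *t* weighted
  `1.05^-(t−1)` ("start" convention, the cost-effectiveness norm).  The
  "end" convention (`1.05^-t`) is a switch; it rescales every total by
  exactly 1/1.05.
* **Half-cycle correction** (on by default, and always on in the PSA):
  trapezoidal — each cycle is valued at the average of its start- and
  end-of-cycle occupancy.  It applies to life years, QALYs and recurring
  state costs, never to one-off costs.
* **QALYs**: alive-state occupancy times the state utility; year-1 utilities
  (acute phase, e.g. mRS 2 = 0.67) in cycle 1, chronic-phase utilities
  (mRS 2 = 0.70) thereafter; the dead state has utility 0.
* **Costs** (2022 AUD, societal perspective): per-state medical,
  non-medical and indirect triples; year-1 rows in cycle 1, chronic rows
  thereafter.  Indirect (productivity) costs accrue only while attained age
  at cycle start is below 64, reflecting labour-force participation.
  One-off add-ons: the IVT delivery cost times the fraction thrombolysed
  (cycle 1); the year-1 death cost applied once to all mass dead by the end
  of cycle 1 (including 90-day tree deaths — deaths in later years accrue
  nothing); and the recurrent-stroke cost per incident recurrence in the
  cycle it occurs.  Recurrence does not reset year-1 acute costs or
  utilities.
* The IVT and recurrent-stroke costs are **not part of the published state
  tables**; the shipped defaults (3 500 and 20 000 AUD) are documented
  placeholder assumptions and must be replaced for any reimbursement-grade
  analysis.  Both are varied ±50% in the one-way sensitivity analysis.

## Parameter handling

The shipped YAML transcribes the published tables verbatim.  The usual-care
90-day row sums to 0.99 through rounding; it is renormalised proportionally
at point of use (no state is privileged), with an error raised if any row
deviates from unit mass by more than 0.05.  A few published cost bases lie
outside their own published intervals; the loader warns and accepts them as
printed, because the interval only bounds sensitivity analyses.  Parameters
published without a distribution (IVT-within-60, adverse-event probability
and row, recurrence case fatality) are fixed; zero-width intervals
(late recurrence, 0.02–0.02) are likewise fixed in the PSA.

## Sensitivity analyses

**One-way (tornado).**  Each uncertain parameter is set to its interval
bounds in turn, all others at base, and both arms re-run; the table records
the incremental cost and incremental QALYs at each bound and is sorted by
descending incremental-cost range.  Varying one entry of an mRS row makes
the row sum ≈ 0.96–1.04; the proportional renormalisation absorbs it, which
is the standard convention for perturbing a single transition probability.
Costs without published intervals are varied ±50%; the starting age is
varied by ± one SD of the cohort age (57.8 ± 10.9).

**Probabilistic (PSA).**  Each of the (default) 10 000 iterations draws
every triangular parameter once by inverse-CDF sampling — independently, as
the distributions are specified — renormalises each drawn mRS row, and
evaluates *both arms on the same draw* (common random numbers, since the
arms share every input except identification accuracy).  Half-cycle
correction is on.  "Optimal" is operationalised as positive incremental net
monetary benefit at a configurable willingness-to-pay (default 50 000
AUD/QALY); because the hypothetical arm gains QALYs *and* saves costs in
every draw, the probability is willingness-to-pay-invariant.  Summaries are
means and 2.5/97.5 percentile intervals of the draws.

## Synthetic life table

Tests and the default pipeline use a Gompertz–Makeham hazard
`h(a) = c + A·exp(b·a)` with `c = 2×10⁻⁴`, `A = 1.21×10⁻⁵`, `b = 0.1005`
over ages 0–110 (terminal `qx` forced to 1), calibrated so that female life
expectancy at 57.8 is 28.8 years — the band typical of contemporary
Australian women.  It reproduces the *shape* of adult female mortality but
not cohort effects, accident humps or the exact national `qx` schedule, so
per-person levels computed with it are not exact reproductions of analyses
built on an official table; substitute one as an `age,sex,qx` CSV
(`--lifetable`) for that purpose.  Because both arms share the table, the
between-arm differences are far less sensitive to this choice than the
levels are.

## Validation

An individual-level microsimulation (`stroke_cea.synthetic.microsimulate`)
re-implements the tree and the yearly event draws per person, sharing the
event-ordering, year-1 and accrual conventions with the cohort engine by
construction, so disagreement isolates arithmetic errors.  The test suite
requires agreement within 3 Monte-Carlo standard errors at n = 10⁵ on the
default inputs and within 4 SE across 20 random valid parameter sets at
n = 10⁴, plus: probability conservation and dead-state monotonicity on
every trace; exactly zero between-arm differences when the two accuracies
are equalised; the closed-form 50-year annuity-due (19.1687 discounted life
years) for an immortal cohort; and a Kolmogorov–Smirnov distance < 0.01
between 10⁵ triangular draws and the analytic CDF.

## Numerical choices

mRS-row normalisation tolerance 0.05 (load/OWSA) — PSA draws are
renormalised before evaluation; occupancy conservation asserted at 1×10⁻⁹;
the triangular inverse CDF clamps to its support to guard one-ulp
overshoot; fractional ages floor to the tabulated integer age; population
extrapolation multiplies unrounded per-person deltas by default, with a
`rounding` switch that first rounds deltas to 2 decimals (LY/QALY) and
whole dollars to mirror published summary arithmetic.

## Known limitations

* **Survival is nearly identical across arms by construction.**  After year
  1 every alive mRS state faces the same background mortality, the same
  recurrence probability and the same recurrence case fatality, so the only
  survival difference between arms is the (small) difference in 90-day
  death mass — and the year-1 residual top-up absorbs most of that.  With
  the shipped inputs the arms differ by ≈ 4×10⁻⁴ discounted life years per
  person.  The gains this model attributes to better identification are
  therefore almost entirely *morbidity* gains (milder 90-day states →
  higher utilities and lower long-term costs: ≈ 0.037 QALYs and ≈ 2 800
  AUD saved per person).  A materially larger life-year gain would require
  mRS-dependent excess mortality, which the input tables do not specify and
  this implementation deliberately does not invent.
* Per-person *levels* depend on the placeholder IVT/recurrence costs and on
  the life table; between-arm *differences* are robust to both.
* The tree is binary (IVT within 60 minutes or usual care); onset-to-needle
  time is not modelled as a continuous effect modifier.
* Period life table only: no mortality-improvement projection, no
  individual heterogeneity in the production engine (the microsimulation
  exists as a test oracle), and no equity weighting.
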