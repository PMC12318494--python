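"""Long-term Markov cohort engine over mRS 0-5 plus an absorbing dead state.

Annual cycles over a 50-year horizon (by default).  In each cycle an alive
patient experiences exactly one of: a recurrent stroke (death with the
recurrent-stroke case fatality, otherwise transition to an equally likely
strictly-worse alive state), death from background mortality, or no event.
Events are mutually exclusive and recurrence is resolved first, so background
mortality applies only to the non-recurrent mass.

Year-1 composition: the published 12-month all-cause death probability is the
*total* first-year probability, part of which is already realised as 90-day
deaths inside the decision tree.  Cycle 1 therefore replaces background
mortality with the residual conditional probability
``max(0, (q12m - d90) / (1 - d90))`` applied to 90-day survivors, which avoids
double counting the tree deaths.

Accrual conventions (all switchable through :class:`EngineOptions`):

* discounting — cycle 1 undiscounted, cycle ``t`` weighted ``(1+r)^-(t-1)``
  ("start" convention); the alternative "end" convention uses ``(1+r)^-t``;
* half-cycle correction — trapezoidal (average of start- and end-of-cycle
  occupancy) on life years, QALYs and recurring state costs, never on one-off
  costs (thrombolysis, the year-1 death cost, recurrent-stroke costs);
* indirect costs accrue only while attained age at cycle start is below the
  labour-force cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lifetable import LifeTable
from .parameters import (
    DEAD_STATE,
    N_STATES,
    CostTable,
    MarkovParams,
    ParameterSet,
    UtilityTable,
    ValidationError,
)

__all__ = [
    "EngineOptions",
    "MarkovTrace",
    "ArmResult",
    "residual_year1_mortality",
    "recurrence_transition",
    "build_cycle_matrix",
    "run_cohort",
    "accrue_outcomes",
]


@dataclass(frozen=True)
class EngineOptions:
    """Switchable accrual conventions."""

    half_cycle: bool = True
    #: "start": cycle 1 undiscounted; "end": every cycle discounted one year more.
    discount_convention: str = "start"
    #: tolerance passed to mRS-row normalisation (PSA draws are pre-normalised).
    normalize_tolerance: float = 0.05

    def __post_init__(self) -> None:
        if self.discount_convention not in ("start", "end"):
            raise ValueError(
                f"discount_convention must be 'start' or 'end', got {self.discount_convention!r}"
            )

    def discount_factors(self, rate: float, horizon: int) -> np.ndarray:
        t = np.arange(1, horizon + 1, dtype=float)
        exponent = t - 1.0 if self.discount_convention == "start" else t
        return (1.0 + rate) ** (-exponent)


@dataclass
class MarkovTrace:
    """Per-cycle record of the cohort run.

    ``occupancy[t]`` is the state distribution after cycle ``t``
    (``occupancy[0]`` is the 90-day vector from the decision tree).
    Accrual arrays are filled by :func:`accrue_outcomes`.
    """

    occupancy: np.ndarray          # (horizon+1, 7)
    ages: np.ndarray               # (horizon,) attained age at cycle start
    recurrence_mass: np.ndarray    # (horizon,) incident recurrent-stroke mass
    ly: np.ndarray | None = None
    ly_disc: np.ndarray | None = None
    qaly: np.ndarray | None = None
    qaly_disc: np.ndarray | None = None
    cost: np.ndarray | None = None
    cost_disc: np.ndarray | None = None

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        """One row per cycle: occupancies, age, accrual increments."""
        cols = {f"mrs{s}": self.occupancy[1:, s] for s in range(N_STATES)}
        df = pd.DataFrame({"cycle": np.arange(1, self.horizon + 1), "age": self.ages, **cols})
        for name in ("ly", "ly_disc", "qaly", "qaly_disc", "cost", "cost_disc"):
            arr = getattr(self, name)
            if arr is not None:
                df[name] = arr
        return df


@dataclass
class ArmResult:
    """Discounted per-person totals for one treatment arm."""

    life_years: float
    qalys: float
    total_cost: float
    components: dict[str, float]
    trace: MarkovTrace
    life_years_undiscounted: float = 0.0
    qalys_undiscounted: float = 0.0
    ivt_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.qalys > self.life_years + 1e-9:
            raise ValidationError("QALYs cannot exceed life years")


def residual_year1_mortality(p_allcause_12m: float, d90: float) -> float:
    """Conditional background mortality for cycle 1 given 90-day deaths.

    The 12-month all-cause probability is treated as the total first-year
    death probability; part of it (``d90``) is already realised in the
    decision tree, so 90-day survivors face the residual conditional risk.
    """
    if d90 >= 1.0:
        return 0.0
    return max(0.0, (p_allcause_12m - d90) / (1.0 - d90))


def recurrence_transition(state: int, p_death_given_recurrence: float) -> np.ndarray:
    """Outcome distribution of a recurrent stroke from an alive state.

    The case fatality goes to the dead state; surviving mass is split equally
    over the strictly-worse alive states.  From mRS 5 no worse alive state
    exists, so survivors remain in mRS 5.
    """
    if not 0 <= state < DEAD_STATE:
        raise ValidationError(f"recurrence from non-alive state {state}")
    out = np.zeros(N_STATES)
    out[DEAD_STATE] = p_death_given_recurrence
    survive = 1.0 - p_death_given_recurrence
    worse = list(range(state + 1, DEAD_STATE))
    if worse:
        out[worse] = survive / len(worse)
    else:
        out[state] = survive
    return out


def build_cycle_matrix(
    cycle_index: int,
    params: MarkovParams,
    lt: LifeTable,
    attained_age: float,
    d90: float | None = None,
) -> np.ndarray:
    """Row-stochastic 7x7 transition matrix for one cycle.

    Cycle 1 uses the first-year recurrence probability and, when ``d90``
    (the tree's 90-day death mass) is given, the residual first-year
    mortality in place of background mortality.
    """
    if cycle_index < 1:
        raise ValidationError("cycle_index must be >= 1")
    if cycle_index == 1:
        p_rec = params.p_recurrent_year1.mode
        if d90 is not None:
            q = residual_year1_mortality(params.p_allcause_mortality_12m.mode, d90)
        else:
            q = lt.annual_death_probability(attained_age)
    else:
        p_rec = params.p_recurrent_later.mode
        q = lt.annual_death_probability(attained_age)

    m = np.zeros((N_STATES, N_STATES))
    m[DEAD_STATE, DEAD_STATE] = 1.0
    for s in range(DEAD_STATE):
        m[s] += p_rec * recurrence_transition(s, params.p_death_given_recurrence)
        m[s, DEAD_STATE] += (1.0 - p_rec) * q
        m[s, s] += (1.0 - p_rec) * (1.0 - q)
    return m


def run_cohort(initial: np.ndarray, params: ParameterSet, lt: LifeTable) -> MarkovTrace:
    """Propagate the 90-day state vector through the full horizon.

    ``initial`` must be normalized and include 90-day deaths in the dead
    state.  The cohort ages one year per cycle from the starting age.
    """
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (N_STATES,):
        raise ValidationError(f"initial vector must have {N_STATES} entries")
    if abs(initial.sum() - 1.0) > 1e-9:
        raise ValidationError("initial state vector must sum to 1")
    mk = params.markov
    horizon = mk.horizon_years
    occupancy = np.zeros((horizon + 1, N_STATES))
    occupancy[0] = initial
    ages = mk.start_age + np.arange(horizon, dtype=float)
    recurrence_mass = np.zeros(horizon)
    d90 = float(initial[DEAD_STATE])
    for t in range(1, horizon + 1):
        p_rec = mk.p_recurrent_year1.mode if t == 1 else mk.p_recurrent_later.mode
        matrix = build_cycle_matrix(t, mk, lt, ages[t - 1], d90=d90 if t == 1 else None)
        recurrence_mass[t - 1] = p_rec * occupancy[t - 1, :DEAD_STATE].sum()
        occupancy[t] = occupancy[t - 1] @ matrix
    return MarkovTrace(occupancy=occupancy, ages=ages, recurrence_mass=recurrence_mass)


def accrue_outcomes(
    trace: MarkovTrace,
    utilities: UtilityTable,
    costs: CostTable,
    params: MarkovParams,
    options: EngineOptions = EngineOptions(),
    ivt_fraction: float = 0.0,
) -> ArmResult:
    """Accumulate life years, QALYs and costs over a completed trace.

    Cycle 1 uses year-1 utilities and year-1 state costs; later cycles use
    the chronic-phase tables.  One-off costs: expected thrombolysis cost
    (``ivt_fraction * ivt_cost``) in cycle 1, the year-1 death cost applied
    once to all mass dead by the end of cycle 1 (including tree deaths), and
    the recurrent-stroke cost per incident recurrence.
    """
    horizon = trace.horizon
    occ = trace.occupancy
    disc = options.discount_factors(params.discount_rate, horizon)
    weights = 0.5 * (occ[:-1] + occ[1:]) if options.half_cycle else occ[:-1].copy()
    alive = weights[:, :DEAD_STATE]  # (horizon, 6)

    ly = alive.sum(axis=1)

    u_year1 = utilities.vector("year1")[:DEAD_STATE]
    u_later = utilities.vector("later")[:DEAD_STATE]
    qaly = np.empty(horizon)
    qaly[0] = alive[0] @ u_year1
    qaly[1:] = alive[1:] @ u_later

    indirect_on = trace.ages < params.indirect_cost_age_cutoff

    med = np.empty(horizon)
    nonmed = np.empty(horizon)
    indirect = np.empty(horizon)
    med[0] = alive[0] @ costs.vector("year1", "medical")
    nonmed[0] = alive[0] @ costs.vector("year1", "non_medical")
    indirect[0] = alive[0] @ costs.vector("year1", "indirect")
    med[1:] = alive[1:] @ costs.vector("later", "medical")
    nonmed[1:] = alive[1:] @ costs.vector("later", "non_medical")
    indirect[1:] = alive[1:] @ costs.vector("later", "indirect")
    indirect *= indirect_on

    # one-off costs, never half-cycle corrected
    death = costs.death_year1
    death_cost = death.medical.base + death.non_medical.base
    if indirect_on[0]:
        death_cost += death.indirect.base
    oneoff_med = np.zeros(horizon)
    oneoff_nonmed = np.zeros(horizon)
    oneoff_ind = np.zeros(horizon)
    oneoff_med[0] += ivt_fraction * costs.ivt_cost.base
    oneoff_med[0] += occ[1, DEAD_STATE] * death.medical.base
    oneoff_nonmed[0] += occ[1, DEAD_STATE] * death.non_medical.base
    if indirect_on[0]:
        oneoff_ind[0] += occ[1, DEAD_STATE] * death.indirect.base
    oneoff_med += trace.recurrence_mass * costs.recurrent_stroke_cost.base

    med_total = med + oneoff_med
    nonmed_total = nonmed + oneoff_nonmed
    ind_total = indirect + oneoff_ind
    cost = med_total + nonmed_total + ind_total

    trace.ly = ly
    trace.ly_disc = ly * disc
    trace.qaly = qaly
    trace.qaly_disc = qaly * disc
    trace.cost = cost
    trace.cost_disc = cost * disc

    components = {
        "medical": float(med_total @ disc),
        "non_medical": float(nonmed_total @ disc),
        "indirect": float(ind_total @ disc),
    }
    return ArmResult(
        life_years=float(ly @ disc),
        qalys=float(qaly @ disc),
        total_cost=float(cost @ disc),
        components=components,
        trace=trace,
        life_years_undiscounted=float(ly.sum()),
        qalys_undiscounted=float(qaly.sum()),
        ivt_fraction=ivt_fraction,
    )
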