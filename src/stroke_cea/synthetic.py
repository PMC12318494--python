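"""Synthetic inputs: life tables, random parameter sets, and a
microsimulation oracle for validating the cohort engine.

The bundled life table is a Gompertz-Makeham hazard calibrated so that
female life expectancy at the cohort starting age (57.8 years) falls in the
28-30 year band typical of a contemporary high-income population.  It stands
in for an official national period life table, which can be substituted as a
``age,sex,qx`` CSV for exact reproduction against published registry data.

The microsimulation simulates individuals through the decision tree and
yearly event draws with the *same* event-ordering and year-1 conventions as
the deterministic cohort engine (single source of truth for those rules), so
any disagreement beyond Monte-Carlo error isolates an arithmetic bug rather
than a convention drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lifetable import LifeTable
from .markov import EngineOptions, residual_year1_mortality
from .parameters import (
    DEAD_STATE,
    N_STATES,
    CostComponent,
    CostTable,
    CostTriple,
    Extrapolation,
    MarkovParams,
    MRSDistribution,
    ParameterSet,
    ShortTermParams,
    TriangularParam,
    UtilityTable,
)
from .tree import evaluate_tree

__all__ = [
    "GompertzMakehamSpec",
    "DEFAULT_FEMALE_SPEC",
    "generate_lifetable",
    "default_lifetable",
    "generate_random_parameter_set",
    "MicrosimResult",
    "microsimulate",
    "microsimulate_tree",
]


@dataclass(frozen=True)
class GompertzMakehamSpec:
    """Annual mortality hazard h(age) = makeham_c + gompertz_a * exp(gompertz_b * age)."""

    makeham_c: float
    gompertz_a: float
    gompertz_b: float
    min_age: int = 0
    max_age: int = 110

    def __post_init__(self) -> None:
        if self.makeham_c < 0 or self.gompertz_a <= 0 or self.gompertz_b < 0:
            raise ValueError("hazard parameters must satisfy c >= 0, a > 0, b >= 0")
        if self.min_age < 0 or self.max_age <= self.min_age:
            raise ValueError("need 0 <= min_age < max_age")

    def hazard(self, age: np.ndarray | float) -> np.ndarray | float:
        return self.makeham_c + self.gompertz_a * np.exp(self.gompertz_b * np.asarray(age, dtype=float))


#: Calibrated so that female life expectancy at age 57.8 is ~28.8 years.
DEFAULT_FEMALE_SPEC = GompertzMakehamSpec(
    makeham_c=2.0e-4,
    gompertz_a=1.21e-5,
    gompertz_b=0.1005,
)


def generate_lifetable(
    spec: GompertzMakehamSpec = DEFAULT_FEMALE_SPEC, sex_label: str = "female"
) -> LifeTable:
    """One row per integer age; qx = 1 - exp(-h(age)); terminal qx forced to 1."""
    ages = np.arange(spec.min_age, spec.max_age + 1)
    qx = 1.0 - np.exp(-np.asarray(spec.hazard(ages)))
    qx[-1] = 1.0
    return LifeTable(sex_label=sex_label, ages=ages, qx=qx)


def default_lifetable() -> LifeTable:
    """The bundled synthetic female life table."""
    return generate_lifetable()


# ---------------------------------------------------------------------------
# Random valid parameter sets (for property-based testing)
# ---------------------------------------------------------------------------


def _random_tri(rng: np.random.Generator, lo: float, hi: float, width: float) -> TriangularParam:
    mode = float(rng.uniform(lo, hi))
    low = max(lo, mode - float(rng.uniform(0, width)))
    high = min(hi, mode + float(rng.uniform(0, width)))
    return TriangularParam(mode=mode, low=low, high=high)


def _random_distribution(rng: np.random.Generator) -> MRSDistribution:
    p = rng.dirichlet(np.ones(N_STATES) * 2.0)
    entries = tuple(
        TriangularParam(
            mode=float(v),
            low=max(0.0, float(v) - 0.02),
            high=min(1.0, float(v) + 0.02),
        )
        for v in p
    )
    return MRSDistribution(entries)


def generate_random_parameter_set(seed: int) -> ParameterSet:
    """A random parameter set satisfying every load-time invariant.

    Deterministic given ``seed``.  Intended for property-based tests of the
    engine/oracle agreement, not as a realistic clinical scenario.
    """
    rng = np.random.default_rng(seed)
    short_term = ShortTermParams(
        p_accurate_women=_random_tri(rng, 0.1, 0.6, 0.02),
        p_accurate_men=_random_tri(rng, 0.1, 0.6, 0.02),
        p_ivt_within_60min=float(rng.uniform(0.1, 0.9)),
        p_adverse_event=float(rng.uniform(0.0, 0.2)),
        dist_ivt=_random_distribution(rng),
        dist_adverse=_random_distribution(rng),
        dist_usual_care=_random_distribution(rng),
    )
    markov = MarkovParams(
        p_recurrent_year1=_random_tri(rng, 0.02, 0.2, 0.02),
        p_recurrent_later=_random_tri(rng, 0.005, 0.08, 0.01),
        p_death_given_recurrence=float(rng.uniform(0.02, 0.3)),
        p_allcause_mortality_12m=_random_tri(rng, 0.05, 0.3, 0.02),
        discount_rate=float(rng.uniform(0.0, 0.07)),
        horizon_years=int(rng.integers(10, 51)),
        start_age=float(rng.uniform(50.0, 70.0)),
        start_age_sd=float(rng.uniform(2.0, 12.0)),
        indirect_cost_age_cutoff=float(rng.uniform(60.0, 70.0)),
        cohort_size=int(rng.integers(100, 10_000)),
    )
    u1 = np.sort(rng.uniform(0.0, 1.0, size=6))[::-1]
    ul = np.sort(rng.uniform(0.0, 1.0, size=6))[::-1]
    utilities = UtilityTable(
        year1=tuple(TriangularParam(float(v), max(0.0, float(v) - 0.05), min(1.0, float(v) + 0.05)) for v in u1),
        later=tuple(TriangularParam(float(v), max(0.0, float(v) - 0.05), min(1.0, float(v) + 0.05)) for v in ul),
    )

    def cost(base: float) -> CostComponent:
        return CostComponent(base=base, low=0.5 * base, high=1.5 * base)

    def triple(scale: float) -> "tuple[CostComponent, CostComponent, CostComponent]":
        return (
            cost(float(rng.uniform(0.2, 1.0)) * scale),
            cost(float(rng.uniform(0.0, 0.5)) * scale),
            cost(float(rng.uniform(0.0, 0.5)) * scale),
        )

    year1_med = np.sort(rng.uniform(10_000, 200_000, size=6))
    year1_rows = []
    for m in year1_med:
        _, nm, ind = triple(50_000)
        year1_rows.append(CostTriple(medical=cost(float(m)), non_medical=nm, indirect=ind))
    m6, nm6, ind6 = triple(60_000)
    year1_rows.append(CostTriple(medical=m6, non_medical=nm6, indirect=ind6))
    later_rows = []
    for _ in range(6):
        m, nm, ind = triple(30_000)
        later_rows.append(CostTriple(medical=m, non_medical=nm, indirect=ind))
    costs = CostTable(
        year1=tuple(year1_rows),
        later=tuple(later_rows),
        ivt_cost=cost(float(rng.uniform(1_000, 8_000))),
        recurrent_stroke_cost=cost(float(rng.uniform(5_000, 50_000))),
    )
    extrapolation = Extrapolation(
        annual_hospitalisations=int(rng.integers(1_000, 10_000)),
        ischaemic_fraction=float(rng.uniform(0.5, 1.0)),
        ivt60_rate_national=float(rng.uniform(0.1, 0.7)),
    )
    return ParameterSet(
        short_term=short_term,
        markov=markov,
        utilities=utilities,
        costs=costs,
        extrapolation=extrapolation,
    )


# ---------------------------------------------------------------------------
# Microsimulation oracle
# ---------------------------------------------------------------------------


@dataclass
class MicrosimResult:
    """Mean per-person outcomes with Monte-Carlo standard errors."""

    life_years: float
    qalys: float
    total_cost: float
    se: dict[str, float]
    n_individuals: int


def microsimulate(
    params: ParameterSet,
    lt: LifeTable,
    n_individuals: int,
    seed: int,
    arm: str = "status_quo",
    options: EngineOptions = EngineOptions(),
) -> MicrosimResult:
    """Individual-level re-implementation of tree + Markov accrual.

    Vectorised over individuals; one RNG stream drives all event draws.
    Shares the residual year-1 mortality, event ordering, discounting and
    half-cycle conventions with the cohort engine.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    from .analyses import arm_accuracy  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    n = n_individuals
    st = params.short_term
    mk = params.markov
    p_acc = arm_accuracy(params, arm)

    d_ivt = st.dist_ivt.normalized(options.normalize_tolerance)
    d_ae = st.dist_adverse.normalized(options.normalize_tolerance)
    d_uc = st.dist_usual_care.normalized(options.normalize_tolerance)

    accurate = rng.random(n) < p_acc
    ivt = accurate & (rng.random(n) < st.p_ivt_within_60min)
    adverse = ivt & (rng.random(n) < st.p_adverse_event)

    # 90-day state per branch
    u = rng.random(n)
    state = np.empty(n, dtype=np.int64)
    for mask, dist in (
        (ivt & ~adverse, d_ivt),
        (adverse, d_ae),
        (~ivt, d_uc),
    ):
        state[mask] = np.searchsorted(np.cumsum(dist), u[mask], side="right")
    state = np.clip(state, 0, DEAD_STATE)

    # analytic 90-day death mass fixes the residual year-1 mortality, exactly
    # as in the cohort engine
    tree = evaluate_tree(p_acc, st, options.normalize_tolerance)
    q1 = residual_year1_mortality(mk.p_allcause_mortality_12m.mode, tree.death_mass)

    horizon = mk.horizon_years
    disc = options.discount_factors(mk.discount_rate, horizon)
    hcc = options.half_cycle

    u_year1 = params.utilities.vector("year1")
    u_later = params.utilities.vector("later")
    cost_y1 = {c: np.append(params.costs.vector("year1", c), 0.0) for c in ("medical", "non_medical", "indirect")}
    cost_lt = {c: np.append(params.costs.vector("later", c), 0.0) for c in ("medical", "non_medical", "indirect")}

    ly = np.zeros(n)
    qaly = np.zeros(n)
    cost = np.zeros(n)

    cost[ivt] += params.costs.ivt_cost.base * disc[0]

    p_death_rec = mk.p_death_given_recurrence
    for t in range(1, horizon + 1):
        age = mk.start_age + (t - 1)
        indirect_on = age < mk.indirect_cost_age_cutoff
        p_rec = mk.p_recurrent_year1.mode if t == 1 else mk.p_recurrent_later.mode
        q = q1 if t == 1 else lt.annual_death_probability(age)

        start = state.copy()
        alive = start < DEAD_STATE

        recur = alive & (rng.random(n) < p_rec)
        cost[recur] += params.costs.recurrent_stroke_cost.base * disc[t - 1]
        rec_die = recur & (rng.random(n) < p_death_rec)
        rec_survive = recur & ~rec_die
        # equal split over strictly-worse alive states; mRS 5 survivors stay
        worse_count = DEAD_STATE - 1 - state[rec_survive]
        jump = np.ones_like(worse_count)
        many = worse_count > 0
        jump[many] = rng.integers(1, worse_count[many] + 1)
        jump[~many] = 0
        new_state = state[rec_survive] + jump
        bg_die = alive & ~recur & (rng.random(n) < q)

        state[rec_die | bg_die] = DEAD_STATE
        state[rec_survive] = new_state

        end_alive = state < DEAD_STATE
        if hcc:
            w_start, w_end = 0.5, 0.5
        else:
            w_start, w_end = 1.0, 0.0
        ly += disc[t - 1] * (w_start * alive + w_end * end_alive)
        uvec = u_year1 if t == 1 else u_later
        qaly += disc[t - 1] * (w_start * uvec[start] + w_end * uvec[state])
        cvec = cost_y1 if t == 1 else cost_lt
        for comp in ("medical", "non_medical", "indirect"):
            if comp == "indirect" and not indirect_on:
                continue
            cost += disc[t - 1] * (w_start * cvec[comp][start] + w_end * cvec[comp][state])

        if t == 1:
            # one-off cost of deaths realised by the end of the first year
            death = params.costs.death_year1
            death_cost = death.medical.base + death.non_medical.base
            if indirect_on:
                death_cost += death.indirect.base
            cost[state == DEAD_STATE] += death_cost * disc[0]

    def se(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else float("inf")

    return MicrosimResult(
        life_years=float(ly.mean()),
        qalys=float(qaly.mean()),
        total_cost=float(cost.mean()),
        se={"life_years": se(ly), "qalys": se(qaly), "total_cost": se(cost)},
        n_individuals=n,
    )


def microsimulate_tree(
    p_accurate: float, stp: ShortTermParams, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical 90-day mRS distribution from ``n`` simulated individuals.

    Returns (frequencies, Monte-Carlo standard errors per state).
    """
    rng = np.random.default_rng(seed)
    d_ivt = stp.dist_ivt.normalized()
    d_ae = stp.dist_adverse.normalized()
    d_uc = stp.dist_usual_care.normalized()
    accurate = rng.random(n) < p_accurate
    ivt = accurate & (rng.random(n) < stp.p_ivt_within_60min)
    adverse = ivt & (rng.random(n) < stp.p_adverse_event)
    u = rng.random(n)
    state = np.empty(n, dtype=np.int64)
    for mask, dist in ((ivt & ~adverse, d_ivt), (adverse, d_ae), (~ivt, d_uc)):
        state[mask] = np.searchsorted(np.cumsum(dist), u[mask], side="right")
    state = np.clip(state, 0, DEAD_STATE)
    freq = np.bincount(state, minlength=N_STATES) / n
    se = np.sqrt(freq * (1 - freq) / n)
    return freq, se
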