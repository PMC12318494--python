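"""Two-arm comparison, sensitivity analyses and population extrapolation.

The comparison holds every input fixed except the probability of accurate
pre-hospital stroke identification: the *status quo* arm uses the accuracy
observed for women, the *hypothetical* arm the accuracy observed for men.
Any difference in outcome is therefore attributable to the identification
gap alone.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .lifetable import LifeTable
from .markov import ArmResult, EngineOptions, accrue_outcomes, run_cohort
from .parameters import (
    CostComponent,
    MRSDistribution,
    ParameterSet,
    TriangularParam,
    ValidationError,
    draw_parameter_set,
)
from .tree import evaluate_tree

__all__ = [
    "ComparisonResult",
    "VariedParameter",
    "TornadoTable",
    "PSAResult",
    "PopulationImpact",
    "evaluate_arm",
    "run_base_case",
    "owsa_parameters",
    "run_owsa",
    "run_psa",
    "national_multiplier",
    "extrapolate",
]

ARMS = ("hypothetical", "status_quo")


# ---------------------------------------------------------------------------
# Base case
# ---------------------------------------------------------------------------


@dataclass
class ComparisonResult:
    """Per-person results for both arms and their differences."""

    hypothetical: ArmResult
    status_quo: ArmResult

    @property
    def per_person(self) -> dict[str, float]:
        return {
            "delta_life_years": self.hypothetical.life_years - self.status_quo.life_years,
            "delta_qalys": self.hypothetical.qalys - self.status_quo.qalys,
            "delta_cost": self.hypothetical.total_cost - self.status_quo.total_cost,
        }

    def to_frame(self) -> pd.DataFrame:
        """Per-person results table: one row per arm plus the difference."""
        rows = []
        for label, arm in (("hypothetical", self.hypothetical), ("status_quo", self.status_quo)):
            rows.append(
                {
                    "arm": label,
                    "life_years": arm.life_years,
                    "qalys": arm.qalys,
                    "cost": arm.total_cost,
                    "life_years_undiscounted": arm.life_years_undiscounted,
                }
            )
        d = self.per_person
        rows.append(
            {
                "arm": "difference",
                "life_years": d["delta_life_years"],
                "qalys": d["delta_qalys"],
                "cost": d["delta_cost"],
                "life_years_undiscounted": self.hypothetical.life_years_undiscounted
                - self.status_quo.life_years_undiscounted,
            }
        )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        d = self.per_person
        lines = [
            "Two-arm comparison (per person, discounted)",
            "-" * 52,
            f"{'':<16s}{'life years':>12s}{'QALYs':>10s}{'cost (AUD)':>14s}",
            f"{'hypothetical':<16s}{self.hypothetical.life_years:>12.4f}"
            f"{self.hypothetical.qalys:>10.4f}{self.hypothetical.total_cost:>14,.0f}",
            f"{'status quo':<16s}{self.status_quo.life_years:>12.4f}"
            f"{self.status_quo.qalys:>10.4f}{self.status_quo.total_cost:>14,.0f}",
            f"{'difference':<16s}{d['delta_life_years']:>12.4f}"
            f"{d['delta_qalys']:>10.4f}{d['delta_cost']:>14,.0f}",
        ]
        return "\n".join(lines)


def arm_accuracy(params: ParameterSet, arm: str) -> float:
    if arm == "hypothetical":
        return params.short_term.p_accurate_men.mode
    if arm == "status_quo":
        return params.short_term.p_accurate_women.mode
    raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")


def evaluate_arm(
    params: ParameterSet,
    lt: LifeTable,
    arm: str,
    options: EngineOptions = EngineOptions(),
) -> ArmResult:
    """Decision tree -> Markov cohort -> accrual for one arm."""
    tree = evaluate_tree(arm_accuracy(params, arm), params.short_term, options.normalize_tolerance)
    trace = run_cohort(tree.mrs_distribution, params, lt)
    return accrue_outcomes(
        trace,
        params.utilities,
        params.costs,
        params.markov,
        options=options,
        ivt_fraction=tree.ivt_fraction,
    )


def run_base_case(
    params: ParameterSet, lt: LifeTable, options: EngineOptions = EngineOptions()
) -> ComparisonResult:
    """Evaluate both arms with identical inputs except identification accuracy."""
    return ComparisonResult(
        hypothetical=evaluate_arm(params, lt, "hypothetical", options),
        status_quo=evaluate_arm(params, lt, "status_quo", options),
    )


# ---------------------------------------------------------------------------
# One-way sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class VariedParameter:
    """One tornado variable: a name, bounds, and a setter on a ParameterSet."""

    name: str
    base: float
    low: float
    high: float
    setter: Callable[[ParameterSet, float], None]

    def apply(self, params: ParameterSet, value: float) -> ParameterSet:
        out = params.copy()
        self.setter(out, value)
        return out


def _set_tri_mode(get: Callable[[ParameterSet], TriangularParam]):
    def setter(ps: ParameterSet, value: float) -> None:
        p = get(ps)
        p.mode = value
        p.low = min(p.low, value)
        p.high = max(p.high, value)

    return setter


def _set_dist_entry(dist_name: str, index: int):
    def setter(ps: ParameterSet, value: float) -> None:
        dist: MRSDistribution = getattr(ps.short_term, dist_name)
        e = dist.entries[index]
        e.mode = value
        e.low = min(e.low, value)
        e.high = max(e.high, value)

    return setter


def _set_utility(phase: str, index: int):
    def setter(ps: ParameterSet, value: float) -> None:
        row = ps.utilities.year1 if phase == "year1" else ps.utilities.later
        u = row[index]
        u.mode = value
        u.low = min(u.low, value)
        u.high = max(u.high, value)

    return setter


def _set_cost(phase: str, index: int, component: str):
    def setter(ps: ParameterSet, value: float) -> None:
        rows = ps.costs.year1 if phase == "year1" else ps.costs.later
        c: CostComponent = getattr(rows[index], component)
        c.base = value
        c.low = min(c.low, value)
        c.high = max(c.high, value)

    return setter


def _set_extra_cost(attr: str):
    def setter(ps: ParameterSet, value: float) -> None:
        c: CostComponent = getattr(ps.costs, attr)
        c.base = value
        c.low = min(c.low, value)
        c.high = max(c.high, value)

    return setter


def _set_start_age(ps: ParameterSet, value: float) -> None:
    ps.markov.start_age = value


def owsa_parameters(params: ParameterSet) -> list[VariedParameter]:
    """The default tornado variable list.

    Every parameter published with an interval is varied over that interval;
    costs without an interval are varied +/- 50%; the starting age is varied
    by +/- one standard deviation of the cohort age.  Parameters published as
    fixed (no distribution) are not varied.
    """
    st = params.short_term
    out: list[VariedParameter] = [
        VariedParameter(
            "p_accurate_women",
            st.p_accurate_women.mode,
            st.p_accurate_women.low,
            st.p_accurate_women.high,
            _set_tri_mode(lambda ps: ps.short_term.p_accurate_women),
        ),
        VariedParameter(
            "p_accurate_men",
            st.p_accurate_men.mode,
            st.p_accurate_men.low,
            st.p_accurate_men.high,
            _set_tri_mode(lambda ps: ps.short_term.p_accurate_men),
        ),
        VariedParameter(
            "p_recurrent_year1",
            params.markov.p_recurrent_year1.mode,
            params.markov.p_recurrent_year1.low,
            params.markov.p_recurrent_year1.high,
            _set_tri_mode(lambda ps: ps.markov.p_recurrent_year1),
        ),
        VariedParameter(
            "p_recurrent_later",
            params.markov.p_recurrent_later.mode,
            params.markov.p_recurrent_later.low,
            params.markov.p_recurrent_later.high,
            _set_tri_mode(lambda ps: ps.markov.p_recurrent_later),
        ),
        VariedParameter(
            "p_allcause_mortality_12m",
            params.markov.p_allcause_mortality_12m.mode,
            params.markov.p_allcause_mortality_12m.low,
            params.markov.p_allcause_mortality_12m.high,
            _set_tri_mode(lambda ps: ps.markov.p_allcause_mortality_12m),
        ),
        VariedParameter(
            "start_age",
            params.markov.start_age,
            params.markov.start_age - params.markov.start_age_sd,
            params.markov.start_age + params.markov.start_age_sd,
            _set_start_age,
        ),
    ]
    for dist_name in ("dist_ivt", "dist_usual_care"):
        dist: MRSDistribution = getattr(st, dist_name)
        for i, e in enumerate(dist.entries):
            if e.is_fixed:
                continue
            out.append(
                VariedParameter(
                    f"{dist_name}_mrs{i}", e.mode, e.low, e.high, _set_dist_entry(dist_name, i)
                )
            )
    for phase, row in (("year1", params.utilities.year1), ("later", params.utilities.later)):
        for i, u in enumerate(row):
            if u.is_fixed:
                continue
            out.append(
                VariedParameter(
                    f"utility_{phase}_mrs{i}", u.mode, u.low, u.high, _set_utility(phase, i)
                )
            )
    for phase, rows in (("year1", params.costs.year1), ("later", params.costs.later)):
        for i, triple in enumerate(rows):
            for comp in ("medical", "non_medical", "indirect"):
                c: CostComponent = getattr(triple, comp)
                if c.is_fixed and c.base == 0:
                    continue
                low, high = (c.low, c.high) if not c.is_fixed else (0.5 * c.base, 1.5 * c.base)
                out.append(
                    VariedParameter(
                        f"cost_{phase}_mrs{i}_{comp}", c.base, low, high, _set_cost(phase, i, comp)
                    )
                )
    for attr in ("ivt_cost", "recurrent_stroke_cost"):
        c = getattr(params.costs, attr)
        low, high = (c.low, c.high) if not c.is_fixed else (0.5 * c.base, 1.5 * c.base)
        out.append(VariedParameter(attr, c.base, low, high, _set_extra_cost(attr)))
    return out


@dataclass
class TornadoTable:
    """Sorted one-way sensitivity table plus the base-case it pivots around."""

    frame: pd.DataFrame
    base: ComparisonResult

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def run_owsa(
    params: ParameterSet,
    lt: LifeTable,
    varied: Sequence[VariedParameter] | None = None,
    options: EngineOptions = EngineOptions(),
) -> TornadoTable:
    """Re-run both arms with each parameter at its bounds, one at a time.

    The table is sorted by descending range of the incremental cost.
    """
    if varied is None:
        varied = owsa_parameters(params)
    if len(varied) == 0:
        raise ValidationError("OWSA requires at least one varied parameter")
    base = run_base_case(params, lt, options)
    rows = []
    for vp in varied:
        deltas = {}
        for bound_name, bound in (("low", vp.low), ("high", vp.high)):
            comp = run_base_case(vp.apply(params, bound), lt, options)
            deltas[bound_name] = comp.per_person
        rows.append(
            {
                "parameter": vp.name,
                "base_value": vp.base,
                "low_value": vp.low,
                "high_value": vp.high,
                "delta_cost_at_low": deltas["low"]["delta_cost"],
                "delta_cost_at_high": deltas["high"]["delta_cost"],
                "delta_qalys_at_low": deltas["low"]["delta_qalys"],
                "delta_qalys_at_high": deltas["high"]["delta_qalys"],
            }
        )
    frame = pd.DataFrame(rows)
    frame["cost_range"] = (frame["delta_cost_at_high"] - frame["delta_cost_at_low"]).abs()
    frame["qaly_range"] = (frame["delta_qalys_at_high"] - frame["delta_qalys_at_low"]).abs()
    frame = frame.sort_values("cost_range", ascending=False, kind="mergesort").reset_index(drop=True)
    return TornadoTable(frame=frame, base=base)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class PSAResult:
    """Monte-Carlo draws of both arms under joint parameter uncertainty."""

    draws: pd.DataFrame
    seed: int
    n_iterations: int
    wtp: float

    @property
    def probability_optimal(self) -> float:
        """Fraction of iterations where the hypothetical arm has positive
        incremental net monetary benefit at the configured willingness-to-pay."""
        d = self.draws
        nmb = self.wtp * (d["qalys_hypothetical"] - d["qalys_status_quo"]) - (
            d["cost_hypothetical"] - d["cost_status_quo"]
        )
        return float((nmb > 0).mean())

    def summary_frame(self) -> pd.DataFrame:
        """Mean and 2.5/97.5 percentile interval per arm and outcome."""
        rows = []
        for arm in ARMS:
            for outcome in ("life_years", "qalys", "cost"):
                col = self.draws[f"{outcome}_{arm}"]
                rows.append(
                    {
                        "arm": arm,
                        "outcome": outcome,
                        "mean": col.mean(),
                        "p2.5": col.quantile(0.025),
                        "p97.5": col.quantile(0.975),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        frame = self.summary_frame()
        return {
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "wtp": self.wtp,
            "probability_optimal": self.probability_optimal,
            "arms": frame.to_dict(orient="records"),
        }


def run_psa(
    params: ParameterSet,
    lt: LifeTable,
    n: int,
    seed: int,
    wtp: float = 50_000.0,
    options: EngineOptions | None = None,
) -> PSAResult:
    """Joint Monte-Carlo propagation of all parameter distributions.

    Each iteration draws every triangular parameter once and evaluates both
    arms with the same draw (common random numbers), with half-cycle
    correction applied.  Fully reproducible given ``seed``.
    """
    if n < 1:
        raise ValidationError("PSA requires n >= 1 iterations")
    if options is None:
        options = EngineOptions(half_cycle=True)
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(n):
        drawn = draw_parameter_set(params, rng)
        record = {}
        for arm in ARMS:
            res = evaluate_arm(drawn, lt, arm, options)
            record[f"life_years_{arm}"] = res.life_years
            record[f"qalys_{arm}"] = res.qalys
            record[f"cost_{arm}"] = res.total_cost
        records.append(record)
    return PSAResult(draws=pd.DataFrame(records), seed=seed, n_iterations=n, wtp=wtp)


# ---------------------------------------------------------------------------
# Population extrapolation
# ---------------------------------------------------------------------------


def national_multiplier(
    hospitalisations: int, ischaemic_fraction: float, ivt60_rate: float
) -> dict[str, int]:
    """Women likely to benefit nationally per year.

    Annual stroke hospitalisations are scaled by the ischaemic fraction and
    then by the national rate of thrombolysis within 60 minutes, rounding to
    the nearest whole person at each step.
    """
    if hospitalisations < 0:
        raise ValidationError("hospitalisations must be >= 0")
    if not 0 <= ischaemic_fraction <= 1 or not 0 <= ivt60_rate <= 1:
        raise ValidationError("fractions must lie in [0, 1]")
    ischaemic_count = int(round(hospitalisations * ischaemic_fraction))
    multiplier = int(round(ischaemic_count * ivt60_rate))
    return {"ischaemic_count": ischaemic_count, "multiplier": multiplier}


@dataclass
class PopulationImpact:
    """Per-person differences scaled to a population of ``multiplier`` persons."""

    multiplier: int
    life_years: float
    qalys: float
    cost_savings: float


def extrapolate(
    comp: ComparisonResult, multiplier: int, rounding: bool = False
) -> PopulationImpact:
    """Scale per-person deltas to a population.

    With ``rounding`` set, per-person deltas are first rounded to two
    decimals (life years, QALYs) and whole dollars (cost), and the life-year
    and QALY totals are rounded to whole units — reproducing the arithmetic
    of published summary tables.  The unrounded path is the default.
    """
    if multiplier < 0:
        raise ValidationError("multiplier must be >= 0")
    d = comp.per_person
    dly, dq, dc = d["delta_life_years"], d["delta_qalys"], d["delta_cost"]
    if rounding:
        dly, dq, dc = round(dly, 2), round(dq, 2), round(dc)
        return PopulationImpact(
            multiplier=multiplier,
            life_years=round(multiplier * dly),
            qalys=round(multiplier * dq),
            cost_savings=-multiplier * dc,
        )
    return PopulationImpact(
        multiplier=multiplier,
        life_years=multiplier * dly,
        qalys=multiplier * dq,
        cost_savings=-multiplier * dc,
    )
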