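"""Model parameters: domain types, config loading, validation and sampling.

The parameter set mirrors the published input tables of the analysis it
implements: short-term decision-tree probabilities and 90-day modified Rankin
Scale (mRS) outcome distributions, long-term Markov transition probabilities,
health-state utilities for year 1 and subsequent years, and per-state cost
triples (medical / non-medical / indirect, 2022 Australian dollars).

Uncertain parameters carry triangular distributions (mode = base-case value,
low/high = the published interval); parameters published without a
distribution are fixed (zero-width interval).  The shipped default
configuration (``data/default_parameters.yaml``) is the machine-readable form
of those tables and is loaded with :func:`default_parameter_set`.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "DEAD_STATE",
    "N_STATES",
    "ParameterError",
    "SchemaError",
    "ValidationError",
    "IntervalWarning",
    "TriangularParam",
    "MRSDistribution",
    "ShortTermParams",
    "MarkovParams",
    "UtilityTable",
    "CostComponent",
    "CostTriple",
    "CostTable",
    "Extrapolation",
    "ParameterSet",
    "normalize_mrs_distribution",
    "triangular_ppf",
    "sample_triangular",
    "draw_parameter_set",
    "load_parameter_set",
    "default_parameter_set",
    "serialize_parameter_set",
    "save_parameter_set",
    "parameter_report",
]

#: Number of modified Rankin Scale states (mRS 0-5 alive, mRS 6 dead).
N_STATES = 7
#: Index of the absorbing dead state.
DEAD_STATE = 6


class ParameterError(ValueError):
    """Base class for configuration problems."""


class SchemaError(ParameterError):
    """A required field is missing or has the wrong shape."""


class ValidationError(ParameterError):
    """A field parses but violates a model invariant."""


class IntervalWarning(UserWarning):
    """A published base value lies outside its published interval."""


# ---------------------------------------------------------------------------
# Scalar parameter types
# ---------------------------------------------------------------------------


@dataclass
class TriangularParam:
    """A value with triangular uncertainty: low <= mode <= high.

    A zero-width interval (low == high == mode) denotes a fixed parameter;
    such parameters are never varied in probabilistic sensitivity analysis.
    """

    mode: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValidationError(
                f"inverted interval: low {self.low} > high {self.high}"
            )
        if not (self.low <= self.mode <= self.high):
            raise ValidationError(
                f"mode {self.mode} outside interval [{self.low}, {self.high}]"
            )

    @classmethod
    def fixed(cls, value: float) -> "TriangularParam":
        return cls(mode=value, low=value, high=value)

    @property
    def is_fixed(self) -> bool:
        return self.high == self.low

    @property
    def mean(self) -> float:
        """Analytic mean of the triangular distribution, (low+mode+high)/3."""
        return (self.low + self.mode + self.high) / 3.0


def triangular_ppf(param: TriangularParam, u: float) -> float:
    """Inverse CDF of the triangular distribution at quantile ``u``.

    ``u = 0`` returns ``low`` exactly and ``u = 1`` returns ``high`` exactly;
    a degenerate parameter returns its single value for any ``u``.
    """
    a, c, b = param.low, param.mode, param.high
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"quantile {u} outside [0, 1]")
    if a > b:
        raise ValidationError(f"inverted interval: low {a} > high {b}")
    if a == b:
        return a
    fc = (c - a) / (b - a)
    if u <= fc:
        x = a + math.sqrt(u * (b - a) * (c - a))
    else:
        x = b - math.sqrt((1.0 - u) * (b - a) * (b - c))
    return min(max(x, a), b)  # guard one-ulp overshoot at the support edges


def sample_triangular(param: TriangularParam, rng: np.random.Generator) -> float:
    """Draw one value from ``param`` via inverse-CDF sampling of ``rng``."""
    return triangular_ppf(param, float(rng.random()))


# ---------------------------------------------------------------------------
# mRS outcome distributions
# ---------------------------------------------------------------------------


def normalize_mrs_distribution(
    values: Sequence[float] | np.ndarray, tolerance: float = 0.05
) -> np.ndarray:
    """Rescale a 7-entry mRS probability vector to sum to exactly 1.

    Published rows can sum to slightly less than 1 through rounding (the
    usual-care 90-day row sums to 0.99); dividing by the observed sum spreads
    the missing mass proportionally rather than privileging any state.  A sum
    deviating from 1 by more than ``tolerance`` signals a mis-entered row and
    raises instead of silently rescaling.
    """
    arr = np.asarray(values, dtype=float)
    if arr.shape != (N_STATES,):
        raise ValidationError(
            f"mRS distribution must have {N_STATES} entries, got shape {arr.shape}"
        )
    if np.any(arr < 0):
        raise ValidationError("mRS distribution entries must be non-negative")
    total = float(arr.sum())
    if total <= 0:
        raise ValidationError("mRS distribution has zero total mass")
    if abs(total - 1.0) > tolerance:
        raise ValidationError(
            f"mRS distribution sums to {total:.4f}, outside 1 +/- {tolerance}"
        )
    return arr / total


@dataclass
class MRSDistribution:
    """Probability mass over mRS 0-6 with optional per-entry uncertainty.

    Entries are stored as printed (the usual-care row keeps its 0.99 sum);
    :meth:`normalized` returns the renormalised vector used by the engine.
    """

    entries: tuple[TriangularParam, ...]

    def __post_init__(self) -> None:
        if len(self.entries) != N_STATES:
            raise ValidationError(
                f"mRS distribution needs {N_STATES} entries, got {len(self.entries)}"
            )
        for i, e in enumerate(self.entries):
            if not (0.0 <= e.low and e.high <= 1.0):
                raise ValidationError(
                    f"mRS {i} probability interval [{e.low}, {e.high}] outside [0, 1]"
                )
        # reject rows that cannot be normalized at all
        normalize_mrs_distribution(self.modes)

    @property
    def modes(self) -> np.ndarray:
        return np.array([e.mode for e in self.entries], dtype=float)

    def normalized(self, tolerance: float = 0.05) -> np.ndarray:
        return normalize_mrs_distribution(self.modes, tolerance=tolerance)

    @property
    def is_fixed(self) -> bool:
        return all(e.is_fixed for e in self.entries)


# ---------------------------------------------------------------------------
# Grouped parameter blocks
# ---------------------------------------------------------------------------


@dataclass
class ShortTermParams:
    """Decision-tree inputs for the first 3 months after stroke."""

    p_accurate_women: TriangularParam
    p_accurate_men: TriangularParam
    p_ivt_within_60min: float
    p_adverse_event: float
    dist_ivt: MRSDistribution
    dist_adverse: MRSDistribution
    dist_usual_care: MRSDistribution

    def __post_init__(self) -> None:
        for name in ("p_accurate_women", "p_accurate_men"):
            p: TriangularParam = getattr(self, name)
            if not (0.0 <= p.low and p.high <= 1.0):
                raise ValidationError(f"{name} interval outside [0, 1]")
        for name in ("p_ivt_within_60min", "p_adverse_event"):
            _check_probability(getattr(self, name), name)


@dataclass
class MarkovParams:
    """Long-term Markov model settings and transition probabilities."""

    p_recurrent_year1: TriangularParam
    p_recurrent_later: TriangularParam
    p_death_given_recurrence: float
    p_allcause_mortality_12m: TriangularParam
    discount_rate: float = 0.05
    horizon_years: int = 50
    cycle_length_years: float = 1.0
    start_age: float = 57.8
    start_age_sd: float = 10.9
    indirect_cost_age_cutoff: float = 64.0
    cohort_size: int = 5513

    def __post_init__(self) -> None:
        _check_probability(self.p_death_given_recurrence, "p_death_given_recurrence")
        for name in (
            "p_recurrent_year1",
            "p_recurrent_later",
            "p_allcause_mortality_12m",
        ):
            p: TriangularParam = getattr(self, name)
            if not (0.0 <= p.low and p.high <= 1.0):
                raise ValidationError(f"{name} interval outside [0, 1]")
        if self.horizon_years < 1:
            raise ValidationError("horizon_years must be >= 1")
        if self.discount_rate < 0:
            raise ValidationError("discount_rate must be >= 0")
        if self.cohort_size < 0:
            raise ValidationError("cohort_size must be >= 0")


@dataclass
class UtilityTable:
    """Health-state utilities for mRS 0-5; the dead state has utility 0.

    Separate rows apply in the first 12-month cycle (acute phase) and in all
    subsequent cycles.  Within each row utility is non-increasing in mRS.
    """

    year1: tuple[TriangularParam, ...]
    later: tuple[TriangularParam, ...]

    def __post_init__(self) -> None:
        for label, row in (("year1", self.year1), ("later", self.later)):
            if len(row) != 6:
                raise ValidationError(f"utilities.{label} needs 6 entries (mRS 0-5)")
            for i, u in enumerate(row):
                if not (0.0 <= u.low and u.high <= 1.0):
                    raise ValidationError(
                        f"utilities.{label} mRS {i} interval outside [0, 1]"
                    )
            for i in range(5):
                if row[i + 1].mode > row[i].mode:
                    raise ValidationError(
                        f"utilities.{label} must be non-increasing in mRS "
                        f"(mRS {i + 1} = {row[i + 1].mode} > mRS {i} = {row[i].mode})"
                    )

    def vector(self, phase: str) -> np.ndarray:
        """7-vector of utilities including 0 for the dead state."""
        row = self.year1 if phase == "year1" else self.later
        return np.array([u.mode for u in row] + [0.0], dtype=float)


@dataclass
class CostComponent:
    """One cost (2022 AUD) with a sensitivity interval.

    Published base values occasionally fall outside their published interval;
    these are accepted with an :class:`IntervalWarning` rather than rejected,
    because the interval is only used to bound sensitivity analyses.
    """

    base: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.base < 0 or self.low < 0 or self.high < 0:
            raise ValidationError("costs must be non-negative")
        if self.low > self.high:
            raise ValidationError(
                f"inverted cost interval: low {self.low} > high {self.high}"
            )
        if not (self.low <= self.base <= self.high):
            warnings.warn(
                f"cost base {self.base} outside published interval "
                f"[{self.low}, {self.high}]; accepted as printed",
                IntervalWarning,
                stacklevel=2,
            )

    @classmethod
    def fixed(cls, value: float) -> "CostComponent":
        return cls(base=value, low=value, high=value)

    @property
    def is_fixed(self) -> bool:
        return self.high == self.low


@dataclass
class CostTriple:
    medical: CostComponent
    non_medical: CostComponent
    indirect: CostComponent


@dataclass
class CostTable:
    """Per-state annual costs: year-1 rows for mRS 0-6, later rows for mRS 0-5.

    The year-1 mRS 6 triple is the one-off cost of a death occurring in the
    first model year; deaths in later years accrue nothing.  ``ivt_cost`` and
    ``recurrent_stroke_cost`` are one-off add-ons (thrombolysis delivery and
    an incident recurrent stroke).
    """

    year1: tuple[CostTriple, ...]
    later: tuple[CostTriple, ...]
    ivt_cost: CostComponent
    recurrent_stroke_cost: CostComponent

    def __post_init__(self) -> None:
        if len(self.year1) != 7:
            raise ValidationError("costs.year1 needs 7 rows (mRS 0-6)")
        if len(self.later) != 6:
            raise ValidationError("costs.later needs 6 rows (mRS 0-5)")
        med = [row.medical.base for row in self.year1[:6]]
        if any(med[i + 1] < med[i] for i in range(5)):
            raise ValidationError(
                "year-1 medical cost must be non-decreasing over mRS 0-5"
            )

    def vector(self, phase: str, component: str) -> np.ndarray:
        """6-vector of alive-state costs for ``phase`` in {'year1','later'}."""
        rows = self.year1[:6] if phase == "year1" else self.later
        return np.array([getattr(r, component).base for r in rows], dtype=float)

    @property
    def death_year1(self) -> CostTriple:
        return self.year1[DEAD_STATE]


@dataclass
class Extrapolation:
    """Inputs for scaling per-person results to the national level."""

    annual_hospitalisations: int = 7471
    ischaemic_fraction: float = 0.83
    ivt60_rate_national: float = 0.29

    def __post_init__(self) -> None:
        if self.annual_hospitalisations < 0:
            raise ValidationError("annual_hospitalisations must be >= 0")
        _check_probability(self.ischaemic_fraction, "ischaemic_fraction")
        _check_probability(self.ivt60_rate_national, "ivt60_rate_national")


@dataclass
class ParameterSet:
    """The complete, validated model input set."""

    short_term: ShortTermParams
    markov: MarkovParams
    utilities: UtilityTable
    costs: CostTable
    extrapolation: Extrapolation

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


def _check_probability(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} = {value} outside [0, 1]")


# ---------------------------------------------------------------------------
# Config parsing
# ---------------------------------------------------------------------------


def _require(mapping: Mapping[str, Any], key: str, path: str) -> Any:
    if not isinstance(mapping, Mapping):
        raise SchemaError(f"expected a mapping at {path!r}")
    if key not in mapping:
        raise SchemaError(f"missing field {path + '.' + key if path else key!r}")
    return mapping[key]


def _parse_triangular(node: Any, path: str) -> TriangularParam:
    if isinstance(node, (int, float)):
        return TriangularParam.fixed(float(node))
    mode = float(_require(node, "mode", path))
    low = float(node.get("low", mode))
    high = float(node.get("high", mode))
    try:
        return TriangularParam(mode=mode, low=low, high=high)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def _parse_distribution(node: Any, path: str) -> MRSDistribution:
    if not isinstance(node, Sequence) or len(node) != N_STATES:
        raise SchemaError(f"{path} must be a list of {N_STATES} entries (mRS 0-6)")
    entries = tuple(
        _parse_triangular(item, f"{path}[mrs{i}]") for i, item in enumerate(node)
    )
    try:
        return MRSDistribution(entries)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def _parse_cost_component(node: Any, path: str) -> CostComponent:
    if isinstance(node, (int, float)):
        # no published interval: sensitivity range is +/- 50% by convention
        base = float(node)
        return CostComponent(base=base, low=0.5 * base, high=1.5 * base)
    base = float(_require(node, "base", path))
    low = float(node.get("low", base))
    high = float(node.get("high", base))
    try:
        return CostComponent(base=base, low=low, high=high)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def _parse_cost_triple(node: Any, path: str) -> CostTriple:
    return CostTriple(
        medical=_parse_cost_component(_require(node, "medical", path), f"{path}.medical"),
        non_medical=_parse_cost_component(
            _require(node, "non_medical", path), f"{path}.non_medical"
        ),
        indirect=_parse_cost_component(
            _require(node, "indirect", path), f"{path}.indirect"
        ),
    )


def load_parameter_set(config_source: str | Path | Mapping[str, Any]) -> ParameterSet:
    """Load and validate a parameter set from YAML text, a path, or a mapping.

    Raises :class:`SchemaError` naming any missing field and
    :class:`ValidationError` for out-of-range values, inverted intervals or
    distributions that cannot be normalized.
    """
    if isinstance(config_source, Mapping):
        raw: Mapping[str, Any] = config_source
    else:
        if isinstance(config_source, Path) or (
            isinstance(config_source, str)
            and "\n" not in config_source
            and Path(config_source).exists()
        ):
            text = Path(config_source).read_text()
        else:
            text = str(config_source)
        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise SchemaError("config did not parse to a mapping")

    st = _require(raw, "short_term", "")
    short_term = ShortTermParams(
        p_accurate_women=_parse_triangular(
            _require(st, "p_accurate_women", "short_term"), "short_term.p_accurate_women"
        ),
        p_accurate_men=_parse_triangular(
            _require(st, "p_accurate_men", "short_term"), "short_term.p_accurate_men"
        ),
        p_ivt_within_60min=float(_require(st, "p_ivt_within_60min", "short_term")),
        p_adverse_event=float(_require(st, "p_adverse_event", "short_term")),
        dist_ivt=_parse_distribution(_require(st, "dist_ivt", "short_term"), "short_term.dist_ivt"),
        dist_adverse=_parse_distribution(
            _require(st, "dist_adverse", "short_term"), "short_term.dist_adverse"
        ),
        dist_usual_care=_parse_distribution(
            _require(st, "dist_usual_care", "short_term"), "short_term.dist_usual_care"
        ),
    )

    mk = _require(raw, "markov", "")
    markov = MarkovParams(
        p_recurrent_year1=_parse_triangular(
            _require(mk, "p_recurrent_year1", "markov"), "markov.p_recurrent_year1"
        ),
        p_recurrent_later=_parse_triangular(
            _require(mk, "p_recurrent_later", "markov"), "markov.p_recurrent_later"
        ),
        p_death_given_recurrence=float(
            _require(mk, "p_death_given_recurrence", "markov")
        ),
        p_allcause_mortality_12m=_parse_triangular(
            _require(mk, "p_allcause_mortality_12m", "markov"),
            "markov.p_allcause_mortality_12m",
        ),
        discount_rate=float(_require(mk, "discount_rate", "markov")),
        horizon_years=int(_require(mk, "horizon_years", "markov")),
        cycle_length_years=float(mk.get("cycle_length_years", 1.0)),
        start_age=float(_require(mk, "start_age", "markov")),
        start_age_sd=float(mk.get("start_age_sd", 0.0)),
        indirect_cost_age_cutoff=float(_require(mk, "indirect_cost_age_cutoff", "markov")),
        cohort_size=int(_require(mk, "cohort_size", "markov")),
    )

    ut = _require(raw, "utilities", "")
    for label in ("year1", "later"):
        if label not in ut:
            raise SchemaError(f"missing field 'utilities.{label}'")
    utilities = UtilityTable(
        year1=tuple(
            _parse_triangular(item, f"utilities.year1[mrs{i}]")
            for i, item in enumerate(ut["year1"])
        ),
        later=tuple(
            _parse_triangular(item, f"utilities.later[mrs{i}]")
            for i, item in enumerate(ut["later"])
        ),
    )

    co = _require(raw, "costs", "")
    year1_rows = _require(co, "year1", "costs")
    later_rows = _require(co, "later", "costs")
    if not isinstance(year1_rows, Sequence) or len(year1_rows) != 7:
        raise SchemaError("costs.year1 must list 7 rows (mRS 0-6)")
    if not isinstance(later_rows, Sequence) or len(later_rows) != 6:
        raise SchemaError("costs.later must list 6 rows (mRS 0-5)")
    costs = CostTable(
        year1=tuple(
            _parse_cost_triple(row, f"costs.year1[mrs{i}]")
            for i, row in enumerate(year1_rows)
        ),
        later=tuple(
            _parse_cost_triple(row, f"costs.later[mrs{i}]")
            for i, row in enumerate(later_rows)
        ),
        ivt_cost=_parse_cost_component(_require(co, "ivt_cost", "costs"), "costs.ivt_cost"),
        recurrent_stroke_cost=_parse_cost_component(
            _require(co, "recurrent_stroke_cost", "costs"), "costs.recurrent_stroke_cost"
        ),
    )

    ex = _require(raw, "extrapolation", "")
    extrapolation = Extrapolation(
        annual_hospitalisations=int(_require(ex, "annual_hospitalisations", "extrapolation")),
        ischaemic_fraction=float(_require(ex, "ischaemic_fraction", "extrapolation")),
        ivt60_rate_national=float(_require(ex, "ivt60_rate_national", "extrapolation")),
    )

    return ParameterSet(
        short_term=short_term,
        markov=markov,
        utilities=utilities,
        costs=costs,
        extrapolation=extrapolation,
    )


def default_parameter_set() -> ParameterSet:
    """Load the shipped default configuration (the published input tables)."""
    text = resources.files("stroke_cea").joinpath("data/default_parameters.yaml").read_text()
    with warnings.catch_warnings():
        # the shipped tables contain the published base-outside-interval rows
        warnings.simplefilter("ignore", IntervalWarning)
        return load_parameter_set(text)


def default_config_text() -> str:
    """Raw YAML text of the shipped default configuration."""
    return resources.files("stroke_cea").joinpath("data/default_parameters.yaml").read_text()


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _tri_dict(p: TriangularParam) -> Any:
    if p.is_fixed:
        return p.mode
    return {"mode": p.mode, "low": p.low, "high": p.high}


def _cost_dict(c: CostComponent) -> Any:
    return {"base": c.base, "low": c.low, "high": c.high}


def serialize_parameter_set(ps: ParameterSet) -> dict[str, Any]:
    """Plain-dict form of a parameter set; re-loadable by load_parameter_set."""
    st = ps.short_term
    mk = ps.markov
    return {
        "short_term": {
            "p_accurate_women": _tri_dict(st.p_accurate_women),
            "p_accurate_men": _tri_dict(st.p_accurate_men),
            "p_ivt_within_60min": st.p_ivt_within_60min,
            "p_adverse_event": st.p_adverse_event,
            "dist_ivt": [_tri_dict(e) for e in st.dist_ivt.entries],
            "dist_adverse": [_tri_dict(e) for e in st.dist_adverse.entries],
            "dist_usual_care": [_tri_dict(e) for e in st.dist_usual_care.entries],
        },
        "markov": {
            "p_recurrent_year1": _tri_dict(mk.p_recurrent_year1),
            "p_recurrent_later": _tri_dict(mk.p_recurrent_later),
            "p_death_given_recurrence": mk.p_death_given_recurrence,
            "p_allcause_mortality_12m": _tri_dict(mk.p_allcause_mortality_12m),
            "discount_rate": mk.discount_rate,
            "horizon_years": mk.horizon_years,
            "cycle_length_years": mk.cycle_length_years,
            "start_age": mk.start_age,
            "start_age_sd": mk.start_age_sd,
            "indirect_cost_age_cutoff": mk.indirect_cost_age_cutoff,
            "cohort_size": mk.cohort_size,
        },
        "utilities": {
            "year1": [_tri_dict(u) for u in ps.utilities.year1],
            "later": [_tri_dict(u) for u in ps.utilities.later],
        },
        "costs": {
            "year1": [
                {
                    "medical": _cost_dict(r.medical),
                    "non_medical": _cost_dict(r.non_medical),
                    "indirect": _cost_dict(r.indirect),
                }
                for r in ps.costs.year1
            ],
            "later": [
                {
                    "medical": _cost_dict(r.medical),
                    "non_medical": _cost_dict(r.non_medical),
                    "indirect": _cost_dict(r.indirect),
                }
                for r in ps.costs.later
            ],
            "ivt_cost": _cost_dict(ps.costs.ivt_cost),
            "recurrent_stroke_cost": _cost_dict(ps.costs.recurrent_stroke_cost),
        },
        "extrapolation": {
            "annual_hospitalisations": ps.extrapolation.annual_hospitalisations,
            "ischaemic_fraction": ps.extrapolation.ischaemic_fraction,
            "ivt60_rate_national": ps.extrapolation.ivt60_rate_national,
        },
    }


def save_parameter_set(ps: ParameterSet, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(serialize_parameter_set(ps), sort_keys=False))


def parameter_report(ps: ParameterSet) -> str:
    """Plain-text audit listing of every loaded value."""
    lines: list[str] = ["Loaded parameter set", "=" * 60]

    def tri(name: str, p: TriangularParam) -> None:
        if p.is_fixed:
            lines.append(f"{name:<44s} {p.mode:>10.4f}  (fixed)")
        else:
            lines.append(f"{name:<44s} {p.mode:>10.4f}  [{p.low}, {p.high}]")

    st = ps.short_term
    tri("short_term.p_accurate_women", st.p_accurate_women)
    tri("short_term.p_accurate_men", st.p_accurate_men)
    tri("short_term.p_ivt_within_60min", TriangularParam.fixed(st.p_ivt_within_60min))
    tri("short_term.p_adverse_event", TriangularParam.fixed(st.p_adverse_event))
    for label in ("dist_ivt", "dist_adverse", "dist_usual_care"):
        dist: MRSDistribution = getattr(st, label)
        for i, e in enumerate(dist.entries):
            tri(f"short_term.{label}[mrs{i}]", e)
    mk = ps.markov
    tri("markov.p_recurrent_year1", mk.p_recurrent_year1)
    tri("markov.p_recurrent_later", mk.p_recurrent_later)
    tri("markov.p_death_given_recurrence", TriangularParam.fixed(mk.p_death_given_recurrence))
    tri("markov.p_allcause_mortality_12m", mk.p_allcause_mortality_12m)
    for name in (
        "discount_rate",
        "horizon_years",
        "cycle_length_years",
        "start_age",
        "start_age_sd",
        "indirect_cost_age_cutoff",
        "cohort_size",
    ):
        lines.append(f"markov.{name:<37s} {getattr(mk, name)!r:>10}")
    for label, row in (("year1", ps.utilities.year1), ("later", ps.utilities.later)):
        for i, u in enumerate(row):
            tri(f"utilities.{label}[mrs{i}]", u)
    for label, rows in (("year1", ps.costs.year1), ("later", ps.costs.later)):
        for i, r in enumerate(rows):
            for comp in ("medical", "non_medical", "indirect"):
                c: CostComponent = getattr(r, comp)
                lines.append(
                    f"costs.{label}[mrs{i}].{comp:<24s} {c.base:>12,.0f}  [{c.low:,.0f}, {c.high:,.0f}]"
                )
    for comp_name in ("ivt_cost", "recurrent_stroke_cost"):
        c = getattr(ps.costs, comp_name)
        lines.append(
            f"costs.{comp_name:<32s} {c.base:>12,.0f}  [{c.low:,.0f}, {c.high:,.0f}]"
        )
    ex = ps.extrapolation
    lines.append(f"extrapolation.annual_hospitalisations       {ex.annual_hospitalisations}")
    lines.append(f"extrapolation.ischaemic_fraction            {ex.ischaemic_fraction}")
    lines.append(f"extrapolation.ivt60_rate_national           {ex.ivt60_rate_national}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Probabilistic draws
# ---------------------------------------------------------------------------


def _draw_tri(p: TriangularParam, rng: np.random.Generator) -> TriangularParam:
    if p.is_fixed:
        return p
    return replace(p, mode=sample_triangular(p, rng))


def _draw_distribution(d: MRSDistribution, rng: np.random.Generator) -> MRSDistribution:
    if d.is_fixed:
        return d
    draws = np.array([sample_triangular(e, rng) for e in d.entries])
    total = draws.sum()
    if total <= 0:
        draws = d.modes
        total = draws.sum()
    draws = draws / total
    entries = tuple(
        replace(e, mode=float(v), low=min(e.low, float(v)), high=max(e.high, float(v)))
        for e, v in zip(d.entries, draws)
    )
    return MRSDistribution(entries)


def draw_parameter_set(ps: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One probabilistic-sensitivity-analysis draw of the parameter set.

    Every triangular parameter is sampled once; fixed parameters (published
    with no distribution, or with a zero-width interval) are left at their
    base values.  Sampled mRS rows are renormalised to sum to 1.  Costs keep
    their base values unless a published interval exists, in which case the
    component is drawn from a triangular distribution over that interval with
    the base value as mode.
    """
    out = ps.copy()
    st = out.short_term
    st.p_accurate_women = _draw_tri(st.p_accurate_women, rng)
    st.p_accurate_men = _draw_tri(st.p_accurate_men, rng)
    st.dist_ivt = _draw_distribution(st.dist_ivt, rng)
    st.dist_usual_care = _draw_distribution(st.dist_usual_care, rng)
    # dist_adverse is fixed (published without a distribution)
    mk = out.markov
    mk.p_recurrent_year1 = _draw_tri(mk.p_recurrent_year1, rng)
    mk.p_recurrent_later = _draw_tri(mk.p_recurrent_later, rng)
    mk.p_allcause_mortality_12m = _draw_tri(mk.p_allcause_mortality_12m, rng)
    # utilities are drawn independently (as published); neighbouring draws may
    # cross the base-table severity ordering, so assign fields directly
    out.utilities.year1 = tuple(_draw_tri(u, rng) for u in out.utilities.year1)
    out.utilities.later = tuple(_draw_tri(u, rng) for u in out.utilities.later)
    # assign fields directly: independent cost draws may legitimately cross
    # the base-table monotonicity check enforced at construction time
    out.costs.year1 = tuple(_draw_cost_triple(r, rng) for r in out.costs.year1)
    out.costs.later = tuple(_draw_cost_triple(r, rng) for r in out.costs.later)
    out.costs.ivt_cost = _draw_cost(out.costs.ivt_cost, rng)
    out.costs.recurrent_stroke_cost = _draw_cost(out.costs.recurrent_stroke_cost, rng)
    return out


def _draw_cost(c: CostComponent, rng: np.random.Generator) -> CostComponent:
    if c.is_fixed:
        return c
    lo, hi = c.low, c.high
    mode = min(max(c.base, lo), hi)  # clamp published out-of-interval bases
    value = triangular_ppf(TriangularParam(mode=mode, low=lo, high=hi), float(rng.random()))
    return CostComponent(base=value, low=min(lo, value), high=max(hi, value))


def _draw_cost_triple(t: CostTriple, rng: np.random.Generator) -> CostTriple:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", IntervalWarning)
        return CostTriple(
            medical=_draw_cost(t.medical, rng),
            non_medical=_draw_cost(t.non_medical, rng),
            indirect=_draw_cost(t.indirect, rng),
        )
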