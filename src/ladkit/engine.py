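"""The LaD monitoring engine.

The engine encodes labor-and-delivery decision support as a finite,
exhaustively checkable function.  A patient's situation is one point
in a configured scenario space — the Cartesian product of categorical
factors (amniotic status, fetal heart rate pattern, cervical progress,
contraction adequacy, blood pressure, fetal descent).  Management
recursion is encoded statically in the factor states themselves:
"recovered"/"responding" coordinates mean first-line management of
that abnormality succeeded, "persistent"/"arrested" mean it failed.
The final decision combines the per-abnormality outcomes: all resolved
keeps the patient on the routine monitoring track, an unresolved
abnormality escalates, and an unresolved *critical* abnormality moves
to the expedited-delivery track.

Under the default ruleset the space has exactly 1152 scenarios and
every recommendation contains at most 16 of the 22 catalog actions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from numbers import Real
from typing import Mapping, Sequence

from .config import Factor, LadConfig, ParameterSpec
from .errors import ConfigError, ValidationError

__all__ = [
    "Observation",
    "ScenarioState",
    "Recommendation",
    "ManagementOutcome",
    "classify_observation",
    "next_due",
    "manage_abnormality",
    "recommend_actions",
    "enumerate_scenarios",
]

_TIER_ORDER = ("routine", "escalate", "deliver")


@dataclass(frozen=True)
class Observation:
    """One classified monitoring observation."""

    parameter: str
    time_minutes: int
    raw_value: object
    state: str


@dataclass(frozen=True)
class ScenarioState:
    """One point of the enumerated scenario space.

    ``coords`` is an ordered tuple of ``(factor, state)`` pairs in
    factorization order; ``scenario_id`` is the position in the
    lexicographic enumeration.
    """

    scenario_id: int
    coords: tuple[tuple[str, str], ...]

    def __getitem__(self, factor: str) -> str:
        for name, state in self.coords:
            if name == factor:
                return state
        raise KeyError(factor)

    def as_dict(self) -> dict[str, str]:
        return dict(self.coords)

    def replace(self, factor: str, state: str, scenario_id: int = -1) -> "ScenarioState":
        """A copy with one coordinate changed (id not recomputed)."""
        coords = tuple((n, state if n == factor else s) for n, s in self.coords)
        return ScenarioState(scenario_id=scenario_id, coords=coords)


@dataclass(frozen=True)
class ManagementOutcome:
    """Result of applying the management rule for one abnormality."""

    parameter: str
    attempted_rule: str
    resolved: bool
    critical: bool = False


@dataclass(frozen=True)
class Recommendation:
    """The engine's action set for one scenario.

    ``rationale`` lists ``(factor, state, rule_id)`` triples explaining
    which rules fired, including the final-decision tier.
    """

    scenario_id: int
    actions: frozenset[int]
    rationale: tuple[tuple[str, str, str], ...] = field(default_factory=tuple)


def classify_observation(spec: ParameterSpec, raw_value) -> str:
    """Map a raw measured value to one of the parameter's states.

    Continuous values are checked against the configured physical range
    and then binned (bins are ordered: ``below`` is a strict upper
    bound, ``upto`` inclusive, a bound-free bin catches the rest).
    Categorical values are looked up in the category map.
    """
    if spec.value_kind == "continuous":
        if not isinstance(raw_value, Real) or isinstance(raw_value, bool):
            raise ValidationError(
                f"{spec.name}: expected a numeric value, got {raw_value!r}"
            )
        value = float(raw_value)
        if spec.physical_range is not None:
            lo, hi = spec.physical_range
            if not (lo <= value <= hi):
                raise ValidationError(
                    f"{spec.name}: value {value} outside physical range [{lo}, {hi}]"
                )
        assert spec.bins is not None
        for b in spec.bins:
            if b.below is not None and value < b.below:
                return b.state
            if b.upto is not None and value <= b.upto:
                return b.state
            if b.below is None and b.upto is None:
                return b.state
        return spec.bins[-1].state
    # categorical
    if not isinstance(raw_value, str):
        raise ValidationError(f"{spec.name}: expected a category label, got {raw_value!r}")
    assert spec.categories is not None
    label = raw_value.strip().lower()
    if label in spec.categories:
        return spec.categories[label]
    if label in spec.states:  # already a state name
        return label
    raise ValidationError(
        f"{spec.name}: unknown category {raw_value!r} "
        f"(known: {sorted(spec.categories)})"
    )


def observe(spec: ParameterSpec, time_minutes: int, raw_value) -> Observation:
    """Classify ``raw_value`` and wrap it as an :class:`Observation`."""
    if time_minutes < 0:
        raise ValidationError("time_minutes must be non-negative")
    return Observation(
        parameter=spec.name,
        time_minutes=time_minutes,
        raw_value=raw_value,
        state=classify_observation(spec, raw_value),
    )


def next_due(
    specs: Sequence[ParameterSpec],
    last_observed: Mapping[str, int],
    now: int,
    stage: str = "first_stage",
) -> list[str]:
    """Parameters due for observation at time ``now`` (minutes).

    A parameter is due when it applies to the current labor stage and
    either has never been observed or its monitoring interval has
    elapsed since the last observation.
    """
    if stage not in ("first_stage", "second_stage"):
        raise ValidationError(f"unknown stage {stage!r}")
    for name, t in last_observed.items():
        if t > now:
            raise ValidationError(f"{name}: last observation at {t} is after now={now}")
    due = []
    for spec in specs:
        if spec.applicable_stage not in ("both", stage):
            continue
        last = last_observed.get(spec.name)
        if last is None or now - last >= spec.interval_minutes:
            due.append(spec.name)
    return due


def _rule_for(config: LadConfig, factor: str, state: str):
    per_state = config.rules.get(factor, {})
    if state not in per_state:
        raise ConfigError(f"no management rule for ({factor}, {state})")
    return per_state[state]


def manage_abnormality(
    state: ScenarioState, parameter: str, config: LadConfig
) -> ManagementOutcome:
    """Apply the configured management rule for one abnormal factor.

    The scenario coordinate itself encodes whether first-line
    management succeeded, so the outcome is deterministic.
    """
    factor = config.factor(parameter)
    coord = state[parameter]
    if coord in factor.normal_states:
        raise ValidationError(
            f"{parameter}={coord} is a normal state; nothing to manage"
        )
    rule = _rule_for(config, parameter, coord)
    return ManagementOutcome(
        parameter=parameter,
        attempted_rule=f"{parameter}:{coord}",
        resolved=rule.resolved,
        critical=rule.critical,
    )


def recommend_actions(state: ScenarioState, config: LadConfig) -> Recommendation:
    """Combine per-abnormality rules and the final decision for one scenario.

    The action set is the union of every fired rule's actions plus the
    final-decision tier's actions.  Tiers are: ``routine`` when every
    abnormality resolved (or none exists), ``escalate`` when any is
    unresolved, ``deliver`` when an unresolved abnormality is critical.
    Pure function of ``(state, config)``.
    """
    actions: set[int] = set()
    rationale: list[tuple[str, str, str]] = []
    tier = 0
    for name, coord in state.coords:
        factor = config.factor(name)
        if coord not in factor.states:
            raise ConfigError(f"scenario has unknown state {name}={coord!r}")
        if coord in factor.normal_states:
            continue
        rule = _rule_for(config, name, coord)
        actions.update(rule.actions)
        rationale.append((name, coord, f"{name}:{coord}"))
        if not rule.resolved:
            tier = max(tier, 2 if rule.critical else 1)
    tier_name = _TIER_ORDER[tier]
    actions.update(getattr(config.final_decision, tier_name))
    rationale.append(("final_decision", tier_name, f"final:{tier_name}"))
    cap = config.meta.max_recommendation_actions
    if len(actions) > cap:
        raise ConfigError(
            f"scenario {state.scenario_id}: {len(actions)} actions exceed the "
            f"cap of {cap}; trim the rule action lists"
        )
    return Recommendation(
        scenario_id=state.scenario_id,
        actions=frozenset(actions),
        rationale=tuple(rationale),
    )


def enumerate_scenarios(factorization: Sequence[Factor]) -> list[ScenarioState]:
    """Enumerate the full scenario space in lexicographic factor order.

    ``scenario_id`` equals the list position; the last factor varies
    fastest.  Under the default ruleset the result has 1152 entries.
    """
    if not factorization:
        raise ValidationError("factorization must contain at least one factor")
    names = [f.name for f in factorization]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate factor names in factorization")
    out = []
    for i, combo in enumerate(itertools.product(*(f.states for f in factorization))):
        out.append(ScenarioState(scenario_id=i, coords=tuple(zip(names, combo))))
    return out


def scenario_index(factorization: Sequence[Factor], coords: Mapping[str, str]) -> int:
    """Mixed-radix index of a coordinate assignment in enumeration order."""
    idx = 0
    for f in factorization:
        idx = idx * len(f.states) + f.states.index(coords[f.name])
    return idx
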