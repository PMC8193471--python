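"""Ruleset configuration: schema, validation and loading.

A ruleset bundles everything the monitoring engine needs:

* ``parameters`` — the monitored labor parameters with their
  classification states, normal ranges and monitoring intervals;
* ``factorization`` — the categorical factors whose Cartesian product
  is the patient scenario space;
* ``actions`` — the catalog of candidate clinical actions;
* ``rules`` — per-abnormality management rules mapping a factor state
  to an action set, a resolution flag and a criticality flag;
* ``final_decision`` — the action sets attached to each outcome tier.

Structural contracts (the expected scenario count, the expected action
count, rule coverage of every non-normal factor state) are enforced at
load time so that downstream code can assume a coherent ruleset.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigError

ALLOWED_INTERVALS = (30, 60, 120, 240)

Stage = Literal["first_stage", "second_stage", "both"]
ActionCategory = Literal["observe", "intervene", "escalate", "deliver"]


class BinSpec(BaseModel):
    """One classification bin for a continuous parameter.

    Bins are evaluated in order: ``below`` matches ``value < below``,
    ``upto`` matches ``value <= upto``; a bin with neither bound is a
    catch-all and must come last.
    """

    model_config = ConfigDict(extra="forbid")

    state: str
    below: Optional[float] = None
    upto: Optional[float] = None


class ParameterSpec(BaseModel):
    """One monitored labor parameter."""

    model_config = ConfigDict(extra="forbid")

    name: str
    value_kind: Literal["continuous", "categorical"]
    unit: Optional[str] = None
    physical_range: Optional[tuple[float, float]] = None
    states: list[str] = Field(min_length=2)
    normal_states: list[str] = Field(min_length=1)
    bins: Optional[list[BinSpec]] = None
    categories: Optional[dict[str, str]] = None
    interval_minutes: int
    applicable_stage: Stage = "both"

    @model_validator(mode="after")
    def _check(self) -> "ParameterSpec":
        if self.interval_minutes not in ALLOWED_INTERVALS:
            raise ValueError(
                f"{self.name}: interval_minutes must be one of "
                f"{ALLOWED_INTERVALS}, got {self.interval_minutes}"
            )
        if not set(self.normal_states) < set(self.states):
            raise ValueError(
                f"{self.name}: normal_states must be a non-empty proper "
                "subset of states"
            )
        if self.value_kind == "continuous":
            if not self.bins:
                raise ValueError(f"{self.name}: continuous parameter needs bins")
            bin_states = {b.state for b in self.bins}
            if bin_states != set(self.states):
                raise ValueError(
                    f"{self.name}: bins cover {sorted(bin_states)}, "
                    f"states are {sorted(self.states)}"
                )
            if any(b.below is None and b.upto is None for b in self.bins[:-1]):
                raise ValueError(f"{self.name}: only the last bin may be unbounded")
        else:
            if not self.categories:
                raise ValueError(f"{self.name}: categorical parameter needs categories")
            unknown = set(self.categories.values()) - set(self.states)
            if unknown:
                raise ValueError(f"{self.name}: categories map to unknown states {unknown}")
        return self


class Factor(BaseModel):
    """One categorical factor of the scenario-space factorization."""

    model_config = ConfigDict(extra="forbid")

    name: str
    states: list[str] = Field(min_length=2)
    normal_states: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "Factor":
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"{self.name}: duplicate factor states")
        if not set(self.normal_states) <= set(self.states):
            raise ValueError(f"{self.name}: normal_states not a subset of states")
        return self


class ActionDef(BaseModel):
    """One catalog action."""

    model_config = ConfigDict(extra="forbid")

    action_id: int = Field(ge=1)
    label: str
    category: ActionCategory


class StateRule(BaseModel):
    """Management rule for one abnormal factor state."""

    model_config = ConfigDict(extra="forbid")

    actions: list[int]
    resolved: bool
    critical: bool = False


class FinalDecision(BaseModel):
    """Action sets for the three outcome tiers."""

    model_config = ConfigDict(extra="forbid")

    routine: list[int]
    escalate: list[int]
    deliver: list[int]


class Meta(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str = "lad"
    active_phase_start_cm: int = 5
    expected_scenario_count: Optional[int] = 1152
    expected_action_count: Optional[int] = 22
    max_recommendation_actions: int = 16


class LadConfig(BaseModel):
    """A complete, validated ruleset."""

    model_config = ConfigDict(extra="forbid")

    meta: Meta = Field(default_factory=Meta)
    parameters: list[ParameterSpec]
    factorization: list[Factor] = Field(min_length=1)
    actions: list[ActionDef]
    rules: dict[str, dict[str, StateRule]]
    final_decision: FinalDecision

    @model_validator(mode="after")
    def _check(self) -> "LadConfig":
        n_scenarios = math.prod(len(f.states) for f in self.factorization)
        if (
            self.meta.expected_scenario_count is not None
            and n_scenarios != self.meta.expected_scenario_count
        ):
            raise ValueError(
                f"factorization enumerates {n_scenarios} scenarios, expected "
                f"{self.meta.expected_scenario_count} "
                "(set meta.expected_scenario_count to null to allow)"
            )
        ids = [a.action_id for a in self.actions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate action_id in catalog")
        if (
            self.meta.expected_action_count is not None
            and len(ids) != self.meta.expected_action_count
        ):
            raise ValueError(
                f"action catalog has {len(ids)} entries, expected "
                f"{self.meta.expected_action_count}"
            )
        id_set = set(ids)
        factor_names = {f.name for f in self.factorization}
        for fname, per_state in self.rules.items():
            if fname not in factor_names:
                raise ValueError(f"rules reference unknown factor {fname!r}")
            factor = next(f for f in self.factorization if f.name == fname)
            for state, rule in per_state.items():
                if state not in factor.states:
                    raise ValueError(f"rule for unknown state {fname}={state!r}")
                bad = set(rule.actions) - id_set
                if bad:
                    raise ValueError(f"rule {fname}={state} uses unknown actions {sorted(bad)}")
        # every non-normal factor state must be covered by a rule
        uncovered = [
            (f.name, s)
            for f in self.factorization
            for s in f.states
            if s not in f.normal_states and s not in self.rules.get(f.name, {})
        ]
        if uncovered:
            raise ValueError(f"factor states without a management rule: {uncovered}")
        for tier in ("routine", "escalate", "deliver"):
            bad = set(getattr(self.final_decision, tier)) - id_set
            if bad:
                raise ValueError(f"final_decision.{tier} uses unknown actions {sorted(bad)}")
        return self

    # -- convenience lookups -------------------------------------------------

    def parameter(self, name: str) -> ParameterSpec:
        for p in self.parameters:
            if p.name == name:
                return p
        raise ConfigError(f"unknown parameter {name!r}")

    def factor(self, name: str) -> Factor:
        for f in self.factorization:
            if f.name == name:
                return f
        raise ConfigError(f"unknown factor {name!r}")

    @property
    def action_ids(self) -> frozenset[int]:
        return frozenset(a.action_id for a in self.actions)

    def action(self, action_id: int) -> ActionDef:
        for a in self.actions:
            if a.action_id == action_id:
                return a
        raise ConfigError(f"unknown action id {action_id}")


def load_config(path: str | Path | None = None) -> LadConfig:
    """Load a ruleset from YAML; with ``path=None`` load the default.

    Raises :class:`ConfigError` on any structural problem.
    """
    if path is None:
        text = resources.files("ladkit.data").joinpath("default_config.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    try:
        return LadConfig.model_validate(raw)
    except ValueError as exc:  # pydantic ValidationError is a ValueError
        raise ConfigError(str(exc)) from exc


def default_config() -> LadConfig:
    """The ruleset shipped with the package."""
    return load_config(None)
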