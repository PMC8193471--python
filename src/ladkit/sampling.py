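"""Stratified case sampling from the scenario space.

The validation design stratifies the enumerated scenarios by amniotic
fluid status (membranes intact / fluid clear / fluid opaque or foul
smelling) and draws a fixed number of cases uniformly without
replacement from each stratum.  Sampling is seeded and reproducible;
within a stratum a partial Fisher–Yates shuffle gives exact uniform
without-replacement draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .engine import ScenarioState
from .errors import ValidationError

logger = logging.getLogger(__name__)

STRATUM_FACTOR = "amniotic_status"
DEFAULT_STRATA = ("membranes_intact", "fluid_clear", "fluid_opaque_or_foul")


@dataclass(frozen=True)
class Stratum:
    name: str
    member_ids: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class CaseSample:
    """A reproducible stratified draw of case scenarios."""

    seed: int
    per_stratum: dict[str, tuple[int, ...]]
    cases: tuple[int, ...]

    def case_labels(self) -> dict[str, int]:
        """P1, P2, ... labels in draw order."""
        return {f"P{i + 1}": sid for i, sid in enumerate(self.cases)}


def stratify(
    scenarios: Sequence[ScenarioState],
    factor: str = STRATUM_FACTOR,
    strata_names: Sequence[str] = DEFAULT_STRATA,
) -> list[Stratum]:
    """Partition scenarios by one factor's state.

    Returns one :class:`Stratum` per name in ``strata_names`` (in that
    order); an absent stratum is returned empty with a logged warning.
    """
    if not scenarios:
        raise ValidationError("cannot stratify an empty scenario list")
    members: dict[str, list[int]] = {name: [] for name in strata_names}
    for s in scenarios:
        try:
            state = s[factor]
        except KeyError:
            raise ValidationError(
                f"scenario {s.scenario_id} lacks factor {factor!r}"
            ) from None
        if state not in members:
            raise ValidationError(
                f"scenario {s.scenario_id}: {factor}={state!r} is not one of "
                f"{tuple(strata_names)}"
            )
        members[state].append(s.scenario_id)
    for name, ids in members.items():
        if not ids:
            logger.warning("stratum %r is empty", name)
    return [Stratum(name=n, member_ids=tuple(members[n])) for n in strata_names]


def _draw_without_replacement(
    ids: Sequence[int], n: int, rng: np.random.Generator
) -> list[int]:
    """Partial Fisher–Yates: first ``n`` positions of a uniform shuffle."""
    pool = list(ids)
    for i in range(n):
        j = int(rng.integers(i, len(pool)))
        pool[i], pool[j] = pool[j], pool[i]
    return pool[:n]


def sample_cases(
    strata: Sequence[Stratum], per_stratum: int, seed: int
) -> CaseSample:
    """Draw ``per_stratum`` scenarios uniformly from each stratum.

    The same seed always yields the same sample.  Raises
    :class:`ValidationError` naming the first stratum smaller than the
    requested draw.
    """
    if per_stratum < 1:
        raise ValidationError("per_stratum must be >= 1")
    for st in strata:
        if len(st) < per_stratum:
            raise ValidationError(
                f"stratum {st.name!r} has {len(st)} scenarios, "
                f"cannot draw {per_stratum}"
            )
    rng = np.random.default_rng(seed)
    drawn: dict[str, tuple[int, ...]] = {}
    cases: list[int] = []
    for st in strata:
        picked = tuple(_draw_without_replacement(st.member_ids, per_stratum, rng))
        drawn[st.name] = picked
        cases.extend(picked)
    return CaseSample(seed=seed, per_stratum=drawn, cases=tuple(cases))
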