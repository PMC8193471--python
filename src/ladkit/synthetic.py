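"""Synthetic expert panels with controllable consensus.

Generative model: for every (case, action) a latent selection
probability p is drawn from a symmetric Beta(1/c, 1/c) distribution,
where c is the ``consensus_concentration``.  Each rater then selects
each action independently with probability p.  Large c pushes p toward
{0, 1} — every rater sees the same near-deterministic signal, so
agreement is high; c → 0 pushes p toward 1/2 — raters flip independent
fair coins and agreement collapses to chance.  E[p] = 1/2 at every c,
so the expected number of selections per rater-case is n_actions/2
before truncation.

If a rater-case block exceeds ``max_select``, the selections with the
lowest latent p are dropped: the truncation is deterministic given the
draw and preserves the high-consensus actions.

``fixed_p`` bypasses the Beta draw with a constant probability, which
gives the two analytic corner cases (p ≡ 0: empty selections, every
pair score undefined; p ≡ 1/2: independent raters with expected
directed sensitivity 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .stats import (
    SelectionMatrix,
    matrix_correlations,
    reliability_alpha,
)

__all__ = ["PanelModel", "generate_panel", "recover_agreement"]


@dataclass(frozen=True)
class PanelModel:
    """Parameters of the synthetic rater panel.

    Defaults mirror the validation study design: 5 experts, 5 analyzed
    cases, 22 candidate actions, at most 16 selectable per case.
    """

    k: int = 5
    n_cases: int = 5
    n_actions: int = 22
    max_select: int = 16
    consensus_concentration: float = 1.0
    fixed_p: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValidationError("panel needs k >= 2 raters")
        if self.n_cases < 1 or self.n_actions < 1:
            raise ValidationError("n_cases and n_actions must be positive")
        if self.max_select <= 0:
            raise ValidationError("max_select must be positive")
        if self.consensus_concentration <= 0:
            raise ValidationError("consensus_concentration must be positive")
        if self.fixed_p is not None and not (0.0 <= self.fixed_p <= 1.0):
            raise ValidationError("fixed_p must lie in [0, 1]")


def generate_panel(model: PanelModel) -> SelectionMatrix:
    """Draw one synthetic panel; a pure function of the model (incl. seed)."""
    rng = np.random.default_rng(model.seed)
    raters = tuple(f"E{i + 1}" for i in range(model.k))
    cases = tuple(f"P{j + 1}" for j in range(model.n_cases))
    a = 1.0 / model.consensus_concentration
    selections: dict[tuple[str, str], frozenset[int]] = {}
    for case in cases:
        if model.fixed_p is not None:
            p = np.full(model.n_actions, model.fixed_p)
        else:
            p = rng.beta(a, a, size=model.n_actions)
        for rater in raters:
            picked = np.flatnonzero(rng.random(model.n_actions) < p)
            if len(picked) > model.max_select:
                # keep the max_select highest-consensus selections
                order = np.argsort(p[picked], kind="stable")[::-1]
                picked = picked[order[: model.max_select]]
            selections[(rater, case)] = frozenset(int(i) + 1 for i in picked)
    return SelectionMatrix(
        raters=raters,
        cases=cases,
        n_actions=model.n_actions,
        max_select=model.max_select,
        selections=selections,
    )


def _panel_agreement(matrix: SelectionMatrix) -> Optional[float]:
    """Mean r^selection over all ordered human pairs and cases."""
    vals = [
        v
        for series in matrix_correlations(matrix, algorithm_rater="__none__").values()
        for v in series
        if v is not None
    ]
    if not vals:
        return None
    return float(np.mean(vals))


def recover_agreement(
    model: PanelModel,
    replicates: int,
    concentrations: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Agreement statistics of replicate panels per consensus level.

    For each concentration level, ``replicates`` independent panels are
    generated (seeds spawned deterministically from ``model.seed``),
    the mean pairwise r\\ :sup:`selection` is computed per panel, and the
    reliability α = kR/(1+(k−1)R) is applied to the across-replicate
    mean R.  Returns a DataFrame with one row per level, sorted by
    concentration; ``mean_r_selection`` and ``alpha`` increase with the
    concentration.
    """
    if replicates < 2:
        raise ValidationError("recover_agreement needs replicates >= 2")
    if concentrations is None:
        concentrations = [model.consensus_concentration]
    rows = []
    for i, level in enumerate(sorted(concentrations)):
        child = np.random.SeedSequence(entropy=model.seed, spawn_key=(i,))
        seeds = child.generate_state(replicates) % (2**31)
        r_vals = []
        for s in seeds:
            m = replace(model, consensus_concentration=float(level), seed=int(s))
            r = _panel_agreement(generate_panel(m))
            if r is not None:
                r_vals.append(r)
        mean_r = float(np.mean(r_vals)) if r_vals else float("nan")
        alpha = (
            reliability_alpha(model.k, mean_r).alpha
            if r_vals and 0.0 <= mean_r <= 1.0
            else float("nan")
        )
        rows.append(
            {
                "concentration": float(level),
                "mean_r_selection": mean_r,
                "alpha": alpha,
                "n_replicates": len(r_vals),
            }
        )
    return pd.DataFrame(rows)
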