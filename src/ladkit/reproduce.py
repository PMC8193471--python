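"""Reproduction suite: recompute the published validation numbers.

Every check recomputes a quantity from the shipped reference fixtures
or the default ruleset and compares it with the published value at the
printing precision: summary rows (mean ±0.05, SD ±0.01, CI bounds
±0.1 — one printed decimal), reliability coefficients (±0.001),
scenario-space counts (exact).  Used by ``lad reproduce`` and the
acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fixtures
from .config import default_config
from .engine import enumerate_scenarios, recommend_actions
from .sampling import sample_cases, stratify
from .stats import per_expert_alphas, rank_evaluators, reliability_alpha, summarize


@dataclass(frozen=True)
class Check:
    name: str
    computed: float
    expected: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return abs(self.computed - self.expected) <= self.tolerance


def summary_checks() -> list[Check]:
    """Recompute mean/SD/CI for every published per-case score row."""
    out = []
    for name, row in fixtures.SCORE_ROWS.items():
        s = summarize(row["values"])
        out.append(Check(f"{name}.mean", s.mean, row["mean"], 0.05))
        out.append(Check(f"{name}.sd", s.sd, row["sd"], 0.01))
        out.append(Check(f"{name}.ci_low", s.ci_low, row["ci"][0], 0.1))
        out.append(Check(f"{name}.ci_high", s.ci_high, row["ci"][1], 0.1))
    return out


def reliability_checks() -> list[Check]:
    """Recompute per-expert and overall α and per-case mean correlations."""
    alphas, overall = per_expert_alphas(fixtures.PAIRWISE_CORRELATIONS, k=fixtures.K_EXPERTS)
    out = [
        Check(f"alpha.{e}", alphas[e].alpha, fixtures.PUBLISHED_ALPHAS[e], 0.001)
        for e in fixtures.EXPERTS
    ]
    out.append(Check("alpha.overall", overall, fixtures.PUBLISHED_OVERALL_ALPHA, 0.001))
    for i, case in enumerate(fixtures.CASES):
        mean_c = float(
            np.mean([vs[i] for vs in fixtures.PAIRWISE_CORRELATIONS.values()])
        )
        out.append(
            Check(
                f"mean_r.{case}", mean_c, fixtures.PER_CASE_MEAN_CORRELATIONS[case], 0.001
            )
        )
    return out


def engine_checks() -> list[Check]:
    """Scenario-space size, strata sizes and recommendation coverage."""
    cfg = default_config()
    scenarios = enumerate_scenarios(cfg.factorization)
    strata = stratify(scenarios)
    cap = cfg.meta.max_recommendation_actions
    n_valid = sum(
        1 for s in scenarios if len(recommend_actions(s, cfg).actions) <= cap
    )
    out = [Check("engine.n_scenarios", len(scenarios), 1152, 0)]
    out += [Check(f"engine.stratum.{st.name}", len(st), 384, 0) for st in strata]
    out.append(Check("engine.valid_recommendations", n_valid, len(scenarios), 0))
    sample = sample_cases(strata, per_stratum=2, seed=20190101)
    out.append(Check("sampling.n_cases", len(sample.cases), 6, 0))
    repeat = sample_cases(strata, per_stratum=2, seed=20190101)
    out.append(Check("sampling.reproducible", float(sample == repeat), 1.0, 0))
    return out


def ranking_check() -> Check:
    """The experts-vs-algorithm comparison is statistically indistinguishable."""
    rows = fixtures.SCORE_ROWS
    ranking = rank_evaluators(
        {
            "experts": (
                summarize(rows["ee_sensitivity_weighted"]["values"]),
                summarize(rows["ee_fpr"]["values"]),
            ),
            "LaD": (
                summarize(rows["elad_sensitivity_weighted"]["values"]),
                summarize(rows["elad_fpr"]["values"]),
            ),
        }
    )
    indist = float(len(ranking.indistinguishable) == 1)
    return Check("ranking.no_statistical_difference", indist, 1.0, 0)


def run_all() -> list[Check]:
    checks = summary_checks() + reliability_checks() + engine_checks()
    checks.append(ranking_check())
    return checks
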