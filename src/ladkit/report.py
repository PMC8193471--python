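"""Panel validation driver and report rendering.

``validate_panel`` runs the full agreement analysis on a selection
matrix (completeness filtering, consensus weights, per-case group
scores, summaries, reliability, CI-border ranking).  ``render_report``
turns the result into a machine-readable dict (JSON-safe) plus a
human-readable text table laid out as statistic × case with mean (SD)
and the 95% CI; percentages are printed with one decimal and
correlations with three, matching the reporting convention of the
original validation study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ValidationError
from .stats import (
    ALGORITHM_RATER,
    ActionWeights,
    AgreementSummary,
    RankingResult,
    SelectionMatrix,
    action_weights,
    filter_complete_cases,
    matrix_correlations,
    per_case_group_score,
    per_expert_alphas,
    rank_evaluators,
    summarize,
)

#: Row order of the per-case score table.
STATISTIC_ROWS = (
    "ee_sensitivity_unadjusted",
    "elad_sensitivity_unadjusted",
    "ee_sensitivity_weighted",
    "elad_sensitivity_weighted",
    "ee_fpr",
    "elad_fpr",
)

_ROW_TITLES = {
    "ee_sensitivity_unadjusted": "E-E pairwise sensitivity: unadjusted",
    "elad_sensitivity_unadjusted": "E-LaD pairwise sensitivity: unadjusted",
    "ee_sensitivity_weighted": "E-E pairwise sensitivity: weighted",
    "elad_sensitivity_weighted": "E-LaD pairwise sensitivity: weighted",
    "ee_fpr": "E-E pairwise FPR",
    "elad_fpr": "E-LaD pairwise FPR",
}


@dataclass(frozen=True)
class PanelValidation:
    """Everything the agreement analysis produces for one panel."""

    cases: tuple[str, ...]
    dropped_cases: tuple[str, ...]
    per_case: dict[str, tuple[float, ...]]  # statistic -> per-case percent
    summaries: dict[str, AgreementSummary]
    weights: ActionWeights
    per_expert_alpha: dict[str, float]
    overall_alpha: float
    mean_r: float
    ranking: Optional[RankingResult] = None
    has_algorithm: bool = True


def validate_panel(
    matrix: SelectionMatrix, algorithm_rater: str = ALGORITHM_RATER
) -> PanelValidation:
    """Run the complete agreement analysis on a selection matrix.

    Cases not answered by every human rater are dropped first.  Scores
    are reported in percent.  When the matrix contains the algorithm
    rater, E-LaD rows and the expert-vs-algorithm ranking are included.
    """
    matrix, dropped = filter_complete_cases(matrix, algorithm_rater)
    if not matrix.cases:
        raise ValidationError("no complete cases to analyze")
    has_alg = algorithm_rater in matrix.raters and all(
        matrix.answered(algorithm_rater, c) for c in matrix.cases
    )
    weights = action_weights(matrix, matrix.human_raters(algorithm_rater))

    def row(kind: str, statistic: str, weighted: bool) -> tuple[float, ...]:
        out = []
        for case in matrix.cases:
            gs = per_case_group_score(
                matrix,
                case,
                kind,
                algorithm_rater=algorithm_rater,
                weights=weights if weighted else None,
                statistic=statistic,
            )
            out.append(100.0 * gs.value if gs.value is not None else float("nan"))
        return tuple(out)

    per_case = {
        "ee_sensitivity_unadjusted": row("E-E", "sensitivity", False),
        "ee_sensitivity_weighted": row("E-E", "sensitivity", True),
        "ee_fpr": row("E-E", "fpr", False),
    }
    if has_alg:
        per_case["elad_sensitivity_unadjusted"] = row("E-LaD", "sensitivity", False)
        per_case["elad_sensitivity_weighted"] = row("E-LaD", "sensitivity", True)
        per_case["elad_fpr"] = row("E-LaD", "fpr", False)

    summaries = {
        name: summarize([v for v in vals if not np.isnan(v)])
        for name, vals in per_case.items()
        if sum(not np.isnan(v) for v in vals) >= 2
    }

    corr = matrix_correlations(matrix, algorithm_rater)
    alphas, overall = per_expert_alphas(
        {k: [v for v in vs if v is not None] for k, vs in corr.items()},
        k=len(matrix.human_raters(algorithm_rater)),
    )
    all_r = [v for vs in corr.values() for v in vs if v is not None]
    mean_r = float(np.mean(all_r)) if all_r else float("nan")

    ranking = None
    if has_alg and all(
        key in summaries
        for key in ("ee_sensitivity_weighted", "ee_fpr", "elad_sensitivity_weighted", "elad_fpr")
    ):
        ranking = rank_evaluators(
            {
                "experts": (summaries["ee_sensitivity_weighted"], summaries["ee_fpr"]),
                algorithm_rater: (summaries["elad_sensitivity_weighted"], summaries["elad_fpr"]),
            }
        )
    return PanelValidation(
        cases=matrix.cases,
        dropped_cases=dropped,
        per_case=per_case,
        summaries=summaries,
        weights=weights,
        per_expert_alpha={e: r.alpha for e, r in alphas.items()},
        overall_alpha=overall,
        mean_r=mean_r,
        ranking=ranking,
        has_algorithm=has_alg,
    )


# ---------------------------------------------------------------------------
# rendering


def _fmt(x: float, digits: int = 1) -> str:
    return "nan" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.{digits}f}"


def render_report(result: PanelValidation | None) -> tuple[dict, str]:
    """Render a validation result as (JSON-safe dict, text table).

    An empty result renders an empty report with only the schema
    header.  The dict mirrors every printed cell so the text table can
    be reconstructed from it.
    """
    if result is None or not result.per_case:
        payload = {"schema": "ladkit.validation/1", "rows": [], "reliability": None}
        return payload, "statistic | (no results)\n"
    rows = []
    for key in STATISTIC_ROWS:
        if key not in result.per_case:
            continue
        summ = result.summaries.get(key)
        rows.append(
            {
                "statistic": key,
                "title": _ROW_TITLES[key],
                "per_case": {c: round(v, 1) for c, v in zip(result.cases, result.per_case[key])},
                "mean": round(summ.mean, 1) if summ else None,
                "sd": round(summ.sd, 2) if summ else None,
                "ci95": [round(summ.ci_low, 1), round(summ.ci_high, 1)] if summ else None,
            }
        )
    payload = {
        "schema": "ladkit.validation/1",
        "cases": list(result.cases),
        "dropped_cases": list(result.dropped_cases),
        "rows": rows,
        "reliability": {
            "per_expert_alpha": {e: round(a, 3) for e, a in result.per_expert_alpha.items()},
            "overall_alpha": round(result.overall_alpha, 3),
            "mean_r_selection": round(result.mean_r, 3),
        },
        "ranking": None
        if result.ranking is None
        else {
            "order": list(result.ranking.order),
            "indistinguishable": [list(p) for p in result.ranking.indistinguishable],
        },
    }

    width = max(len(r["title"]) for r in rows) + 2
    header = (
        "statistic".ljust(width)
        + "".join(c.rjust(8) for c in result.cases)
        + "mean (SD)".rjust(16)
        + "95% CI".rjust(16)
    )
    lines = [header, "-" * len(header)]
    for r in rows:
        cells = "".join(_fmt(v).rjust(8) for v in r["per_case"].values())
        mean_sd = f"{_fmt(r['mean'])} ({_fmt(r['sd'], 2)})"
        ci = f"{_fmt(r['ci95'][0])} to {_fmt(r['ci95'][1])}"
        lines.append(r["title"].ljust(width) + cells + mean_sd.rjust(16) + ci.rjust(16))
    rel = payload["reliability"]
    lines.append("")
    lines.append(
        "mean r^selection "
        + _fmt(rel["mean_r_selection"], 3)
        + ", reliability alpha "
        + _fmt(rel["overall_alpha"], 3)
        + " (per expert: "
        + ", ".join(f"{e}={a:.3f}" for e, a in rel["per_expert_alpha"].items())
        + ")"
    )
    if payload["ranking"] is not None:
        lines.append(
            "CI-border ranking: "
            + " > ".join(payload["ranking"]["order"])
            + (
                "; statistically indistinguishable: "
                + "; ".join(" ~ ".join(p) for p in payload["ranking"]["indistinguishable"])
                if payload["ranking"]["indistinguishable"]
                else ""
            )
        )
    return payload, "\n".join(lines) + "\n"


def report_to_json(payload: dict) -> str:
    return json.dumps(payload, indent=2, sort_keys=False)
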