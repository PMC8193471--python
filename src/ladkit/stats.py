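"""Agreement statistics for expert-panel validation.

With no gold standard for intrapartum decisions, an algorithm is
validated against a panel of k human experts acting as a silver
standard.  Each rater (experts E1..Ek, optionally the algorithm)
selects a subset of a fixed action catalog for each patient case.
This module implements the agreement framework used for that design:

* **consensus weights** — an action's weight in a case is the fraction
  of *human* raters who selected it (1.0 if all five of five, 0.6 if
  three, 0 if none);
* **directed pairwise sensitivity** — the fraction of a reference
  rater's selections that the test rater also selected, optionally
  weighted by consensus;
* **pairwise false-positive rate** — the fraction of actions the
  reference left unselected that the test rater selected;
* **selection correlation** r\\ :sup:`selection` — the geometric mean of
  the two directed sensitivities between two raters (an extension of
  Pearson r suited to non-independent action selections, where kappa
  or pi would mislead);
* **reliability coefficient** α = kR/(1 + (k−1)R), the Spearman–Brown /
  Cronbach-type coefficient for k raters with mean pairwise
  correlation R;
* small-sample summaries (mean, n−1 SD, t-based 95% CI) and the
  CI-border ranking rule (rank by sensitivity CI lower bound, then FPR
  CI upper bound; overlap on both means statistically
  indistinguishable).

Scores with an undefined denominator (e.g. an empty reference
selection) are returned as ``None`` and excluded from averages with an
explicit exclusion count — never imputed as zero, which would conflate
disagreement with missingness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_N_ACTIONS = 22
DEFAULT_MAX_SELECT = 16
ALGORITHM_RATER = "LaD"


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class SelectionMatrix:
    """Binary rater × case × action selections.

    ``selections`` holds one frozen action-id set per *answered*
    (rater, case) block; a missing key means the rater did not answer
    that case (distinct from answering with no selections).
    """

    raters: tuple[str, ...]
    cases: tuple[str, ...]
    n_actions: int = DEFAULT_N_ACTIONS
    max_select: int = DEFAULT_MAX_SELECT
    selections: Mapping[tuple[str, str], frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.raters)) != len(self.raters):
            raise ValidationError("duplicate rater ids")
        if len(set(self.cases)) != len(self.cases):
            raise ValidationError("duplicate case labels")
        for (rater, case), sel in self.selections.items():
            if rater not in self.raters or case not in self.cases:
                raise ValidationError(f"selection block for unknown ({rater}, {case})")
            if len(sel) > self.max_select:
                raise ValidationError(
                    f"rater {rater}, case {case}: {len(sel)} selections exceed "
                    f"the limit of {self.max_select}"
                )
            bad = [a for a in sel if not (1 <= a <= self.n_actions)]
            if bad:
                raise ValidationError(
                    f"rater {rater}, case {case}: action ids {sorted(bad)} outside "
                    f"1..{self.n_actions}"
                )

    def answered(self, rater: str, case: str) -> bool:
        return (rater, case) in self.selections

    def selected(self, rater: str, case: str) -> frozenset[int]:
        try:
            return self.selections[(rater, case)]
        except KeyError:
            raise ValidationError(f"rater {rater} did not answer case {case}") from None

    def human_raters(self, algorithm_rater: str = ALGORITHM_RATER) -> tuple[str, ...]:
        return tuple(r for r in self.raters if r != algorithm_rater)


@dataclass(frozen=True)
class ActionWeights:
    """Per-case, per-action consensus weights from the human raters.

    weight(case, a) = (number of human raters selecting a in case) / k.
    The algorithm's own selections never contribute, so an action only
    the algorithm picked carries weight 0.
    """

    k: int
    weights: Mapping[tuple[str, int], float]

    def weight(self, case: str, action: int) -> float:
        return self.weights.get((case, action), 0.0)

    def total(self, case: str, actions: Iterable[int]) -> float:
        """Weighted selection total: sum of weights over an action set."""
        return sum(self.weight(case, a) for a in actions)


@dataclass(frozen=True)
class PairScore:
    """One directed pair comparison for one case."""

    reference: str
    test: str
    case: str
    sensitivity: Optional[float]
    fpr: Optional[float]
    weighted: bool = False


@dataclass(frozen=True)
class GroupScore:
    """A per-case group average with its exclusion bookkeeping."""

    value: Optional[float]
    n_pairs: int
    n_excluded: int


@dataclass(frozen=True)
class AgreementSummary:
    """Mean, sample SD and t-based 95% CI of per-case statistics."""

    values: tuple[float, ...]
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class ReliabilityResult:
    k: int
    R: float
    alpha: float


@dataclass(frozen=True)
class RankingResult:
    """CI-border ranking with the overlap (indistinguishability) report."""

    order: tuple[str, ...]
    indistinguishable: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class DifferenceResult:
    """Welch unpaired-t comparison of two small samples of per-case scores."""

    diff: float
    ci_low: float
    ci_high: float
    p_value: float
    df: float


# ---------------------------------------------------------------------------
# weights


def action_weights(
    matrix: SelectionMatrix, human_raters: Sequence[str] | None = None
) -> ActionWeights:
    """Consensus weights from the human raters' selections.

    Only cases a rater answered count toward that rater's
    contribution; the divisor is always the panel size k.
    """
    if human_raters is None:
        human_raters = matrix.human_raters()
    human_raters = tuple(human_raters)
    if not human_raters:
        raise ValidationError("human rater set is empty")
    unknown = set(human_raters) - set(matrix.raters)
    if unknown:
        raise ValidationError(f"unknown human raters {sorted(unknown)}")
    k = len(human_raters)
    if k < 2:
        raise ValidationError("need at least 2 human raters for consensus weights")
    weights: dict[tuple[str, int], float] = {}
    for case in matrix.cases:
        for a in range(1, matrix.n_actions + 1):
            count = sum(
                1
                for r in human_raters
                if matrix.answered(r, case) and a in matrix.selected(r, case)
            )
            if count:
                weights[(case, a)] = count / k
    return ActionWeights(k=k, weights=weights)


# ---------------------------------------------------------------------------
# pairwise scores


def pairwise_sensitivity(
    matrix: SelectionMatrix,
    reference: str,
    test: str,
    case: str,
    weights: ActionWeights | None = None,
) -> Optional[float]:
    """Directed sensitivity of ``test`` with ``reference`` as truth.

    Unweighted: \\|test ∩ reference\\| / \\|reference\\|.  Weighted: the
    consensus-weight mass of the overlap divided by the mass of the
    reference set.  Returns ``None`` (flagged undefined) when the
    denominator is zero.
    """
    ref = matrix.selected(reference, case)
    tst = matrix.selected(test, case)
    if weights is None:
        if not ref:
            return None
        return len(tst & ref) / len(ref)
    denom = weights.total(case, ref)
    if denom == 0:
        return None
    return weights.total(case, tst & ref) / denom


def pairwise_fpr(
    matrix: SelectionMatrix, reference: str, test: str, case: str
) -> Optional[float]:
    """False-positive rate of ``test`` against ``reference``.

    \\|test \\ reference\\| / (n_actions − \\|reference\\|): of the actions
    the reference deemed unnecessary, the fraction the test rater
    selected.  Undefined (``None``) when the reference selected every
    action.
    """
    ref = matrix.selected(reference, case)
    tst = matrix.selected(test, case)
    denom = matrix.n_actions - len(ref)
    if denom == 0:
        return None
    return len(tst - ref) / denom


def r_selection(
    matrix: SelectionMatrix, rater_a: str, rater_b: str, case: str
) -> Optional[float]:
    """Selection correlation: √(sens(a→b) × sens(b→a)).

    The geometric mean of the two directed sensitivities; symmetric in
    its arguments.  Undefined when either direction is undefined.
    """
    s_ab = pairwise_sensitivity(matrix, rater_a, rater_b, case)
    s_ba = pairwise_sensitivity(matrix, rater_b, rater_a, case)
    if s_ab is None or s_ba is None:
        return None
    return math.sqrt(s_ab * s_ba)


def per_case_group_score(
    matrix: SelectionMatrix,
    case: str,
    kind: str,
    algorithm_rater: str = ALGORITHM_RATER,
    weights: ActionWeights | None = None,
    statistic: str = "sensitivity",
) -> GroupScore:
    """Average a pairwise statistic over a rater grouping for one case.

    ``kind="E-E"`` averages over all ordered human pairs (reference ≠
    test); ``kind="E-LaD"`` averages over human raters as reference
    with the algorithm as test.  ``statistic`` is ``"sensitivity"`` or
    ``"fpr"`` (FPR is always unweighted).  Undefined pair scores are
    excluded and counted.
    """
    if kind not in ("E-E", "E-LaD"):
        raise ValidationError(f"kind must be 'E-E' or 'E-LaD', got {kind!r}")
    if statistic not in ("sensitivity", "fpr"):
        raise ValidationError(f"unknown statistic {statistic!r}")
    humans = [
        r
        for r in matrix.human_raters(algorithm_rater)
        if matrix.answered(r, case)
    ]
    if kind == "E-E":
        if len(humans) < 2:
            raise ValidationError("E-E scores need at least 2 human raters")
        pairs = [(a, b) for a in humans for b in humans if a != b]
    else:
        if not matrix.answered(algorithm_rater, case):
            raise ValidationError(
                f"algorithm rater {algorithm_rater!r} has no block for case {case}"
            )
        pairs = [(r, algorithm_rater) for r in humans]
    scores = []
    excluded = 0
    for ref, tst in pairs:
        if statistic == "sensitivity":
            s = pairwise_sensitivity(matrix, ref, tst, case, weights=weights)
        else:
            s = pairwise_fpr(matrix, ref, tst, case)
        if s is None:
            excluded += 1
        else:
            scores.append(s)
    if not scores:
        return GroupScore(value=None, n_pairs=len(pairs), n_excluded=excluded)
    return GroupScore(
        value=float(np.mean(scores)), n_pairs=len(pairs), n_excluded=excluded
    )


def pairwise_table(
    matrix: SelectionMatrix,
    weights: ActionWeights | None = None,
    algorithm_rater: str = ALGORITHM_RATER,
) -> list[PairScore]:
    """All directed pair scores for every case (reporting helper)."""
    out = []
    for case in matrix.cases:
        present = [r for r in matrix.raters if matrix.answered(r, case)]
        for ref in present:
            for tst in present:
                if ref == tst:
                    continue
                out.append(
                    PairScore(
                        reference=ref,
                        test=tst,
                        case=case,
                        sensitivity=pairwise_sensitivity(
                            matrix, ref, tst, case, weights=weights
                        ),
                        fpr=pairwise_fpr(matrix, ref, tst, case),
                        weighted=weights is not None,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# reliability


def reliability_alpha(k: int, R: float) -> ReliabilityResult:
    """Spearman–Brown / Cronbach-type reliability: α = kR/(1 + (k−1)R)."""
    if k < 2:
        raise ValidationError("reliability needs k >= 2 raters")
    if not (-1.0 / (k - 1) <= R <= 1.0):
        raise ValidationError(f"mean correlation R={R} outside [-1/(k-1), 1]")
    alpha = k * R / (1.0 + (k - 1) * R)
    return ReliabilityResult(k=k, R=R, alpha=alpha)


def per_expert_alphas(
    correlations: Mapping[tuple[str, str], Sequence[float]], k: int | None = None
) -> tuple[dict[str, ReliabilityResult], float]:
    """Per-reference-expert α values and their mean.

    ``correlations`` maps an ordered ``(reference, partner)`` pair to
    its per-case r\\ :sup:`selection` values.  Each expert's R is the
    mean of all values in that expert's reference block (every partner
    × every case); the overall reliability is the mean of the
    per-expert α values.
    """
    refs = sorted({ref for ref, _ in correlations})
    if k is None:
        k = len(refs)
    out: dict[str, ReliabilityResult] = {}
    for ref in refs:
        vals = [
            v
            for (r, _), vs in correlations.items()
            if r == ref
            for v in vs
            if v is not None
        ]
        if not vals:
            raise ValidationError(f"no correlations with reference {ref!r}")
        out[ref] = reliability_alpha(k, float(np.mean(vals)))
    overall = float(np.mean([res.alpha for res in out.values()]))
    return out, overall


def matrix_correlations(
    matrix: SelectionMatrix, algorithm_rater: str = ALGORITHM_RATER
) -> dict[tuple[str, str], list[Optional[float]]]:
    """r^selection for every ordered human pair, per case."""
    humans = matrix.human_raters(algorithm_rater)
    out: dict[tuple[str, str], list[Optional[float]]] = {}
    for a in humans:
        for b in humans:
            if a == b:
                continue
            out[(a, b)] = [
                r_selection(matrix, a, b, case)
                if matrix.answered(a, case) and matrix.answered(b, case)
                else None
                for case in matrix.cases
            ]
    return out


# ---------------------------------------------------------------------------
# summaries, differences, ranking


def summarize(values: Sequence[float], confidence: float = 0.95) -> AgreementSummary:
    """Mean, sample SD (n−1) and t-based CI of per-case statistics.

    The CI half-width is t(1−(1−confidence)/2, n−1) · sd/√n, the usual
    small-sample convention for a handful of per-case scores.
    """
    vals = [float(v) for v in values]
    n = len(vals)
    if n < 2:
        raise ValidationError("summarize needs at least 2 values")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    tcrit = float(sps.t.ppf(0.5 + confidence / 2.0, n - 1))
    hw = tcrit * sd / math.sqrt(n)
    return AgreementSummary(
        values=tuple(vals), mean=mean, sd=sd, ci_low=mean - hw, ci_high=mean + hw, n=n
    )


def difference_of_means(
    a: Sequence[float], b: Sequence[float], confidence: float = 0.95
) -> DifferenceResult:
    """Welch unpaired-t comparison of two score samples (mean(a) − mean(b))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("difference_of_means needs >= 2 values per sample")
    res = sps.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    tcrit = float(sps.t.ppf(0.5 + confidence / 2.0, df))
    diff = float(a.mean() - b.mean())
    hw = tcrit * math.sqrt(va + vb)
    return DifferenceResult(
        diff=diff,
        ci_low=diff - hw,
        ci_high=diff + hw,
        p_value=float(res.pvalue),
        df=float(df),
    )


def _overlap(lo1: float, hi1: float, lo2: float, hi2: float) -> bool:
    return max(lo1, lo2) <= min(hi1, hi2)


def rank_evaluators(
    summaries: Mapping[str, tuple[AgreementSummary, AgreementSummary]],
) -> RankingResult:
    """Rank evaluators by CI borders.

    Each evaluator supplies a (sensitivity, FPR) summary pair.  Primary
    order: sensitivity CI lower bound, descending.  Secondary: FPR CI
    upper bound, ascending.  Pairs whose intervals overlap on *both*
    criteria are reported as statistically indistinguishable.
    """
    names = list(summaries)
    order = sorted(
        names,
        key=lambda n: (-summaries[n][0].ci_low, summaries[n][1].ci_high, n),
    )
    indist = []
    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            sa, fa = summaries[a]
            sb, fb = summaries[b]
            if _overlap(sa.ci_low, sa.ci_high, sb.ci_low, sb.ci_high) and _overlap(
                fa.ci_low, fa.ci_high, fb.ci_low, fb.ci_high
            ):
                indist.append((a, b))
    return RankingResult(order=tuple(order), indistinguishable=tuple(indist))


# ---------------------------------------------------------------------------
# completeness filtering


def filter_complete_cases(
    matrix: SelectionMatrix, algorithm_rater: str = ALGORITHM_RATER
) -> tuple[SelectionMatrix, tuple[str, ...]]:
    """Keep only cases answered by every human rater.

    Returns the filtered matrix and the labels of the dropped cases.
    The algorithm rater's blocks never affect completeness.
    """
    humans = matrix.human_raters(algorithm_rater)
    complete = tuple(
        c for c in matrix.cases if all(matrix.answered(r, c) for r in humans)
    )
    dropped = tuple(c for c in matrix.cases if c not in complete)
    if dropped:
        logger.warning("dropping incomplete cases: %s", ", ".join(dropped))
    if not complete:
        logger.warning("no case was answered by every human rater")
    selections = {
        (r, c): sel for (r, c), sel in matrix.selections.items() if c in complete
    }
    return (
        SelectionMatrix(
            raters=matrix.raters,
            cases=complete,
            n_actions=matrix.n_actions,
            max_select=matrix.max_select,
            selections=selections,
        ),
        dropped,
    )
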