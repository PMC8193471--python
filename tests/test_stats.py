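import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ladkit import fixtures
from ladkit.errors import ValidationError
from ladkit.stats import (
    ActionWeights,
    SelectionMatrix,
    action_weights,
    difference_of_means,
    filter_complete_cases,
    pairwise_fpr,
    pairwise_sensitivity,
    per_case_group_score,
    per_expert_alphas,
    r_selection,
    rank_evaluators,
    reliability_alpha,
    summarize,
)
from tests.conftest import HAND_SELECTIONS


def small_matrix(case_sets, n_actions=22, raters=None, case="P1"):
    """Matrix with one case from a {rater: set} mapping (cap relaxed)."""
    raters = tuple(raters or case_sets)
    return SelectionMatrix(
        raters=raters,
        cases=(case,),
        n_actions=n_actions,
        max_select=n_actions,
        selections={(r, case): frozenset(case_sets[r]) for r in raters},
    )


# ---------------------------------------------------------------------------
# consensus weights


def test_action_weights_are_selection_fractions(hand_matrix):
    w = action_weights(hand_matrix)
    # P1: action 1 picked by E1,E2,E3,E5 -> 4/5; action 6 only by E4 -> 1/5
    assert w.weight("P1", 1) == pytest.approx(0.8)
    assert w.weight("P1", 6) == pytest.approx(0.2)
    assert w.weight("P1", 22) == 0.0  # selected by none
    # three of five -> 0.6
    assert w.weight("P1", 2) == pytest.approx(0.8)
    assert w.weight("P2", 2) == pytest.approx(0.6)
    # the algorithm's selections never contribute: action 8 is LaD-only
    assert w.weight("P1", 8) == 0.0


def test_weighted_total_bounds(hand_matrix):
    """Each human rater's weighted total lies in [raw/k, raw] because
    every own selection contributes at least 1/k."""
    w = action_weights(hand_matrix)
    for case, by_rater in HAND_SELECTIONS.items():
        for rater, sel in by_rater.items():
            if rater == "LaD":
                continue
            total = w.total(case, sel)
            assert len(sel) / 5 - 1e-12 <= total <= len(sel) + 1e-12


def test_published_adjusted_totals_respect_weight_bounds():
    """The published raw/weighted selection totals obey the same
    algebraic bounds (e.g. E1 on P1: 7.2 within [9/5, 9])."""
    for rater, by_case in fixtures.SELECTION_COUNTS.items():
        if rater == "LaD":
            continue
        for case, (raw, adjusted) in by_case.items():
            assert raw / 5 <= adjusted <= raw


def test_action_weights_validates_raters(hand_matrix):
    with pytest.raises(ValidationError):
        action_weights(hand_matrix, human_raters=[])
    with pytest.raises(ValidationError):
        action_weights(hand_matrix, human_raters=["E1", "E9"])


# ---------------------------------------------------------------------------
# pairwise scores


def test_pairwise_sensitivity_examples():
    m = small_matrix({"R": {1, 2, 3, 4}, "T": {1, 2, 5}})
    assert pairwise_sensitivity(m, "R", "T", "P1") == pytest.approx(0.5)
    assert pairwise_sensitivity(m, "R", "R", "P1") == 1.0
    m2 = small_matrix({"R": {1}, "T": set()})
    assert pairwise_sensitivity(m2, "R", "T", "P1") == 0.0
    # empty reference is flagged undefined, not zero
    assert pairwise_sensitivity(m2, "T", "R", "P1") is None


def test_pairwise_fpr_examples():
    m = small_matrix({"R": {1, 2, 3, 4}, "T": {1, 2, 3, 4, 5}})
    assert pairwise_fpr(m, "R", "T", "P1") == pytest.approx(1 / 18)
    m2 = small_matrix({"R": {1, 2, 3, 4}, "T": {1, 2}})
    assert pairwise_fpr(m2, "R", "T", "P1") == 0.0
    comp = set(range(5, 23))
    m3 = small_matrix({"R": {1, 2, 3, 4}, "T": comp}, n_actions=22)
    assert pairwise_fpr(m3, "R", "T", "P1") == 1.0
    # reference selected everything -> undefined
    m4 = small_matrix({"R": set(range(1, 5)), "T": {1}}, n_actions=4)
    assert pairwise_fpr(m4, "R", "T", "P1") is None


def test_r_selection_examples():
    m = small_matrix({"A": {1, 2, 3, 4}, "B": {1, 2}})
    assert r_selection(m, "A", "B", "P1") == pytest.approx(math.sqrt(0.5))
    m2 = small_matrix({"A": {1, 2}, "B": {1, 2}})
    assert r_selection(m2, "A", "B", "P1") == 1.0
    m3 = small_matrix({"A": {1, 2}, "B": {3, 4}})
    assert r_selection(m3, "A", "B", "P1") == 0.0


def random_matrix(rng, k=4, n_actions=10):
    sets = {
        f"E{i + 1}": set(
            int(a) + 1
            for a in np.flatnonzero(rng.random(n_actions) < rng.uniform(0.1, 0.9))
        )
        for i in range(k)
    }
    return small_matrix(sets, n_actions=n_actions)


def test_r_selection_symmetry_random():
    rng = np.random.default_rng(123)
    for _ in range(200):
        m = random_matrix(rng)
        raters = m.raters
        for a in raters:
            for b in raters:
                if a >= b:
                    continue
                r_ab = r_selection(m, a, b, "P1")
                r_ba = r_selection(m, b, a, "P1")
                assert (r_ab is None) == (r_ba is None)
                if r_ab is not None:
                    assert r_ab == pytest.approx(r_ba, abs=1e-12)
                    assert 0.0 <= r_ab <= 1.0


@given(
    ref=st.sets(st.integers(1, 12), min_size=1, max_size=10),
    test=st.sets(st.integers(1, 12), max_size=10),
    extra=st.integers(1, 12),
)
def test_monotonicity_properties(ref, test, extra):
    """Adding a matching action never decreases sensitivity; adding a
    non-reference action never decreases FPR."""
    m = small_matrix({"R": ref, "T": test}, n_actions=12)
    s0 = pairwise_sensitivity(m, "R", "T", "P1")
    f0 = pairwise_fpr(m, "R", "T", "P1")
    m2 = small_matrix({"R": ref, "T": test | {extra}}, n_actions=12)
    s1 = pairwise_sensitivity(m2, "R", "T", "P1")
    f1 = pairwise_fpr(m2, "R", "T", "P1")
    if extra in ref:
        assert s1 >= s0
        assert f1 == f0
    else:
        assert s1 == s0
        if f0 is not None:
            assert f1 >= f0


def test_weighted_equals_unweighted_under_equal_weights():
    """With all actions equally weighted the weighted sensitivity
    collapses to the plain count ratio."""
    rng = np.random.default_rng(5)
    for _ in range(50):
        m = random_matrix(rng, k=3, n_actions=8)
        w = ActionWeights(k=3, weights={("P1", a): 0.4 for a in range(1, 9)})
        for ref in m.raters:
            for tst in m.raters:
                if ref == tst:
                    continue
                plain = pairwise_sensitivity(m, ref, tst, "P1")
                weighted = pairwise_sensitivity(m, ref, tst, "P1", weights=w)
                if plain is None:
                    assert weighted is None
                else:
                    assert weighted == pytest.approx(plain, abs=1e-12)


# ---------------------------------------------------------------------------
# group scores


def brute_force_group(case_sets, kind, n_actions=22, weights=None):
    """Independent oracle: direct loops over explicit selection dicts."""
    humans = [r for r in case_sets if r != "LaD"]
    if kind == "E-E":
        pairs = [(a, b) for a in humans for b in humans if a != b]
    else:
        pairs = [(r, "LaD") for r in humans]
    vals = []
    for ref, tst in pairs:
        rset, tset = case_sets[ref], case_sets[tst]
        if weights is None:
            if rset:
                vals.append(len(rset & tset) / len(rset))
        else:
            denom = sum(weights.get(a, 0.0) for a in rset)
            if denom:
                vals.append(sum(weights.get(a, 0.0) for a in rset & tset) / denom)
    return sum(vals) / len(vals)


@pytest.mark.parametrize("case", ["P1", "P2"])
@pytest.mark.parametrize("kind", ["E-E", "E-LaD"])
def test_group_scores_match_brute_force(hand_matrix, case, kind):
    sets = HAND_SELECTIONS[case]
    gs = per_case_group_score(hand_matrix, case, kind)
    assert gs.value == pytest.approx(brute_force_group(sets, kind))
    assert gs.n_excluded == 0
    # weighted variant against the same oracle
    w = action_weights(hand_matrix)
    wdict = {a: w.weight(case, a) for a in range(1, 23)}
    gw = per_case_group_score(hand_matrix, case, kind, weights=w)
    assert gw.value == pytest.approx(brute_force_group(sets, kind, weights=wdict))


def test_identical_raters_agree_perfectly():
    m = small_matrix({"E1": {1, 2, 3}, "E2": {1, 2, 3}})
    assert per_case_group_score(m, "P1", "E-E").value == 1.0


def test_algorithm_matching_each_reference_scores_one():
    m = small_matrix({"E1": {1, 2}, "E2": {1, 2}, "LaD": {1, 2}})
    assert per_case_group_score(m, "P1", "E-LaD").value == 1.0


def test_undefined_pairs_are_excluded_not_imputed():
    m = small_matrix({"E1": set(), "E2": {1, 2}, "E3": {1}})
    gs = per_case_group_score(m, "P1", "E-E")
    # pairs with E1 as reference are undefined (empty reference)
    assert gs.n_excluded == 2
    assert gs.n_pairs == 6
    # the four defined ordered pairs: E2->E1 0, E2->E3 1/2, E3->E1 0, E3->E2 1
    assert gs.value == pytest.approx(np.mean([0.0, 1 / 2, 0.0, 1.0]))
    m_all_empty = small_matrix({"E1": set(), "E2": set()})
    assert per_case_group_score(m_all_empty, "P1", "E-E").value is None


# ---------------------------------------------------------------------------
# reliability


def test_reliability_alpha_formula():
    assert reliability_alpha(5, 0.0).alpha == 0.0
    assert reliability_alpha(5, 1.0).alpha == 1.0
    assert reliability_alpha(5, 0.55275).alpha == pytest.approx(0.861, abs=5e-4)
    # alpha increases with R at fixed k
    alphas = [reliability_alpha(5, r).alpha for r in np.linspace(0.05, 0.95, 10)]
    assert all(a < b for a, b in zip(alphas, alphas[1:]))
    with pytest.raises(ValidationError):
        reliability_alpha(1, 0.5)
    with pytest.raises(ValidationError):
        reliability_alpha(5, 1.2)


def test_per_expert_alphas_from_published_correlations():
    alphas, overall = per_expert_alphas(fixtures.PAIRWISE_CORRELATIONS, k=5)
    assert alphas["E4"].R == pytest.approx(0.55275)
    for e, printed in fixtures.PUBLISHED_ALPHAS.items():
        assert alphas[e].alpha == pytest.approx(printed, abs=1e-3)
    assert overall == pytest.approx(0.910, abs=1e-3)


# ---------------------------------------------------------------------------
# summaries and ranking


def test_summarize_recovers_published_convention():
    """The n-1 SD and t-based CI reproduce a published score row."""
    s = summarize([65.9, 56.5, 55.0, 45.6, 62.8])
    assert s.mean == pytest.approx(57.2, abs=0.05)
    assert s.sd == pytest.approx(7.86, abs=0.01)
    assert s.ci_low == pytest.approx(47.4, abs=0.1)
    assert s.ci_high == pytest.approx(67.0, abs=0.1)
    s2 = summarize([30.2, 19.7, 43.0, 20.5, 18.3])
    assert (s2.mean, s2.sd) == (pytest.approx(26.3, abs=0.05), pytest.approx(10.43, abs=0.01))
    assert (s2.ci_low, s2.ci_high) == (pytest.approx(13.3, abs=0.1), pytest.approx(39.3, abs=0.1))


def test_summarize_degenerate_and_invalid():
    s = summarize([4.0, 4.0, 4.0])
    assert (s.mean, s.sd, s.ci_low, s.ci_high) == (4.0, 0.0, 4.0, 4.0)
    with pytest.raises(ValidationError):
        summarize([1.0])


def test_difference_of_means_welch():
    d = difference_of_means([10.0, 12.0, 11.0], [10.0, 12.0, 11.0])
    assert d.diff == 0.0
    assert d.ci_low < 0 < d.ci_high
    d2 = difference_of_means([20.0, 21.0, 19.0], [10.0, 11.0, 9.0])
    assert d2.diff == pytest.approx(10.0)
    assert d2.p_value < 0.01


def test_rank_evaluators_dominance_and_ties():
    a = summarize([60.0, 70.0, 80.0])
    a_fpr = summarize([10.0, 15.0, 20.0])
    b = summarize([30.0, 50.0, 70.0])
    b_fpr = summarize([20.0, 25.0, 30.0])
    ranking = rank_evaluators({"A": (a, a_fpr), "B": (b, b_fpr)})
    assert ranking.order == ("A", "B")
    tie = rank_evaluators({"A": (a, a_fpr), "B": (a, a_fpr)})
    assert ("A", "B") in tie.indistinguishable


def test_rank_experts_vs_algorithm_published_summaries():
    """The published weighted-sensitivity and FPR intervals overlap on
    both criteria: experts and algorithm are indistinguishable."""
    ee = fixtures.SCORE_ROWS["ee_sensitivity_weighted"]["values"]
    lad = fixtures.SCORE_ROWS["elad_sensitivity_weighted"]["values"]
    ee_fpr = fixtures.SCORE_ROWS["ee_fpr"]["values"]
    lad_fpr = fixtures.SCORE_ROWS["elad_fpr"]["values"]
    ranking = rank_evaluators(
        {
            "experts": (summarize(ee), summarize(ee_fpr)),
            "LaD": (summarize(lad), summarize(lad_fpr)),
        }
    )
    assert set(ranking.indistinguishable) == {("experts", "LaD")}


# ---------------------------------------------------------------------------
# completeness filtering


def test_filter_complete_cases(hand_matrix):
    selections = dict(hand_matrix.selections)
    # sixth case answered by two experts only
    selections[("E1", "P6")] = frozenset({1})
    selections[("E2", "P6")] = frozenset({1, 2})
    m = SelectionMatrix(
        raters=hand_matrix.raters,
        cases=("P1", "P2", "P6"),
        selections=selections,
    )
    filtered, dropped = filter_complete_cases(m)
    assert filtered.cases == ("P1", "P2")
    assert dropped == ("P6",)
    # idempotent on complete matrices
    again, dropped2 = filter_complete_cases(filtered)
    assert again.cases == filtered.cases and dropped2 == ()


def test_filter_no_complete_cases(caplog):
    m = SelectionMatrix(
        raters=("E1", "E2"),
        cases=("P1",),
        selections={("E1", "P1"): frozenset({1})},
    )
    with caplog.at_level("WARNING"):
        filtered, dropped = filter_complete_cases(m)
    assert filtered.cases == () and dropped == ("P1",)


def test_selection_matrix_enforces_cap():
    with pytest.raises(ValidationError, match="exceed"):
        SelectionMatrix(
            raters=("E1",),
            cases=("P1",),
            selections={("E1", "P1"): frozenset(range(1, 18))},
        )
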