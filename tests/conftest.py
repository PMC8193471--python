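import pytest
from hypothesis import settings

from ladkit.config import default_config
from ladkit.engine import enumerate_scenarios
from ladkit.stats import SelectionMatrix

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def scenarios(cfg):
    return enumerate_scenarios(cfg.factorization)


#: Hand-written 5-expert + algorithm panel over two cases; small enough
#: that every statistic can be enumerated by hand or by a brute-force
#: loop in the tests.
HAND_SELECTIONS = {
    "P1": {
        "E1": {1, 2, 3, 4},
        "E2": {1, 2, 5},
        "E3": {1, 2, 3},
        "E4": {2, 3, 4, 6},
        "E5": {1, 3, 5, 7},
        "LaD": {1, 2, 3, 8},
    },
    "P2": {
        "E1": {1, 2},
        "E2": {1, 2},
        "E3": {1, 2, 3},
        "E4": {4},
        "E5": {1, 5},
        "LaD": {1, 2},
    },
}


@pytest.fixture()
def hand_matrix():
    selections = {
        (rater, case): frozenset(sel)
        for case, by_rater in HAND_SELECTIONS.items()
        for rater, sel in by_rater.items()
    }
    return SelectionMatrix(
        raters=("E1", "E2", "E3", "E4", "E5", "LaD"),
        cases=("P1", "P2"),
        n_actions=22,
        max_select=16,
        selections=selections,
    )
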