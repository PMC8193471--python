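"""Reference values from the original five-expert validation study.

The algorithm was validated by five childbirth experts (E1..E5) who
each selected up to 16 of 22 candidate actions for five stratified
patient case scenarios (P1..P5; a sixth case was answered by only two
experts and dropped).  These constants hold the published per-case
agreement scores, selection totals and pairwise selection
correlations, exactly as printed; they are the inputs for the
reproduction suite (``lad reproduce`` and the acceptance script).

A checksum over the canonical JSON rendering guards against accidental
edits.  Note that a handful of printed correlation pairs differ in the
third decimal between their two directions (e.g. E1–E4 vs E4–E1 on
P3); the values are kept verbatim, asymmetries included — the
symmetry of r^selection is a property of the computed statistic, not
of the rounded published table.
"""

from __future__ import annotations

import hashlib
import json

CASES = ("P1", "P2", "P3", "P4", "P5")
EXPERTS = ("E1", "E2", "E3", "E4", "E5")
N_ACTIONS = 22
MAX_SELECT = 16
K_EXPERTS = 5

#: Number of times each expert selected actions across the 5 cases (max 80).
EXPERT_SELECTION_TOTALS = {"E1": 36, "E2": 34, "E3": 44, "E4": 35, "E5": 46}

#: Raw and consensus-weighted selection totals per evaluator and case.
SELECTION_COUNTS = {
    # evaluator: {case: (raw, weighted)}
    "E1": {"P1": (9, 7.2), "P2": (5, 3.4), "P3": (5, 4.0), "P4": (6, 3.4), "P5": (11, 8.0)},
    "E2": {"P1": (8, 6.8), "P2": (5, 3.4), "P3": (8, 4.8), "P4": (5, 3.6), "P5": (8, 6.0)},
    "E3": {"P1": (12, 7.4), "P2": (4, 2.8), "P3": (6, 3.4), "P4": (9, 5.2), "P5": (13, 9.4)},
    "E4": {"P1": (11, 7.8), "P2": (5, 2.6), "P3": (7, 3.6), "P4": (4, 1.4), "P5": (8, 5.0)},
    "E5": {"P1": (13, 8.8), "P2": (5, 3.4), "P3": (5, 3.6), "P4": (9, 4.6), "P5": (14, 9.6)},
    "LaD": {"P1": (8, 4.6), "P2": (7, 3.4), "P3": (12, 5.4), "P4": (7, 3.8), "P5": (8, 5.6)},
}

#: Published per-case score rows: values (percent, P1..P5), printed
#: mean, SD and 95% CI bounds.
SCORE_ROWS = {
    "ee_sensitivity_unadjusted": {
        "values": (65.9, 56.5, 55.0, 45.6, 62.8),
        "mean": 57.2, "sd": 7.86, "ci": (47.4, 67.0),
    },
    "elad_sensitivity_unadjusted": {
        "values": (44.4, 74.0, 85.6, 58.7, 50.3),
        "mean": 62.6, "sd": 17.01, "ci": (41.5, 83.7),
    },
    "ee_sensitivity_weighted": {
        "values": (75.9, 67.2, 68.6, 57.3, 71.9),
        "mean": 68.2, "sd": 6.95, "ci": (59.6, 76.8),
    },
    "elad_sensitivity_weighted": {
        "values": (49.3, 80.8, 92.1, 71.0, 54.0),
        "mean": 69.4, "sd": 17.95, "ci": (47.1, 91.7),
    },
    "ee_fpr": {
        "values": (33.1, 12.2, 18.3, 23.2, 32.9),
        "mean": 23.9, "sd": 9.14, "ci": (12.6, 35.2),
    },
    "elad_fpr": {
        "values": (30.2, 19.7, 43.0, 20.5, 18.3),
        "mean": 26.3, "sd": 10.43, "ci": (13.3, 39.3),
    },
}

#: Published pairwise selection correlations r^selection per ordered
#: (reference, partner) expert pair, cases P1..P5.
PAIRWISE_CORRELATIONS = {
    ("E1", "E2"): (0.857, 0.706, 0.913, 0.686, 0.722),
    ("E1", "E3"): (0.685, 0.907, 0.705, 0.714, 0.877),
    ("E1", "E4"): (0.703, 0.538, 0.685, 0.275, 0.443),
    ("E1", "E5"): (0.829, 0.706, 0.848, 0.607, 0.844),
    ("E2", "E1"): (0.857, 0.706, 0.913, 0.686, 0.722),
    ("E2", "E3"): (0.649, 0.583, 0.644, 0.832, 0.772),
    ("E2", "E4"): (0.751, 0.538, 0.625, 0.267, 0.511),
    ("E2", "E5"): (0.879, 1.000, 0.770, 0.737, 0.685),
    ("E3", "E1"): (0.685, 0.908, 0.705, 0.713, 0.876),
    ("E3", "E2"): (0.648, 0.583, 0.644, 0.832, 0.772),
    ("E3", "E4"): (0.720, 0.593, 0.629, 0.445, 0.613),
    ("E3", "E5"): (0.719, 0.583, 0.514, 0.777, 0.927),
    ("E4", "E1"): (0.703, 0.538, 0.760, 0.275, 0.443),
    ("E4", "E2"): (0.751, 0.538, 0.626, 0.268, 0.511),
    ("E4", "E3"): (0.720, 0.593, 0.629, 0.445, 0.613),
    ("E4", "E5"): (0.782, 0.538, 0.500, 0.158, 0.664),
    ("E5", "E1"): (0.829, 0.706, 0.843, 0.607, 0.844),
    ("E5", "E2"): (0.879, 1.000, 0.770, 0.737, 0.685),
    ("E5", "E3"): (0.719, 0.583, 0.514, 0.777, 0.926),
    ("E5", "E4"): (0.783, 0.538, 0.500, 0.158, 0.664),
}

#: Published per-reference-expert reliability coefficients and overall mean.
PUBLISHED_ALPHAS = {"E1": 0.925, "E2": 0.923, "E3": 0.919, "E4": 0.861, "E5": 0.922}
PUBLISHED_OVERALL_ALPHA = 0.910

#: Published per-case mean correlations (bottom row of the pairwise table).
PER_CASE_MEAN_CORRELATIONS = {
    "P1": 0.757, "P2": 0.669, "P3": 0.687, "P4": 0.550, "P5": 0.706,
}

#: Published overall mean correlation (two printed decimals).
PUBLISHED_MEAN_R = 0.67

#: The sixth sampled case, answered by only two experts and excluded
#: from all analyses.
INCOMPLETE_CASE = {"label": "P6", "answered_by": 2}


def _canonical() -> str:
    payload = {
        "totals": EXPERT_SELECTION_TOTALS,
        "counts": SELECTION_COUNTS,
        "rows": SCORE_ROWS,
        "corr": {f"{a}-{b}": v for (a, b), v in PAIRWISE_CORRELATIONS.items()},
        "alphas": PUBLISHED_ALPHAS,
        "overall": PUBLISHED_OVERALL_ALPHA,
        "case_means": PER_CASE_MEAN_CORRELATIONS,
        "mean_r": PUBLISHED_MEAN_R,
    }
    return json.dumps(payload, sort_keys=True)


FIXTURE_SHA256 = "4133df1f472c689caa4fe9a54f00c4aa5a7a52bd52c1920384dfe216cff422e7"


def verify_checksum() -> bool:
    """True iff the fixture constants hash to the recorded digest."""
    return hashlib.sha256(_canonical().encode()).hexdigest() == FIXTURE_SHA256
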