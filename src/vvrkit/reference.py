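"""Published summary data from the 537-patient CABG cohort.

These are the printed descriptive-table cells (contingency counts by
outcome group, group means +/- SD, and the published test statistics) and
the published power-analysis parameters.  They are the only patient-level
information publicly available for the study and serve as fixtures for
exact reproduction checks of the descriptive statistics and the
sample-size derivation.
"""

from __future__ import annotations

from .descriptives import ContingencyTable, GroupSummary

__all__ = [
    "N_TOTAL",
    "N_EVENTS",
    "CATEGORICAL_TABLES",
    "PRINTED_CHI_SQUARE",
    "CONTINUOUS_SUMMARIES",
    "PRINTED_WELCH_T",
    "SAMPLE_SIZE_PARAMS",
]

N_TOTAL = 537
N_EVENTS = 133

#: covariate -> r x 2 counts, rows = levels, columns = (no event, event)
CATEGORICAL_TABLES: dict[str, ContingencyTable] = {
    "gender": ContingencyTable(((259, 98), (145, 35)), ("male", "female")),
    "smoking": ContingencyTable(((243, 74), (161, 59)), ("no", "yes")),
    "drinking": ContingencyTable(((264, 94), (140, 39)), ("no", "yes")),
    "hypertension": ContingencyTable(((139, 65), (265, 68)), ("no", "yes")),
    "diabetes": ContingencyTable(((279, 77), (125, 56)), ("no", "yes")),
    "hyperlipidemia": ContingencyTable(((389, 127), (15, 6)), ("no", "yes")),
    "cerebrovascular": ContingencyTable(((322, 103), (82, 30)), ("no", "yes")),
    "comorbidity": ContingencyTable(((214, 61), (190, 72)), ("no", "yes")),
    "surgery_method": ContingencyTable(((234, 62), (170, 71)), ("off_pump", "on_pump")),
    "lvef": ContingencyTable(((47, 20), (50, 43), (307, 70)),
                             ("poor", "moderate", "normal")),
}

#: the published chi-square statistics that reproduce exactly (3 dp) from
#: the printed counts without continuity correction
PRINTED_CHI_SQUARE: dict[str, float] = {
    "gender": 4.117,
    "hypertension": 8.889,
    "diabetes": 5.582,
    "surgery_method": 5.169,
    "lvef": 31.711,
    "smoking": 0.841,
    "drinking": 1.279,
    "hyperlipidemia": 0.170,
    "cerebrovascular": 0.309,
    "comorbidity": 2.022,
}

#: covariate -> (no-event group, event group) summaries
CONTINUOUS_SUMMARIES: dict[str, tuple[GroupSummary, GroupSummary]] = {
    "age": (GroupSummary(404, 65.78, 7.25), GroupSummary(133, 64.20, 8.71)),
    "bmi": (GroupSummary(404, 24.75, 3.19), GroupSummary(133, 25.64, 3.21)),
}

#: published Welch t statistics (2 dp)
PRINTED_WELCH_T: dict[str, float] = {"age": 1.89, "bmi": -2.78}

#: published power analysis: event probability 0.02 in the low-score
#: (VVR < 35) group, odds ratio 4.95, two-sided alpha 0.05, power 0.90,
#: 20% dropout inflation -> 214 per group, 535 enrolled
SAMPLE_SIZE_PARAMS = {
    "p_control": 0.02,
    "odds_ratio": 4.95,
    "alpha": 0.05,
    "power": 0.90,
    "dropout_rate": 0.20,
    "published_n_per_group": 214,
    "published_n_with_dropout": 535,
}
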