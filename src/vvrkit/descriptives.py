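"""Descriptive group comparisons for the cohort characteristics table.

Categorical covariates are compared between outcome groups with Pearson's
chi-square (no continuity correction — the convention that reproduces the
published statistics from their printed counts), approximately normal
continuous covariates with Welch's unequal-variance t test, and skewed
severity scores with the Mann-Whitney U test reported as a tie-corrected
normal-approximation Z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "GroupSummary",
    "TestResult",
    "pearson_chi_square",
    "welch_t",
    "mann_whitney_z",
    "summarize_cohort",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Observed r x 2 counts: covariate levels (rows) by outcome no/yes."""

    observed: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, str] = ("no", "yes")

    def __post_init__(self) -> None:
        arr = np.asarray(self.observed)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("need at least a 2x2 table")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            raise ValueError("zero row or column marginal")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.observed, dtype=float)


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics (n, mean, sd) for one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd <= 0:
            raise ValueError("sd must be > 0")

    @classmethod
    def from_sample(cls, x: Sequence[float]) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(n=len(x), mean=float(x.mean()), sd=float(x.std(ddof=1)))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    warnings: tuple[str, ...] = field(default=())


def pearson_chi_square(table: ContingencyTable) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction.

    statistic = sum (O - E)^2 / E with E = row_total x col_total / N;
    df = (r - 1)(c - 1); p from the upper chi-square tail.
    """
    obs = table.array
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    notes: tuple[str, ...] = ()
    if (expected < 1).any():
        notes = ("expected count < 1 in at least one cell",)
        warnings.warn("chi-square approximation unreliable: expected count < 1",
                      stacklevel=2)
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(stat, df))
    return TestResult(statistic=stat, df=df, p_value=p, warnings=notes)


def welch_t(a: GroupSummary, b: GroupSummary) -> TestResult:
    """Welch's unequal-variance t test from group summaries."""
    stat, p = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=False
    )
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return TestResult(statistic=float(stat), df=float(df), p_value=float(p))


def mann_whitney_z(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Mann-Whitney U via midranks, reported as a tie-corrected Z.

    Z = (U - n1 n2 / 2) / sqrt(var) with the tie-corrected variance and no
    continuity correction; the two-sided p comes from the normal tail.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("each sample needs at least one observation")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        raise ValueError("all pooled values tied: zero-variance Mann-Whitney")
    z = (u1 - n1 * n2 / 2.0) / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return TestResult(statistic=float(z), df=np.inf, p_value=p)


def mann_whitney_exact_p(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Exact two-sided Mann-Whitney p by enumerating group assignments.

    Feasible only for small pooled samples (n1 + n2 <= 12); serves as the
    small-sample oracle for the normal-approximation Z reported by
    :func:`mann_whitney_z`.
    """
    from itertools import combinations

    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 + n2 > 12:
        raise ValueError("exact enumeration limited to n1 + n2 <= 12")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)

    def u_stat(idx: tuple[int, ...]) -> float:
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0

    u_obs = u_stat(tuple(range(n1)))
    mean = n1 * n2 / 2.0
    deviations = [abs(u_stat(c) - mean) for c in combinations(range(n1 + n2), n1)]
    return float(np.mean([d >= abs(u_obs - mean) - 1e-12 for d in deviations]))


#: covariate -> (kind, display label); order mirrors the published table
_TABLE_SPEC = [
    ("sex", "categorical", "Gender"),
    ("age", "normal", "Age (year)"),
    ("bmi", "normal", "BMI (kg/m2)"),
    ("smoking", "categorical", "Smoking"),
    ("drinking", "categorical", "Drinking"),
    ("hypertension", "categorical", "Hypertension"),
    ("diabetes", "categorical", "Diabetes"),
    ("hyperlipidemia", "categorical", "Hyperlipidemia"),
    ("cerebrovascular", "categorical", "Cerebrovascular disease"),
    ("chronic_nephrosis", "categorical", "Chronic nephrosis"),
    ("copd", "categorical", "COPD"),
    ("comorbidity", "categorical", "Comorbidity"),
    ("surgery_method", "categorical", "Surgery methods"),
    ("lvef_category", "categorical", "LVEF"),
    ("vis", "skewed", "VIS"),
    ("vvr", "skewed", "VVR"),
    ("mvvr", "skewed", "M-VVR"),
]


def summarize_cohort(frame: pd.DataFrame, outcome: str = "poor_prognosis") -> pd.DataFrame:
    """Build the characteristics table: one row per covariate with the
    test routed by type (categorical -> chi-square, normal continuous ->
    Welch t, skewed score -> Mann-Whitney Z).

    Percentages are reported to 2 dp and statistics to 3 dp in the
    ``summary_*`` display columns; ``statistic`` and ``p_value`` keep full
    precision.
    """
    if frame.empty:
        raise ValueError("empty cohort")
    y = frame[outcome].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; group comparison undefined")
    no, yes = frame[y == 0], frame[y == 1]
    rows = []
    for col, kind, label in _TABLE_SPEC:
        if col not in frame.columns:
            continue
        if kind == "categorical":
            levels = sorted(frame[col].unique(), key=str)
            counts = [
                (sum(no[col] == lv), sum(yes[col] == lv)) for lv in levels
            ]
            res = pearson_chi_square(ContingencyTable(
                observed=tuple(counts), row_labels=tuple(map(str, levels))
            ))
            total = frame[col].value_counts()
            summary = "; ".join(
                f"{lv}: {total.get(lv, 0)} ({100 * total.get(lv, 0) / len(frame):.2f}%)"
                for lv in levels
            )
            test_name = "chi-square"
        elif kind == "normal":
            res = welch_t(GroupSummary.from_sample(no[col]),
                          GroupSummary.from_sample(yes[col]))
            summary = f"{frame[col].mean():.2f} +/- {frame[col].std(ddof=1):.2f}"
            test_name = "welch-t"
        elif kind == "skewed":
            res = mann_whitney_z(yes[col], no[col])
            q1, med, q3 = frame[col].quantile([0.25, 0.5, 0.75])
            summary = f"{med:.2f} ({q1:.2f}, {q3:.2f})"
            test_name = "mann-whitney"
        else:  # pragma: no cover
            raise ValueError(f"unknown covariate type {kind!r}")
        rows.append({
            "variable": label,
            "test": test_name,
            "summary_total": summary,
            "statistic": res.statistic,
            "statistic_3dp": round(res.statistic, 3),
            "df": res.df,
            "p_value": res.p_value,
        })
    return pd.DataFrame(rows)
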