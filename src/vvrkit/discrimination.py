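"""Discrimination and calibration of severity scores.

AUC is the probability that a random case outscores a random control,
estimated with midranks so heavily tied scores (many patients at VIS = 0)
are handled exactly.  Correlated AUCs on the same subjects are compared
with the DeLong test: per-subject structural components (the placement of
each case among the controls and vice versa) give a U-statistic covariance
for single-score confidence intervals and paired contrasts.  Calibration
is assessed with the Hosmer-Lemeshow chi-square on equal-frequency risk
bins and with per-bin observed-vs-predicted plot data.

Higher scores are treated as predicting the poor outcome; all outputs are
invariant under strictly increasing transforms of a score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RocCurve",
    "RocComparison",
    "CalibrationResult",
    "roc_curve",
    "auc_midrank",
    "delong_components",
    "delong_auc_ci",
    "delong_paired_test",
    "compare_scores",
    "hosmer_lemeshow",
    "calibration_bins",
]


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve with its trapezoidal area."""

    thresholds: np.ndarray  # descending score cutoffs
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class RocComparison:
    """Per-score AUC with CI plus pairwise DeLong contrasts."""

    auc_per_score: dict
    contrasts: dict


@dataclass(frozen=True)
class CalibrationResult:
    n_bins: int
    bin_edges: np.ndarray
    observed_events: np.ndarray
    expected_events: np.ndarray
    bin_sizes: np.ndarray
    hl_statistic: float
    df: int
    p_value: float
    warnings: tuple[str, ...] = field(default=())


def _split(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    cases, controls = s[y == 1], s[y == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both outcome classes must be present")
    return cases, controls


def auc_midrank(scores, labels) -> float:
    """AUC = mean over case-control pairs of 1[case>control] + 0.5*ties.

    Computed in O(n log n) via midranks; equals the trapezoidal area
    under the empirical ROC curve.
    """
    cases, controls = _split(scores, labels)
    m, n = len(cases), len(controls)
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    return float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n))


def roc_curve(scores, labels) -> RocCurve:
    """Empirical ROC stepping through unique score cutoffs (descending)."""
    cases, controls = _split(scores, labels)
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    cuts = np.unique(s)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for c in cuts:
        tpr.append(float((cases >= c).mean()))
        fpr.append(float((controls >= c).mean()))
    fpr_a, tpr_a = np.asarray(fpr), np.asarray(tpr)
    auc = float(np.trapezoid(tpr_a, fpr_a))
    thresholds = np.concatenate([[np.inf], cuts])
    return RocCurve(thresholds=thresholds, fpr=fpr_a, tpr=tpr_a, auc=auc)


def delong_components(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """DeLong structural components for one score.

    Returns (auc, V10, V01): V10[i] is the placement of case i among the
    controls (fraction of controls it beats, ties half), V01[j] the
    placement of control j among the cases.  Means of both equal the AUC.
    """
    cases, controls = _split(scores, labels)
    m, n = len(cases), len(controls)
    all_ranks = stats.rankdata(np.concatenate([cases, controls]))
    case_ranks = stats.rankdata(cases)
    control_ranks = stats.rankdata(controls)
    v10 = (all_ranks[:m] - case_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - control_ranks) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_auc_ci(scores, labels, level: float = 0.95) -> tuple[float, tuple[float, float], float]:
    """AUC with a DeLong Wald CI truncated to [0, 1].

    Returns (auc, (lo, hi), se).  With perfect separation the placement
    variance is 0; the CI collapses to the point and a warning is issued.
    """
    auc, v10, v01 = delong_components(scores, labels)
    m, n = len(v10), len(v01)
    if m < 2 or n < 2:
        raise ValueError("need at least 2 members per class for a DeLong CI")
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    se = float(np.sqrt(var))
    if se == 0.0:
        warnings.warn("degenerate DeLong variance: CI collapses to the point",
                      stacklevel=2)
        return auc, (auc, auc), 0.0
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return auc, (lo, hi), se


def delong_paired_test(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """DeLong test for two correlated AUCs measured on the same subjects.

    Returns (auc_a - auc_b, z, two-sided p).  The variance of the
    difference uses the paired covariance of the structural components:
    var_a + var_b - 2 cov, separately for cases and controls.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired scores must cover the same subjects")
    auc_a, v10_a, v01_a = delong_components(a, labels)
    auc_b, v10_b, v01_b = delong_components(b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(v10_a, v10_b, ddof=1)
    s01 = np.cov(v01_a, v01_b, ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) < 1e-12:
            return 0.0, 0.0, 1.0
        raise ValueError("zero variance of the AUC difference with a nonzero difference")
    z = diff / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(diff), float(z), p


def compare_scores(frame: pd.DataFrame, scores=("vis", "vvr", "mvvr"),
                   outcome: str = "poor_prognosis") -> RocComparison:
    """AUC table with pairwise DeLong contrasts for the selected scores."""
    y = frame[outcome].to_numpy()
    auc_per_score = {}
    for s in scores:
        auc, ci, se = delong_auc_ci(frame[s].to_numpy(), y)
        auc_per_score[s] = {"auc": auc, "ci_95": ci, "se": se}
    contrasts = {}
    for i, a in enumerate(scores):
        for b in scores[i + 1:]:
            diff, z, p = delong_paired_test(frame[a].to_numpy(),
                                            frame[b].to_numpy(), y)
            contrasts[(a, b)] = {"auc_difference": diff, "z": z, "p_value": p}
    return RocComparison(auc_per_score=auc_per_score, contrasts=contrasts)


def _equal_frequency_bins(probs: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin ids from probability deciles; ties stay in one bin, empty bins merged."""
    edges = np.quantile(probs, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    ids = np.clip(np.searchsorted(edges, probs, side="right") - 1, 0, len(edges) - 2)
    # relabel to consecutive occupied bins
    occupied = np.unique(ids)
    remap = {old: new for new, old in enumerate(occupied)}
    return np.array([remap[i] for i in ids]), edges


def hosmer_lemeshow(predicted_probs, outcomes, n_bins: int = 10) -> CalibrationResult:
    """Hosmer-Lemeshow goodness of fit on equal-frequency risk bins.

    H = sum (O - E)^2 / (E (1 - E/n_g)) over bins; df = n_bins - 2 (reduced
    when ties force bin merging, with a warning attached).
    """
    p = np.asarray(predicted_probs, dtype=float)
    y = np.asarray(outcomes)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("predicted probabilities must lie strictly in (0, 1)")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if len(p) < 5 * n_bins:
        raise ValueError(f"need n >= {5 * n_bins} for {n_bins} bins")
    ids, edges = _equal_frequency_bins(p, n_bins)
    g = ids.max() + 1
    notes: tuple[str, ...] = ()
    if g < n_bins:
        notes = (f"ties merged bins: {g} effective bins (requested {n_bins})",)
        warnings.warn(notes[0], stacklevel=2)
    df = g - 2
    if df < 1:
        raise ValueError("fewer than 3 effective bins: Hosmer-Lemeshow undefined")
    observed = np.bincount(ids, weights=y.astype(float), minlength=g)
    expected = np.bincount(ids, weights=p, minlength=g)
    sizes = np.bincount(ids, minlength=g).astype(float)
    h = float((((observed - expected) ** 2) /
               (expected * (1.0 - expected / sizes))).sum())
    pval = float(stats.chi2.sf(h, df))
    return CalibrationResult(
        n_bins=g, bin_edges=edges, observed_events=observed,
        expected_events=expected, bin_sizes=sizes,
        hl_statistic=h, df=df, p_value=pval, warnings=notes,
    )


def calibration_bins(predicted_probs, outcomes, n_bins: int = 10,
                     level: float = 0.95) -> pd.DataFrame:
    """Per-bin mean predicted vs observed event fraction with binomial CIs.

    The rows are ready to plot as a calibration curve against the
    diagonal of perfect calibration.
    """
    p = np.asarray(predicted_probs, dtype=float)
    y = np.asarray(outcomes)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("predicted probabilities must lie strictly in (0, 1)")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    ids, _ = _equal_frequency_bins(p, n_bins)
    rows = []
    for b in range(ids.max() + 1):
        mask = ids == b
        k, ng = int(y[mask].sum()), int(mask.sum())
        ci = stats.binomtest(k, ng).proportion_ci(confidence_level=level)
        rows.append({
            "bin": b,
            "n": ng,
            "mean_predicted": float(p[mask].mean()),
            "observed_rate": k / ng,
            "ci_low": ci.low,
            "ci_high": ci.high,
        })
    return pd.DataFrame(rows)
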