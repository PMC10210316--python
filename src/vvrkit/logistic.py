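"""Logistic regression of the binary endpoint on severity scores.

Maximum likelihood via iteratively reweighted least squares (IRLS) with
step-halving, Wald covariance from the inverse observed information, and
odds ratios with 95% Wald confidence intervals — the output layout of the
published association table (unadjusted "model 1" and a "model 2"
adjusted for gender, BMI, hypertension, diabetes, surgery method and LVEF
category with two indicator contrasts against the "normal" reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_ADJUSTMENT_SET",
    "ModelSpec",
    "LogisticFit",
    "SeparationError",
    "fit_logistic",
    "build_design",
    "score_or",
    "or_table",
]

#: covariates of the adjusted ("model 2") specification, in design order
DEFAULT_ADJUSTMENT_SET = ("male", "bmi", "hypertension", "diabetes",
                          "on_pump", "lvef_moderate", "lvef_poor")


class SeparationError(RuntimeError):
    """Raised when quasi-complete separation prevents a finite MLE."""


@dataclass(frozen=True)
class ModelSpec:
    """Which score is the predictor and what is adjusted for."""

    predictor: str
    adjustment_set: tuple[str, ...] = DEFAULT_ADJUSTMENT_SET

    def __post_init__(self) -> None:
        if self.predictor in self.adjustment_set:
            raise ValueError("predictor cannot appear in the adjustment set")


@dataclass
class LogisticFit:
    """MLE results for one logistic model."""

    names: tuple[str, ...]
    coefficients: np.ndarray       # log-odds per unit
    covariance: np.ndarray         # inverse observed information
    converged: bool
    n_iterations: int
    log_likelihood: float
    n_obs: int
    warnings: tuple[str, ...] = field(default=())

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    @property
    def or_estimates(self) -> np.ndarray:
        self._require_converged()
        return np.exp(self.coefficients)

    def ci_95(self) -> np.ndarray:
        """Wald interval exp(beta +/- z0.975 * se), one row per term."""
        self._require_converged()
        z = stats.norm.ppf(0.975)
        lo = np.exp(self.coefficients - z * self.se)
        hi = np.exp(self.coefficients + z * self.se)
        return np.column_stack([lo, hi])

    def p_values(self) -> np.ndarray:
        self._require_converged()
        z = self.coefficients / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def _require_converged(self) -> None:
        if not self.converged:
            raise SeparationError(
                "fit did not converge (possible quasi-complete separation); "
                "odds ratios are not reportable"
            )

    def summary_frame(self) -> pd.DataFrame:
        ci = self.ci_95()
        return pd.DataFrame({
            "term": self.names,
            "coef": self.coefficients,
            "se": self.se,
            "or": self.or_estimates,
            "or_ci_low": ci[:, 0],
            "or_ci_high": ci[:, 1],
            "p_value": self.p_values(),
        })


def _log_likelihood(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1 + e^eta) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    design: np.ndarray | pd.DataFrame,
    outcome: Sequence[int],
    *,
    names: Sequence[str] | None = None,
    add_intercept: bool = True,
    max_iter: int = 100,
    grad_tol: float = 1e-8,
    ll_rtol: float = 1e-10,
    separation_beta: float = 15.0,
) -> LogisticFit:
    """Fit a logistic model by IRLS with step-halving.

    Convergence requires max |score gradient| < ``grad_tol`` or a relative
    log-likelihood change < ``ll_rtol``.  A coefficient exceeding
    ``separation_beta`` in absolute value marks quasi-complete separation:
    the fit is returned flagged non-converged and odds-ratio accessors
    raise :class:`SeparationError`.
    """
    if isinstance(design, pd.DataFrame):
        if names is None:
            names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if names is None:
            names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class; logistic MLE undefined")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("design or outcome contains missing values")
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["intercept", *names]
    # a non-intercept column with zero variance makes the model unidentifiable
    for j in range(1 if add_intercept else 0, X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"constant non-intercept column: {names[j]!r}")

    n, p = X.shape
    beta = np.zeros(p)
    ll = _log_likelihood(X, y, beta)
    converged = False
    notes: list[str] = []
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < grad_tol:
            converged = True
            break
        XtWX = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError:
            notes.append("singular information matrix")
            break
        # step-halving: the deviance must never increase across iterations
        factor = 1.0
        for _ in range(30):
            candidate = beta + factor * step
            ll_new = _log_likelihood(X, y, candidate)
            if ll_new >= ll:
                break
            factor /= 2.0
        else:
            converged = True  # no uphill step exists at float precision
            break
        beta = candidate
        if abs(ll_new - ll) <= ll_rtol * (abs(ll) + 1e-300):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    if np.max(np.abs(beta)) > separation_beta:
        converged = False
        notes.append(
            f"|beta| > {separation_beta}: quasi-complete separation suspected"
        )

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    XtWX = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return LogisticFit(
        names=tuple(names),
        coefficients=beta,
        covariance=cov,
        converged=converged,
        n_iterations=it,
        log_likelihood=_log_likelihood(X, y, beta),
        n_obs=n,
        warnings=tuple(notes),
    )


def build_design(frame: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Assemble a numeric design matrix, deriving the standard encodings.

    ``male`` comes from ``sex``, ``on_pump`` from ``surgery_method`` and
    ``lvef_moderate``/``lvef_poor`` are indicator contrasts of
    ``lvef_category`` against the "normal" reference; any other name must
    be a numeric column of ``frame``.
    """
    out = {}
    for col in columns:
        if col in frame.columns:
            out[col] = frame[col].astype(float)
        elif col == "male":
            out[col] = (frame["sex"] == "male").astype(float)
        elif col == "on_pump":
            out[col] = (frame["surgery_method"] == "on_pump").astype(float)
        elif col == "lvef_moderate":
            out[col] = (frame["lvef_category"] == "moderate").astype(float)
        elif col == "lvef_poor":
            out[col] = (frame["lvef_category"] == "poor").astype(float)
        else:
            raise KeyError(f"no column or known encoding for {col!r}")
    return pd.DataFrame(out, index=frame.index)


def score_or(
    frame: pd.DataFrame,
    spec: ModelSpec,
    *,
    adjusted: bool,
    outcome: str = "poor_prognosis",
) -> dict:
    """Odds ratio per 1-unit score increment, unadjusted or adjusted.

    Returns a table row: estimate, Wald 95% CI and p for the score term,
    plus the underlying :class:`LogisticFit`.
    """
    cols = [spec.predictor] + (list(spec.adjustment_set) if adjusted else [])
    X = build_design(frame, cols)
    fit = fit_logistic(X, frame[outcome].to_numpy())
    idx = fit.names.index(spec.predictor)
    ci = fit.ci_95()[idx]
    return {
        "predictor": spec.predictor,
        "model": "adjusted" if adjusted else "unadjusted",
        "or": float(fit.or_estimates[idx]),
        "or_ci_low": float(ci[0]),
        "or_ci_high": float(ci[1]),
        "p_value": float(fit.p_values()[idx]),
        "fit": fit,
    }


def or_table(
    frame: pd.DataFrame,
    scores: Sequence[str] = ("vis", "vvr", "mvvr"),
    *,
    adjustment_set: tuple[str, ...] = DEFAULT_ADJUSTMENT_SET,
    outcome: str = "poor_prognosis",
) -> pd.DataFrame:
    """Association table: one row per score x (unadjusted, adjusted)."""
    rows = []
    for score in scores:
        spec = ModelSpec(predictor=score, adjustment_set=adjustment_set)
        for adjusted in (False, True):
            row = score_or(frame, spec, adjusted=adjusted, outcome=outcome)
            row.pop("fit")
            rows.append(row)
    return pd.DataFrame(rows)
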