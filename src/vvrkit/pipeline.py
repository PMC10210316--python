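"""Config-driven orchestration: cohort in, full report suite out.

Stages run in a fixed order — score panels, descriptive comparisons,
logistic odds ratios, ROC/DeLong discrimination, Hosmer-Lemeshow
calibration, and the design-stage sample-size report — and the artifacts
mirror the published tables.  Outputs are a pure function of (config,
seed, input bytes); run timestamps go to the log stream only, so repeated
runs produce byte-identical report files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, PatientRecord, frame_to_records, generate_frame
from .descriptives import summarize_cohort
from .discrimination import calibration_bins, compare_scores, hosmer_lemeshow, roc_curve
from .logistic import DEFAULT_ADJUSTMENT_SET, ModelSpec, build_design, fit_logistic, or_table, score_or
from .samplesize import SampleSizeSpec, two_proportion_n

__all__ = [
    "RunConfig",
    "RunReport",
    "run_analysis",
    "read_cohort_csv",
    "write_cohort_csv",
    "compute_score_columns",
]

log = logging.getLogger("vvrkit")

#: columns every cohort CSV must carry (scores are recomputed if absent)
REQUIRED_COLUMNS = (
    "patient_id", "sex", "age", "bmi", "weight",
    "smoking", "drinking", "hypertension", "diabetes", "hyperlipidemia",
    "cerebrovascular", "chronic_nephrosis", "copd", "comorbidity",
    "surgery_method", "lvef_category",
    "dopamine", "dobutamine", "epinephrine", "norepinephrine",
    "milrinone", "vasopressin",
    "respiratory_rate", "pip", "peep", "paco2",
    "serum_creatinine_post", "serum_creatinine_baseline",
    "poor_prognosis",
)

_DOSE_COLUMNS = ("dopamine", "dobutamine", "epinephrine",
                 "norepinephrine", "milrinone", "vasopressin")


@dataclass
class RunConfig:
    """Everything one analysis run depends on."""

    input_csv: str | None = None                 # exclusive with `synthetic`
    synthetic: CohortConfig | None = None
    scores: tuple[str, ...] = ("vis", "vvr", "mvvr")
    adjustment_set: tuple[str, ...] = DEFAULT_ADJUSTMENT_SET
    calibration_score: str = "mvvr"
    n_bins: int = 10
    seed: int = 0
    output_dir: str | None = None
    report_formats: tuple[str, ...] = ("csv", "json")

    def validate(self) -> None:
        if (self.input_csv is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_csv or synthetic must be set")
        if not self.scores:
            raise ValueError("at least one score must be selected")
        unknown = set(self.scores) - {"vis", "vvr", "mvvr"}
        if unknown:
            raise ValueError(f"unknown scores: {sorted(unknown)}")
        bad = set(self.report_formats) - {"csv", "json"}
        if bad:
            raise ValueError(f"unknown report formats: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = CohortConfig(**raw["synthetic"])
        for key in ("scores", "adjustment_set", "report_formats"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunReport:
    """All artifacts of one run, as in-memory tables and dicts."""

    descriptives: pd.DataFrame
    or_table: pd.DataFrame
    auc_table: pd.DataFrame
    contrasts: pd.DataFrame
    roc_points: pd.DataFrame
    calibration: pd.DataFrame
    hl_result: dict
    sample_size: dict
    provenance: dict
    cohort: pd.DataFrame = field(repr=False, default=None)


def compute_score_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """(Re)compute vis/vi/delta_cr/ccr/vvr/mvvr columns vectorized."""
    out = frame.copy()
    out["vis"] = (out["dopamine"] + out["dobutamine"]
                  + 100.0 * out["epinephrine"] + 100.0 * out["norepinephrine"]
                  + 10.0 * out["milrinone"] + 10000.0 * out["vasopressin"])
    out["vi"] = (out["respiratory_rate"] * (out["pip"] - out["peep"])
                 * out["paco2"] / 1000.0)
    out["delta_cr"] = np.maximum(
        out["serum_creatinine_post"] - out["serum_creatinine_baseline"], 0.0)
    male = (out["sex"] == "male").to_numpy()
    out["ccr"] = ((140.0 - out["age"]) * out["weight"]
                  / (72.0 * out["serum_creatinine_post"])
                  * np.where(male, 1.0, 0.85))
    out["vvr"] = out["vi"] + out["vis"] + 10.0 * out["delta_cr"]
    out["mvvr"] = out["vi"] + out["vis"] + out["ccr"]
    return out


def _validate_cohort(frame: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort is missing required columns: {missing}")
    for col in _DOSE_COLUMNS:
        bad = frame.index[frame[col] < 0].tolist()
        if bad:
            raise ValueError(f"negative {col} dose at rows {bad[:10]}")
    for col in ("serum_creatinine_post", "serum_creatinine_baseline", "weight"):
        bad = frame.index[frame[col] <= 0].tolist()
        if bad:
            raise ValueError(f"non-positive {col} at rows {bad[:10]}")
    if frame.index[frame["pip"] < frame["peep"]].tolist():
        bad = frame.index[frame["pip"] < frame["peep"]].tolist()
        raise ValueError(f"pip < peep at rows {bad[:10]}")
    if set(frame["poor_prognosis"].unique()) - {0, 1}:
        raise ValueError("poor_prognosis must be binary 0/1")


def read_cohort_csv(path: str | Path, *, as_records: bool = False
                    ) -> pd.DataFrame | list[PatientRecord]:
    """Read and validate a cohort CSV (snake_case headers, any case).

    Extra columns are preserved untouched; score columns are recomputed
    from the physiology so stale values cannot leak through.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"empty cohort file: {path}")
    frame.columns = [c.strip().lower() for c in frame.columns]
    _validate_cohort(frame)
    frame = compute_score_columns(frame)
    return frame_to_records(frame) if as_records else frame


def write_cohort_csv(frame: pd.DataFrame, path: str | Path,
                     *, provenance: dict | None = None) -> None:
    """Write a cohort CSV, with an adjacent ``.provenance.json`` if given."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    if provenance is not None:
        side = path.with_suffix(".provenance.json")
        side.write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    payload = dataclasses.asdict(config)
    payload.pop("output_dir", None)  # where the report lands is not analytic input
    blob = json.dumps(payload, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_analysis(config: RunConfig) -> RunReport:
    """Execute the full pipeline; write artifacts if output_dir is set.

    Stage order: scores -> descriptives -> logistic -> discrimination ->
    calibration -> sample-size.  A failing stage aborts with its name in
    the raised error.
    """
    config.validate()
    input_bytes = b""
    if config.input_csv is not None:
        input_bytes = Path(config.input_csv).read_bytes()
        cohort = read_cohort_csv(config.input_csv)
        gen_info = None
        log.info("loaded cohort of %d patients from %s", len(cohort), config.input_csv)
    else:
        synth = dataclasses.replace(config.synthetic, seed=config.seed)
        cohort, gen_info = generate_frame(synth)
        log.info("generated synthetic cohort of %d patients (seed %d)",
                 len(cohort), config.seed)

    stage = "scores"
    try:
        cohort = compute_score_columns(cohort)
        log.info("scores: %d panels, %d poor-prognosis events",
                 len(cohort), int(cohort["poor_prognosis"].sum()))

        stage = "descriptives"
        descriptives = summarize_cohort(cohort)

        stage = "logistic"
        ors = or_table(cohort, config.scores, adjustment_set=config.adjustment_set)

        stage = "discrimination"
        comparison = compare_scores(cohort, config.scores)
        auc_rows = [
            {"score": s, "auc": d["auc"],
             "ci_low": d["ci_95"][0], "ci_high": d["ci_95"][1], "se": d["se"]}
            for s, d in comparison.auc_per_score.items()
        ]
        contrast_rows = [
            {"score_a": a, "score_b": b, **d}
            for (a, b), d in comparison.contrasts.items()
        ]
        roc_rows = []
        for s in config.scores:
            curve = roc_curve(cohort[s].to_numpy(), cohort["poor_prognosis"].to_numpy())
            roc_rows.append(pd.DataFrame({
                "score": s, "threshold": curve.thresholds,
                "fpr": curve.fpr, "tpr": curve.tpr,
            }))

        stage = "calibration"
        cal_score = (config.calibration_score if config.calibration_score
                     in config.scores else config.scores[0])
        spec = ModelSpec(predictor=cal_score, adjustment_set=config.adjustment_set)
        fitted = score_or(cohort, spec, adjusted=True)["fit"]
        X = build_design(cohort, [cal_score, *config.adjustment_set])
        eta = fitted.coefficients[0] + X.to_numpy() @ fitted.coefficients[1:]
        probs = 1.0 / (1.0 + np.exp(-eta))
        hl = hosmer_lemeshow(probs, cohort["poor_prognosis"].to_numpy(), config.n_bins)
        cal = calibration_bins(probs, cohort["poor_prognosis"].to_numpy(), config.n_bins)

        stage = "sample_size"
        ss = two_proportion_n(SampleSizeSpec())
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    provenance = {
        "config_hash": _config_hash(config),
        "input_sha256": hashlib.sha256(input_bytes).hexdigest() if input_bytes else None,
        "seed": config.seed,
        "software_version": __version__,
        "generator_info": gen_info,
    }
    report = RunReport(
        descriptives=descriptives,
        or_table=ors,
        auc_table=pd.DataFrame(auc_rows),
        contrasts=pd.DataFrame(contrast_rows),
        roc_points=pd.concat(roc_rows, ignore_index=True),
        calibration=cal,
        hl_result={"statistic": float(hl.hl_statistic), "df": int(hl.df),
                   "p_value": float(hl.p_value), "n_bins": int(hl.n_bins),
                   "warnings": list(hl.warnings)},
        sample_size=dataclasses.asdict(ss),
        provenance=provenance,
        cohort=cohort,
    )
    if config.output_dir is not None:
        _write_report(report, config)
    return report


def _write_report(report: RunReport, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "descriptives": report.descriptives,
        "or_table": report.or_table,
        "auc_table": report.auc_table,
        "delong_contrasts": report.contrasts,
        "roc_points": report.roc_points,
        "calibration": report.calibration,
    }
    for name, frame in tables.items():
        if "csv" in config.report_formats:
            frame.to_csv(out / f"{name}.csv", index=False)
        if "json" in config.report_formats:
            (out / f"{name}.json").write_text(
                frame.to_json(orient="records", indent=2) + "\n")
    for name, payload in (("hosmer_lemeshow", report.hl_result),
                          ("sample_size", report.sample_size),
                          ("provenance", report.provenance)):
        (out / f"{name}.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n")
    log.info("report written to %s", out)
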