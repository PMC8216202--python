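"""CSV interchange, pipeline orchestration, and run logging.

The trial table is a UTF-8, comma-delimited CSV with a header row and one row
per trial. Required columns: participant_id, block, trial, stimulus,
response, confidence, rt_ms, soa_ms, comprehension_pass. Stimulus and
response are the strings "S1"/"S2" (experiment-specific display labels such
as "Q"/"O" are presentation-only and never stored). Confidence lives on
[0, 1]; rows violating the schema are dropped with a warning, or abort the
read when they exceed 1% of the table.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference, preprocess, sdt_matched, type2roc
from .observer_sim import S1, S2

logger = logging.getLogger("metaroc")

REQUIRED_COLUMNS = [
    "participant_id",
    "block",
    "trial",
    "stimulus",
    "response",
    "confidence",
    "rt_ms",
    "soa_ms",
    "comprehension_pass",
]

MAX_MALFORMED_FRACTION = 0.01


@dataclass(frozen=True)
class RunConfig:
    command: str
    input_path: Path | None = None
    output_dir: Path = Path("metaroc_out")
    seed: int = 0
    experiment_label: str = "Q_in_O"
    bf_alternative: str = "directional"
    rscale: float = inference.DEFAULT_RSCALE
    overwrite: bool = False
    extra: dict = field(default_factory=dict)


def read_trials_csv(path):
    """Read and validate a trial CSV.

    Returns ``(trials, comprehension)`` — the validated trial table (with a
    recomputed ``correct`` column) and a participant-indexed boolean Series.
    Missing columns are fatal; malformed rows (labels outside {S1, S2},
    confidence outside [0, 1], non-positive or non-numeric rt/soa) are
    dropped with a warning unless they exceed 1% of rows, which is fatal.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    n_raw = len(df)
    if n_raw == 0:
        raise ValueError(f"{path}: no trial rows")

    for col in ("confidence", "rt_ms", "soa_ms", "block", "trial"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = (
        ~df["stimulus"].isin([S1, S2])
        | ~df["response"].isin([S1, S2])
        | df["confidence"].isna()
        | (df["confidence"] < 0)
        | (df["confidence"] > 1)
        | df["rt_ms"].isna()
        | (df["rt_ms"] <= 0)
        | df["soa_ms"].isna()
        | (df["soa_ms"] <= 0)
        | df["block"].isna()
        | df["trial"].isna()
    )
    n_bad = int(bad.sum())
    if n_bad:
        if n_bad / n_raw > MAX_MALFORMED_FRACTION:
            raise ValueError(
                f"{path}: {n_bad}/{n_raw} malformed rows exceed the "
                f"{MAX_MALFORMED_FRACTION:.0%} tolerance"
            )
        warnings.warn(f"{path}: dropped {n_bad} malformed rows", stacklevel=2)
        logger.warning("%s: dropped %d malformed rows", path, n_bad)
        df = df.loc[~bad]
    df = df.copy()
    df["block"] = df["block"].astype(int)
    df["trial"] = df["trial"].astype(int)
    df["correct"] = df["stimulus"] == df["response"]
    df["comprehension_pass"] = df["comprehension_pass"].astype(bool)
    comprehension = df.groupby("participant_id")["comprehension_pass"].first()
    return df, comprehension


def write_trials_csv(trials: pd.DataFrame, path, overwrite: bool = False) -> Path:
    path = Path(path)
    _guard_overwrite(path, overwrite)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in REQUIRED_COLUMNS if c in trials.columns]
    extra = [c for c in trials.columns if c not in cols]
    trials[cols + extra].to_csv(path, index=False)
    return path


def _guard_overwrite(path: Path, overwrite: bool) -> None:
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite to replace it")


def _roc_curve_table(trials: pd.DataFrame, included_ids) -> pd.DataFrame:
    """Tidy empirical + model curves for every included participant."""
    rows = []
    for pid in included_ids:
        sub = preprocess.filter_trials(trials[trials["participant_id"] == pid])
        fit = sdt_matched.estimate_sdt(sub)
        for resp in (S1, S2):
            cc, ci = type2roc.split_confidences(sub, resp)
            emp = type2roc.response_conditional_roc(cc, ci, response=resp)
            model = sdt_matched.expected_roc_curve(fit, resp, ci)
            for kind, curve in (("empirical", emp), ("model", model)):
                rows.append(
                    pd.DataFrame(
                        {
                            "participant_id": pid,
                            "response": resp,
                            "kind": kind,
                            "far": curve.far,
                            "hr": curve.hr,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def run_pipeline(config: RunConfig, trials: pd.DataFrame | None = None) -> dict:
    """Analyze a trial table end to end and write the report bundle.

    Stages: trial filter -> participant exclusion -> participant summaries ->
    empirical and SDT-matched ROC curves -> hypothesis battery. Artifacts in
    ``config.output_dir``: exclusions.csv, summaries.csv, roc_curves.csv,
    report.json, run.log. Fails when fewer than 3 participants survive
    exclusion.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        if trials is None:
            trials, comprehension = read_trials_csv(config.input_path)
        else:
            comprehension = None
        logger.info("seed=%s command=%s", config.seed, config.command)
        logger.info("input rows=%d participants=%d",
                    len(trials), trials["participant_id"].nunique())
        exclusions, summaries = preprocess.process_cohort(trials, comprehension)
        n_excluded = int(exclusions["excluded"].sum())
        logger.info("excluded=%d included=%d", n_excluded, len(summaries))
        if len(summaries) < 3:
            reasons = exclusions.loc[exclusions["excluded"], "reasons"].tolist()
            raise RuntimeError(
                "fewer than 3 participants included after exclusion; see "
                f"exclusion report (reasons: {reasons})"
            )
        results = inference.hypothesis_battery(
            summaries, rscale=config.rscale, bf_alternative=config.bf_alternative
        )
        report = {
            "seed": config.seed,
            "experiment_label": config.experiment_label,
            "n_participants": int(len(exclusions)),
            "n_included": int(len(summaries)),
            "n_trials_input": int(len(trials)),
        }
        report.update(
            inference.battery_report(
                results, rscale=config.rscale, bf_alternative=config.bf_alternative
            )
        )
        for name, frame in (
            ("exclusions.csv", exclusions),
            ("summaries.csv", summaries),
        ):
            _guard_overwrite(out / name, config.overwrite)
            frame.to_csv(out / name, index=False)
        curves = _roc_curve_table(trials, summaries["participant_id"])
        _guard_overwrite(out / "roc_curves.csv", config.overwrite)
        curves.to_csv(out / "roc_curves.csv", index=False)
        _guard_overwrite(out / "report.json", config.overwrite)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        logger.info("wrote report bundle to %s", out)
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()


__all__ = [
    "REQUIRED_COLUMNS",
    "RunConfig",
    "read_trials_csv",
    "write_trials_csv",
    "run_pipeline",
]
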