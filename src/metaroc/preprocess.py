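"""Pre-registered trial filtering, participant exclusion, and summaries.

Trial filter: only blocks 2-6 are analyzed, and trials with response times
below 250 ms or above 5 s are dropped. Participant exclusion: accuracy below
60% (on the analyzed trials), response times out of range in more than 25% of
all trials, a failed comprehension check, or fewer than two errors for either
response type (without errors of both kinds the response-conditional type-2
ROCs are undefined). Per-participant summaries hold the four pre-registered
dependent variables: mean confidence per response, response-conditional
auROC per response (and their difference), the equal-variance-SDT-matched
asymmetry, and mean natural-log response time per response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sdt_matched, type2roc
from .observer_sim import S1, S2

RT_MIN_MS = 250.0
RT_MAX_MS = 5000.0
FIRST_ANALYZED_BLOCK = 2
MIN_ACCURACY = 0.60
MAX_RT_VIOLATION_PROP = 0.25
MIN_ERRORS_PER_RESPONSE = 2

_REQUIRED = ["block", "response", "correct", "confidence", "rt_ms"]


@dataclass(frozen=True)
class ExclusionReport:
    participant_id: str
    excluded: bool
    reasons: frozenset = field(default_factory=frozenset)
    accuracy: float = float("nan")
    prop_rt_out_of_range: float = float("nan")
    n_errors_s1_response: int = 0
    n_errors_s2_response: int = 0

    def __post_init__(self) -> None:
        if self.excluded != bool(self.reasons):
            raise ValueError("excluded must hold exactly when reasons is non-empty")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["reasons"] = ";".join(sorted(self.reasons))
        return d


@dataclass(frozen=True)
class ParticipantSummary:
    """Per-participant dependent variables for the four hypotheses."""

    participant_id: str
    mean_conf_s1: float
    mean_conf_s2: float
    auroc_s1: float
    auroc_s2: float
    delta_auc: float
    matched_delta_auc: float
    asymmetry_beyond_sdt: float
    mean_log_rt_s1: float
    mean_log_rt_s2: float


def _check_columns(trials: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing required columns: {missing}")


def filter_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Keep analyzed trials: blocks 2+ with response time in [250 ms, 5 s]."""
    _check_columns(trials)
    keep = (
        (trials["block"] >= FIRST_ANALYZED_BLOCK)
        & (trials["rt_ms"] >= RT_MIN_MS)
        & (trials["rt_ms"] <= RT_MAX_MS)
    )
    return trials.loc[keep].copy()


def participant_exclusion(
    trials: pd.DataFrame, comprehension_pass: bool = True
) -> ExclusionReport:
    """Apply the pre-registered participant-level rejection rules.

    Accuracy and error counts use the analyzed (post-filter) trials, which are
    the ones feeding the ROC analysis; the response-time-violation proportion
    is computed over all trials as pre-registered.
    """
    _check_columns(trials)
    if len(trials) == 0:
        raise ValueError("participant has no trials")
    pid = str(trials["participant_id"].iloc[0]) if "participant_id" in trials else ""
    rt_out = (trials["rt_ms"] < RT_MIN_MS) | (trials["rt_ms"] > RT_MAX_MS)
    prop_rt_out = float(rt_out.mean())

    analyzed = filter_trials(trials)
    reasons = set()
    if len(analyzed) == 0:
        accuracy = float("nan")
        n_err_s1 = n_err_s2 = 0
        reasons.update({"low_accuracy", "too_few_errors"})
    else:
        accuracy = float(analyzed["correct"].mean())
        errors = analyzed.loc[~analyzed["correct"].astype(bool)]
        n_err_s1 = int((errors["response"] == S1).sum())
        n_err_s2 = int((errors["response"] == S2).sum())
        if accuracy < MIN_ACCURACY:
            reasons.add("low_accuracy")
        if min(n_err_s1, n_err_s2) < MIN_ERRORS_PER_RESPONSE:
            reasons.add("too_few_errors")
    if prop_rt_out > MAX_RT_VIOLATION_PROP:
        reasons.add("rt_violations")
    if not comprehension_pass:
        reasons.add("comprehension_fail")
    return ExclusionReport(
        participant_id=pid,
        excluded=bool(reasons),
        reasons=frozenset(reasons),
        accuracy=accuracy,
        prop_rt_out_of_range=prop_rt_out,
        n_errors_s1_response=n_err_s1,
        n_errors_s2_response=n_err_s2,
    )


def summarize_participant(trials: pd.DataFrame) -> ParticipantSummary:
    """Compute the dependent variables from one participant's analyzed trials.

    Expects the post-filter table of an included participant. Response times
    enter as natural logs of milliseconds.
    """
    _check_columns(trials)
    pid = str(trials["participant_id"].iloc[0]) if "participant_id" in trials else ""
    emp = type2roc.delta_auc(trials)
    fit = sdt_matched.estimate_sdt(trials)
    hat = sdt_matched.matched_delta_auc(trials, fit=fit)
    is_s1 = trials["response"] == S1
    conf = trials["confidence"]
    log_rt = np.log(trials["rt_ms"])
    return ParticipantSummary(
        participant_id=pid,
        mean_conf_s1=float(conf[is_s1].mean()),
        mean_conf_s2=float(conf[~is_s1].mean()),
        auroc_s1=emp.auroc_s1,
        auroc_s2=emp.auroc_s2,
        delta_auc=emp.delta,
        matched_delta_auc=hat.delta_hat,
        asymmetry_beyond_sdt=emp.delta - hat.delta_hat,
        mean_log_rt_s1=float(log_rt[is_s1].mean()),
        mean_log_rt_s2=float(log_rt[~is_s1].mean()),
    )


def process_cohort(
    trials: pd.DataFrame, comprehension: pd.Series | dict | None = None
):
    """Filter, exclude, and summarize every participant in a trial table.

    ``comprehension`` maps participant id to a boolean; when omitted, a
    ``comprehension_pass`` column is used if present, else all pass. Returns
    ``(exclusions, summaries)`` DataFrames, one row per participant
    (summaries only for included participants).
    """
    if "participant_id" not in trials.columns:
        raise ValueError("trial table is missing required columns: ['participant_id']")
    if comprehension is None and "comprehension_pass" in trials.columns:
        comprehension = (
            trials.groupby("participant_id")["comprehension_pass"].first().to_dict()
        )
    if comprehension is None:
        comprehension = {}
    comprehension = dict(comprehension)
    reports, summaries = [], []
    for pid, sub in trials.groupby("participant_id", sort=True):
        report = participant_exclusion(sub, bool(comprehension.get(pid, True)))
        reports.append(report.to_dict())
        if not report.excluded:
            summaries.append(summarize_participant(filter_trials(sub)).__dict__)
    exclusions_df = pd.DataFrame(reports)
    summaries_df = pd.DataFrame(
        summaries,
        columns=[f.name for f in ParticipantSummary.__dataclass_fields__.values()]
        if not summaries
        else None,
    )
    return exclusions_df, summaries_df


__all__ = [
    "RT_MIN_MS",
    "RT_MAX_MS",
    "ExclusionReport",
    "ParticipantSummary",
    "filter_trials",
    "participant_exclusion",
    "summarize_participant",
    "process_cohort",
]
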