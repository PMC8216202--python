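"""Response-conditional type-2 ROC curves and their areas.

A type-2 ROC relates confidence to accuracy: for trials sharing a given
response, it plots the empirical cumulative proportion of incorrect trials
with confidence at or above each threshold (x-axis) against the same
cumulative proportion for correct trials (y-axis). The area under the curve
(auROC) measures metacognitive sensitivity — how well confidence separates
correct from incorrect decisions. Computed separately for S1 and S2
responses, the difference between the two areas (``delta_auc``) quantifies
the metacognitive asymmetry between "feature present" and "feature absent"
decisions.

Thresholds are taken at the distinct observed confidence values so that tied
ratings move together; with trapezoidal integration the area then equals the
tie-corrected Mann-Whitney statistic, P(conf_correct > conf_incorrect) +
0.5 * P(tie). Areas are always computed from the raw, unbinned ratings; the
20-bin summary exists for visualization only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .observer_sim import S1, S2


@dataclass(frozen=True)
class ROCCurve:
    """An empirical response-conditional type-2 ROC curve."""

    far: np.ndarray
    hr: np.ndarray
    area: float
    response: str
    n_correct: int
    n_incorrect: int

    def __post_init__(self) -> None:
        if len(self.far) != len(self.hr):
            raise ValueError("far and hr must have equal length")


def _cumulative_at(thresholds: np.ndarray, values: np.ndarray) -> np.ndarray:
    """P(value >= t) for each threshold t (thresholds descending)."""
    sorted_vals = np.sort(values)
    n = len(values)
    return (n - np.searchsorted(sorted_vals, thresholds, side="left")) / n


def response_conditional_roc(
    conf_correct, conf_incorrect, response: str = S1
) -> ROCCurve:
    """Build the empirical type-2 ROC for one response from raw confidences.

    One curve point per distinct confidence value, in descending threshold
    order, anchored at (0, 0) and (1, 1); area by the trapezoidal rule.

    Raises ``ValueError`` when either class is empty — participants without
    errors for a response cannot contribute a curve and must be excluded
    upstream.
    """
    cc = np.asarray(conf_correct, dtype=float)
    ci = np.asarray(conf_incorrect, dtype=float)
    if cc.size == 0 or ci.size == 0:
        raise ValueError(
            "both correct and incorrect trials are required for a type-2 ROC; "
            "exclude participants without errors upstream"
        )
    thresholds = np.unique(np.concatenate([cc, ci]))[::-1]
    far = np.concatenate([[0.0], _cumulative_at(thresholds, ci)])
    hr = np.concatenate([[0.0], _cumulative_at(thresholds, cc)])
    area = float(np.trapezoid(hr, far))
    return ROCCurve(
        far=far,
        hr=hr,
        area=area,
        response=response,
        n_correct=cc.size,
        n_incorrect=ci.size,
    )


def auroc_mwu_oracle(conf_correct, conf_incorrect) -> float:
    """Brute-force Mann-Whitney area: concordant pairs plus half the ties.

    Independent of the curve construction; used to validate it.
    """
    cc = np.asarray(conf_correct, dtype=float)
    ci = np.asarray(conf_incorrect, dtype=float)
    if cc.size == 0 or ci.size == 0:
        raise ValueError("both classes must be non-empty")
    diff = cc[:, None] - ci[None, :]
    wins = np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0)
    return float(wins / (cc.size * ci.size))


class DeltaAUC(NamedTuple):
    auroc_s1: float
    auroc_s2: float
    delta: float


def split_confidences(trials: pd.DataFrame, response: str):
    """Confidence vectors (correct, incorrect) for one response."""
    sel = trials[trials["response"] == response]
    return (
        sel.loc[sel["correct"], "confidence"].to_numpy(),
        sel.loc[~sel["correct"].astype(bool), "confidence"].to_numpy(),
    )


def delta_auc(trials: pd.DataFrame) -> DeltaAUC:
    """Metacognitive asymmetry: auROC(S1 responses) - auROC(S2 responses)."""
    curves = {}
    for resp in (S1, S2):
        cc, ci = split_confidences(trials, resp)
        curves[resp] = response_conditional_roc(cc, ci, response=resp)
    return DeltaAUC(
        auroc_s1=curves[S1].area,
        auroc_s2=curves[S2].area,
        delta=curves[S1].area - curves[S2].area,
    )


def participant_roc_curves(trials: pd.DataFrame) -> pd.DataFrame:
    """Both empirical curves of one participant as a tidy frame
    (columns: response, far, hr)."""
    rows = []
    for resp in (S1, S2):
        cc, ci = split_confidences(trials, resp)
        curve = response_conditional_roc(cc, ci, response=resp)
        rows.append(
            pd.DataFrame({"response": resp, "far": curve.far, "hr": curve.hr})
        )
    return pd.concat(rows, ignore_index=True)


def bin_confidence(confidences, n_bins: int = 20):
    """Equal-width bins spanning the participant's dynamic range.

    For visualization only — never used in area computation. Returns
    ``(edges, counts)``. A degenerate range (all ratings identical) yields a
    single bin and a warning.
    """
    conf = np.asarray(confidences, dtype=float)
    if conf.size == 0:
        raise ValueError("confidences must be non-empty")
    lo, hi = float(conf.min()), float(conf.max())
    if lo == hi:
        warnings.warn(
            "all confidence ratings identical; returning a single degenerate bin",
            stacklevel=2,
        )
        return np.array([lo, hi]), np.array([conf.size])
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(conf, bins=edges)
    return edges, counts


__all__ = [
    "ROCCurve",
    "DeltaAUC",
    "response_conditional_roc",
    "auroc_mwu_oracle",
    "split_confidences",
    "delta_auc",
    "participant_roc_curves",
    "bin_confidence",
]
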