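"""Equal-variance SDT control for the metacognitive asymmetry.

A response bias (criterion away from the midpoint between the evidence
distributions) produces a difference between the two response-conditional
type-2 ROC areas even in an equal-variance observer with no genuine
metacognitive asymmetry. This module computes the asymmetry such an ideal
observer would show, matched to the participant's measured sensitivity,
response bias, and empirical distribution of confidence in incorrect
responses, so that the asymmetry *beyond* equal-variance SDT can be isolated.

Construction: fit equal-variance SDT to the choice data (d' and criterion
from hit and false-alarm rates). For each response, take the participant's
empirical cumulative error-confidence proportions as x-values and map each
through the model's type-2 hit-rate function — the cumulative proportion of
correct trials an equal-variance observer would place above the same type-2
criterion. The area under that curve is the model-expected auROC for the
response; the S1 - S2 difference is the model-expected asymmetry.

For an equal-variance observer, confidence is any monotone function of the
distance between the decision variable and the criterion, so type-2 criteria
map one-to-one onto evidence-axis cutoffs and all tail probabilities are
normal integrals with closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .observer_sim import S1, S2
from .type2roc import delta_auc as _empirical_delta_auc
from .type2roc import split_confidences


@dataclass(frozen=True)
class SDTFit:
    """Equal-variance SDT parameters estimated from one participant's choices.

    ``criterion_c`` follows the standard convention, measured from the
    midpoint of the two evidence distributions: ``c = -(z(HR) + z(FAR)) / 2``.
    The absolute cutoff on the evidence axis (S2 distribution centred at 0)
    is ``criterion_abs = criterion_c + dprime / 2``.
    """

    dprime: float
    criterion_c: float
    hr: float
    far: float
    n_s1: int
    n_s2: int

    @property
    def criterion_abs(self) -> float:
        return self.criterion_c + self.dprime / 2.0


def _correct_rate(k: int, n: int, method: str) -> float:
    """Proportion k/n with an extreme-rate correction keeping it in (0, 1)."""
    if method == "extreme":
        p = k / n
        lo = 1.0 / (2 * n)
        return min(max(p, lo), 1.0 - lo)
    if method == "loglinear":
        return (k + 0.5) / (n + 1.0)
    raise ValueError(f"unknown correction {method!r}")


def estimate_sdt(trials: pd.DataFrame, correction: str = "extreme") -> SDTFit:
    """Fit equal-variance SDT to one participant's stimulus/response table.

    ``correction`` handles hit or false-alarm rates of exactly 0 or 1:
    ``"extreme"`` replaces them by 1/(2N) and 1 - 1/(2N); ``"loglinear"``
    adds 0.5 to each count and 1 to each denominator.
    """
    is_s1 = trials["stimulus"] == S1
    n_s1 = int(is_s1.sum())
    n_s2 = int((~is_s1).sum())
    if n_s1 == 0 or n_s2 == 0:
        raise ValueError("both stimulus classes must be present to fit SDT")
    resp_s1 = trials["response"] == S1
    hits = int((resp_s1 & is_s1).sum())
    fas = int((resp_s1 & ~is_s1).sum())
    hr = _correct_rate(hits, n_s1, correction)
    far = _correct_rate(fas, n_s2, correction)
    z_hr, z_far = ndtri(hr), ndtri(far)
    return SDTFit(
        dprime=float(z_hr - z_far),
        criterion_c=float(-0.5 * (z_hr + z_far)),
        hr=hr,
        far=far,
        n_s1=n_s1,
        n_s2=n_s2,
    )


def expected_type2_hr(p_far, response: str, fit: SDTFit):
    """Model type-2 hit rate at given type-2 false-alarm proportions.

    For S1 responses (evidence above the absolute criterion ``c``): solve for
    the evidence cutoff ``theta >= c`` with
    ``P(x > theta | S2) / P(x > c | S2) = p_far`` and return
    ``P(x > theta | S1) / P(x > c | S1)``, with S1 evidence ~ Normal(d', 1)
    and S2 evidence ~ Normal(0, 1). For S2 responses the construction is
    mirrored below the criterion with the stimulus roles swapped. Both steps
    are closed-form normal quantile/CDF evaluations. Maps 0 to 0 and 1 to 1
    and is monotone non-decreasing in ``p_far``.
    """
    p = np.asarray(p_far, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_far must lie in [0, 1]")
    d, c = fit.dprime, fit.criterion_abs
    if response == S1:
        # incorrect = S2 stimuli above c; correct = S1 stimuli above c
        theta = ndtri(1.0 - p * (1.0 - ndtr(c)))
        hr = (1.0 - ndtr(theta - d)) / (1.0 - ndtr(c - d))
    elif response == S2:
        # incorrect = S1 stimuli below c; correct = S2 stimuli below c
        theta = d + ndtri(p * ndtr(c - d))
        hr = ndtr(theta) / ndtr(c)
    else:
        raise ValueError(f"response must be {S1!r} or {S2!r}")
    hr = np.clip(hr, 0.0, 1.0)
    return float(hr) if np.isscalar(p_far) else hr


def expected_roc_curve(fit: SDTFit, response: str, conf_incorrect) -> "ModelCurve":
    """Model curve anchored to the empirical error-confidence distribution.

    x-values are the participant's cumulative error-confidence proportions
    (one per distinct rating, plus the (0, 0) anchor); y-values come from
    ``expected_type2_hr``.
    """
    ci = np.asarray(conf_incorrect, dtype=float)
    if ci.size == 0:
        raise ValueError("conf_incorrect must be non-empty")
    thresholds = np.unique(ci)[::-1]
    n = ci.size
    far = np.concatenate(
        [[0.0], (n - np.searchsorted(np.sort(ci), thresholds, side="left")) / n]
    )
    hr = expected_type2_hr(far, response, fit)
    area = float(np.trapezoid(hr, far))
    return ModelCurve(far=far, hr=hr, area=area, response=response)


@dataclass(frozen=True)
class ModelCurve:
    far: np.ndarray
    hr: np.ndarray
    area: float
    response: str


class MatchedDeltaAUC(NamedTuple):
    auroc_hat_s1: float
    auroc_hat_s2: float
    delta_hat: float


def matched_delta_auc(
    trials: pd.DataFrame, fit: SDTFit | None = None, correction: str = "extreme"
) -> MatchedDeltaAUC:
    """Asymmetry expected from the matched equal-variance SDT observer."""
    fit = fit or estimate_sdt(trials, correction=correction)
    areas = {}
    for resp in (S1, S2):
        _, ci = split_confidences(trials, resp)
        areas[resp] = expected_roc_curve(fit, resp, ci).area
    return MatchedDeltaAUC(
        auroc_hat_s1=areas[S1],
        auroc_hat_s2=areas[S2],
        delta_hat=areas[S1] - areas[S2],
    )


def asymmetry_beyond_sdt(trials: pd.DataFrame, correction: str = "extreme") -> float:
    """Empirical minus model-expected asymmetry: the H3 summary statistic."""
    emp = _empirical_delta_auc(trials)
    hat = matched_delta_auc(trials, correction=correction)
    return emp.delta - hat.delta_hat


__all__ = [
    "SDTFit",
    "ModelCurve",
    "MatchedDeltaAUC",
    "estimate_sdt",
    "expected_type2_hr",
    "expected_roc_curve",
    "matched_delta_auc",
    "asymmetry_beyond_sdt",
]
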