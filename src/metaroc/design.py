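"""Design analysis: frequentist power and Bayes-factor outcome simulation.

``power_one_tailed`` gives the exact noncentral-t power of the one-tailed
one-sample t-test at the planned sample size. ``bf_outcome_simulation``
estimates, by Monte Carlo, how often the JZS Bayes factor supports the null
or the alternative at the planned n — once under a true null and once with
the true standardized effect drawn from the same Cauchy distribution used as
the analysis prior.

The simulation follows the Schonbrodt-style Bayes-factor design analysis in
its two-sample form (two groups of ``n`` observations, pooled-variance t,
effective sample size n/2, 2n - 2 degrees of freedom) with the symmetric
two-sided JZS prior; a paired/one-sample mode is available via ``design``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .inference import DEFAULT_RSCALE, jzs_bf_batch


def power_one_tailed(n: int, d: float, alpha: float = 0.05) -> float:
    """Power of the one-tailed one-sample t-test.

    Exact: P(T > t_crit) with T noncentral t, df = n - 1, noncentrality
    d * sqrt(n), and t_crit the upper-alpha central-t quantile.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if d < 0:
        raise ValueError("d must be non-negative")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    t_crit = stats.t.ppf(1.0 - alpha, n - 1)
    return float(stats.nct.sf(t_crit, n - 1, d * np.sqrt(n)))


@dataclass(frozen=True)
class DesignResult:
    """Bayes-factor outcome proportions from one simulation run."""

    n_per_cohort: int
    rscale: float
    n_reps: int
    truth: str
    design: str
    pct_support_null: float
    pct_bf01_gt3: float
    pct_support_alt: float
    pct_bf10_gt3: float
    mc_se: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _simulate_t_values(
    n: int, effects: np.ndarray, design: str, rng: np.random.Generator
) -> tuple[np.ndarray, float, float]:
    """Draw one t statistic per repetition; returns (t, n_eff, df)."""
    n_reps = effects.size
    if design == "two_sample":
        g1 = rng.standard_normal((n_reps, n)) + effects[:, None]
        g2 = rng.standard_normal((n_reps, n))
        pooled = np.sqrt((g1.var(axis=1, ddof=1) + g2.var(axis=1, ddof=1)) / 2.0)
        t = (g1.mean(axis=1) - g2.mean(axis=1)) / (pooled * np.sqrt(2.0 / n))
        return t, n / 2.0, 2 * n - 2
    if design == "paired":
        x = rng.standard_normal((n_reps, n)) + effects[:, None]
        t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / np.sqrt(n))
        return t, float(n), n - 1
    raise ValueError("design must be 'two_sample' or 'paired'")


def bf_outcome_simulation(
    n: int = 106,
    rscale: float = DEFAULT_RSCALE,
    truth: str = "null",
    n_reps: int = 10_000,
    seed: int | None = None,
    design: str = "two_sample",
    alternative: str = "two_sided",
    rscale_truth: float | None = None,
) -> DesignResult:
    """Monte-Carlo distribution of JZS Bayes-factor outcomes at the planned n.

    Per repetition: draw the true standardized effect (0 under
    ``truth='null'``, or Cauchy(0, ``rscale_truth``) under ``truth='cauchy'``,
    defaulting to the analysis prior scale), simulate the raw data, compute
    the t statistic and the JZS Bayes factor, and tally how often BF01 > 1,
    BF01 > 3, BF10 > 1, and BF10 > 3. ``mc_se`` is the worst-case binomial
    Monte-Carlo standard error of the reported percentages.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    if truth not in ("null", "cauchy"):
        raise ValueError("truth must be 'null' or 'cauchy'")
    rng = np.random.default_rng(seed)
    if truth == "null":
        effects = np.zeros(n_reps)
    else:
        scale = rscale if rscale_truth is None else rscale_truth
        effects = scale * rng.standard_cauchy(n_reps)
    t, n_eff, df = _simulate_t_values(n, effects, design, rng)
    bf10 = jzs_bf_batch(t, n_eff=n_eff, df=df, rscale=rscale, alternative=alternative)
    return DesignResult(
        n_per_cohort=n,
        rscale=rscale,
        n_reps=n_reps,
        truth=truth,
        design=design,
        pct_support_null=100.0 * float(np.mean(bf10 < 1.0)),
        pct_bf01_gt3=100.0 * float(np.mean(bf10 < 1.0 / 3.0)),
        pct_support_alt=100.0 * float(np.mean(bf10 > 1.0)),
        pct_bf10_gt3=100.0 * float(np.mean(bf10 > 3.0)),
        mc_se=100.0 * float(np.sqrt(0.25 / n_reps)),
    )


__all__ = ["DesignResult", "power_one_tailed", "bf_outcome_simulation"]
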