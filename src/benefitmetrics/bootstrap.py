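"""Bootstrap confidence intervals for the matched-pair metrics.

The resampling unit is the matched pair: each resample draws ``n_p`` pairs
with replacement from the cohort and reruns the full metric pipeline,
including re-fitting the smoother.  Matching itself is *not* redone —
observed pairwise effects are a property of the fixed pairing.  Intervals are
percentile intervals; resamples on which a metric is undefined (e.g. no
informative comparisons for C-for-benefit) are dropped for that metric and
counted in the report.
"""

from __future__ import annotations

import numpy as np

from .cohort import DataError, MatchedCohort, MetricReport
from .metrics import EPSILON, evaluate_arrays
from .smoothing import SmootherSettings

__all__ = ["bootstrap_metrics"]


def bootstrap_metrics(cohort: MatchedCohort,
                      B: int = 100,
                      level: float = 0.95,
                      seed: int | None = None,
                      smoother: SmootherSettings | None = None,
                      epsilon: float = EPSILON) -> MetricReport:
    """Point estimates plus percentile bootstrap intervals for every metric.

    Parameters
    ----------
    B : int
        Number of pair-level resamples (default 100).
    level : float
        Nominal two-sided coverage of the percentile interval.
    seed : int, optional
        Seed of the resampling generator; a fixed seed makes the intervals
        reproducible.
    """
    if cohort.n_p < 2:
        raise DataError("bootstrap needs at least two matched pairs")
    if B < 2:
        raise ValueError("B must be at least 2")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")

    smoother = smoother or SmootherSettings()
    point = evaluate_arrays(cohort.J, cohort.K, cohort.L, cohort.M,
                            smoother=smoother, epsilon=epsilon)

    rng = np.random.default_rng(seed)
    n = cohort.n_p
    J, K, L, M = cohort.J, cohort.K, cohort.L, cohort.M
    draws: dict[str, list[float]] = {name: [] for name in point.metrics}
    dropped = {name: 0 for name in point.metrics}
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        rep = evaluate_arrays(J[idx], K[idx], L[idx], M[idx],
                              smoother=smoother, epsilon=epsilon)
        for name, value in rep.metrics.items():
            if value is None or (isinstance(value, float) and np.isnan(value)):
                dropped[name] += 1
            else:
                draws[name].append(value)

    alpha = 1.0 - level
    intervals = {}
    for name, values in draws.items():
        if not values:
            continue  # interval unavailable: every resample was undefined
        lo, hi = np.quantile(values, [alpha / 2.0, 1.0 - alpha / 2.0])
        intervals[name] = (float(lo), float(hi), level)

    point.intervals = intervals
    point.dropped = {k: v for k, v in dropped.items() if v}
    point.provenance.update({"bootstrap": {"B": B, "level": level, "seed": seed,
                                           "unit": "matched pair"}})
    return point
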