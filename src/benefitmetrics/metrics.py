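"""Performance metrics for treatment-effect predictions on a matched cohort.

Calibration
    * calibration-in-the-large: agreement of the average observed and average
      predicted pairwise treatment effect.  The signed form ``mean(M) -
      mean(L)`` is positive when treatment effect is underestimated; the
      absolute smoothed form ``|mean(M) - mean(N)|`` compares against the
      loess-smoothed observed effects.
    * E-for-benefit statistics: the mean / median / 90th-percentile absolute
      vertical distance ``|L - N|`` between the smoothed calibration curve and
      the diagonal of perfect calibration.

Discrimination
    * C-for-benefit: among pairs-of-matched-pairs with unequal observed
      effect, the fraction in which the pair with the larger observed effect
      also has the larger predicted effect.

Overall performance
    * cross-entropy-for-benefit and Brier-for-benefit: three-class log-loss
      and (half-)squared error of the per-pair predicted (benefit, no-effect,
      harm) probabilities against the observed class.

Every public function accepts a :class:`~benefitmetrics.cohort.MatchedCohort`;
array-level variants (``*_arrays``) operate directly on the ``J, K, L, M``
vectors and are what the simulation harness uses at super-population scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .cohort import (BenefitProbabilities, DataError, MatchedCohort,
                     MatchedPair, MetricReport)
from .smoothing import SmootherSettings, local_regression

__all__ = [
    "EStatistics",
    "QuantileGroupSummary",
    "calibration_in_the_large",
    "e_for_benefit",
    "c_for_benefit",
    "c_for_benefit_arrays",
    "benefit_probabilities",
    "benefit_probability_arrays",
    "cross_entropy_for_benefit",
    "cross_entropy_arrays",
    "brier_for_benefit",
    "brier_arrays",
    "quantile_groups",
    "evaluate",
    "evaluate_arrays",
]

EPSILON = 1e-15  # floor for class probabilities before taking logs


class EStatistics(NamedTuple):
    e_avg: float
    e50: float
    e90: float


@dataclass(frozen=True)
class QuantileGroupSummary:
    """One quantile group of pairs sorted by predicted pairwise effect."""

    group: int
    mean_predicted: float
    mean_observed: float
    size: int


def _require_nonempty(n: int) -> None:
    if n == 0:
        raise DataError("metric is undefined on an empty cohort")


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibration_in_the_large(cohort: MatchedCohort, N=None,
                             variant: str = "raw") -> float:
    """Mean calibration of the pairwise treatment-effect predictions.

    ``variant="raw"`` returns the signed ``mean(M) - mean(L)`` (positive =
    underestimated treatment effect); ``variant="smoothed"`` returns
    ``|mean(M) - mean(N)|`` against the smoothed observed effects ``N``.
    """
    _require_nonempty(cohort.n_p)
    if variant == "raw":
        return float(cohort.M.mean() - cohort.L.mean())
    if variant == "smoothed":
        if N is None:
            raise ValueError("variant='smoothed' requires the smoothed vector N")
        N = np.asarray(N, dtype=float)
        return float(abs(cohort.M.mean() - N.mean()))
    raise ValueError(f"variant must be 'raw' or 'smoothed', got {variant!r}")


def _quantile_type7(sorted_values: np.ndarray, p: float) -> float:
    """Sample quantile with the linear-interpolation convention h=(n-1)p+1."""
    n = sorted_values.size
    h = (n - 1) * p + 1
    lo = int(np.floor(h)) - 1
    frac = h - np.floor(h)
    if lo + 1 >= n:
        return float(sorted_values[-1])
    return float(sorted_values[lo] + frac * (sorted_values[lo + 1] - sorted_values[lo]))


def e_for_benefit(L, N) -> EStatistics:
    """(E_avg, E_50, E_90)-for-benefit: mean, median and 0.9 quantile of |L - N|."""
    L = np.asarray(L, dtype=float)
    N = np.asarray(N, dtype=float)
    if L.shape != N.shape:
        raise ValueError(f"L and N must have equal length, got {L.size} and {N.size}")
    _require_nonempty(L.size)
    a = np.sort(np.abs(L - N))
    return EStatistics(e_avg=float(a.mean()),
                       e50=_quantile_type7(a, 0.5),
                       e90=_quantile_type7(a, 0.9))


# ---------------------------------------------------------------------------
# Discrimination
# ---------------------------------------------------------------------------

def c_for_benefit_arrays(L, M) -> float | None:
    """C-for-benefit from the ``L`` and ``M`` vectors; ``None`` when undefined.

    Counts, over all unordered pairs of matched pairs with unequal observed
    effect, how often the pair with the larger ``M`` also has the larger
    ``L``.  Predicted-value ties (equal ``L``, unequal ``M``) are excluded
    from both numerator and denominator.  Runs in ``O(n log n)`` by sorting
    the three observed-effect classes.
    """
    L = np.asarray(L, dtype=float)
    M = np.asarray(M)
    if L.size != M.size:
        raise ValueError("L and M must have equal length")
    if L.size < 2:
        raise DataError("C-for-benefit needs at least two matched pairs")
    by_class = {m: np.sort(L[M == m]) for m in (-1, 0, 1)}
    concordant = 0
    discordant = 0
    for m_low, m_high in ((-1, 0), (-1, 1), (0, 1)):
        low, high = by_class[m_low], by_class[m_high]
        if low.size == 0 or high.size == 0:
            continue
        below = np.searchsorted(low, high, side="left")    # low-L strictly smaller
        at_most = np.searchsorted(low, high, side="right")
        concordant += int(below.sum())
        discordant += int((low.size - at_most).sum())
    denom = concordant + discordant
    if denom == 0:
        return None
    return concordant / denom


def c_for_benefit(cohort: MatchedCohort) -> float | None:
    """C-for-benefit of a matched cohort; ``None`` if no informative comparison."""
    return c_for_benefit_arrays(cohort.L, cohort.M)


# ---------------------------------------------------------------------------
# Overall performance
# ---------------------------------------------------------------------------

def benefit_probability_arrays(J, K) -> np.ndarray:
    """(n, 3) array of (benefit, no-effect, harm) probabilities from J and K."""
    J = np.asarray(J, dtype=float)
    K = np.asarray(K, dtype=float)
    p_benefit = (1.0 - K) * J
    p_harm = K * (1.0 - J)
    p_none = (1.0 - K) * (1.0 - J) + K * J
    return np.column_stack([p_benefit, p_none, p_harm])


def benefit_probabilities(pair: MatchedPair) -> BenefitProbabilities:
    """Predicted class probabilities for one matched pair.

    Treating the two patients' outcomes as independent Bernoulli draws with
    success probabilities ``J`` (untreated) and ``K`` (treated):
    ``p_benefit = (1-K)J``, ``p_harm = K(1-J)``, and ``p_none`` the rest.
    """
    row = benefit_probability_arrays([pair.J], [pair.K])[0]
    return BenefitProbabilities(p_benefit=float(row[0]), p_none=float(row[1]),
                                p_harm=float(row[2]))


def _observed_class_index(M: np.ndarray) -> np.ndarray:
    # column order of benefit_probability_arrays: benefit, none, harm
    return np.select([M == 1, M == 0, M == -1], [0, 1, 2])


def cross_entropy_arrays(J, K, M, epsilon: float = EPSILON) -> float:
    M = np.asarray(M)
    _require_nonempty(M.size)
    P = benefit_probability_arrays(J, K)
    observed = P[np.arange(M.size), _observed_class_index(M)]
    return float(-np.log(np.clip(observed, epsilon, 1.0)).mean())


def cross_entropy_for_benefit(cohort: MatchedCohort,
                              epsilon: float = EPSILON) -> float:
    """Three-class log-loss (natural log) of the pair-level class probabilities.

    Probabilities are clipped to ``[epsilon, 1]`` before the log so that
    degenerate predictions (``p0`` or ``p1`` exactly 0 or 1) stay finite.
    """
    return cross_entropy_arrays(cohort.J, cohort.K, cohort.M, epsilon=epsilon)


def brier_arrays(J, K, M) -> float:
    M = np.asarray(M)
    _require_nonempty(M.size)
    P = benefit_probability_arrays(J, K)
    onehot = np.zeros_like(P)
    onehot[np.arange(M.size), _observed_class_index(M)] = 1.0
    return float(((P - onehot) ** 2).sum() / (2 * M.size))


def brier_for_benefit(cohort: MatchedCohort) -> float:
    """Three-class Brier score with normalizer ``1/(2 n_p)``; bounded in [0, 1]."""
    return brier_arrays(cohort.J, cohort.K, cohort.M)


# ---------------------------------------------------------------------------
# Calibration-plot groupings and the one-call façade
# ---------------------------------------------------------------------------

def quantile_groups(cohort: MatchedCohort, n_groups: int = 4) -> list[QuantileGroupSummary]:
    """Near-equal groups of pairs by predicted pairwise effect.

    Each group's mean observed effect is its nonparametric treatment-effect
    estimate — the black dots of a treatment-effect calibration plot.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if cohort.n_p < n_groups:
        raise DataError(f"cannot form {n_groups} groups from {cohort.n_p} pairs")
    order = np.argsort(cohort.L, kind="stable")
    summaries = []
    for g, idx in enumerate(np.array_split(order, n_groups)):
        summaries.append(QuantileGroupSummary(
            group=g,
            mean_predicted=float(cohort.L[idx].mean()),
            mean_observed=float(cohort.M[idx].mean()),
            size=int(idx.size),
        ))
    return summaries


def evaluate_arrays(J, K, L, M,
                    smoother: SmootherSettings | None = None,
                    smoothed=None,
                    epsilon: float = EPSILON) -> MetricReport:
    """Full metric suite from the raw pair vectors.

    ``smoothed`` injects a precomputed smoothed vector ``N`` (bypassing the
    loess fit) — used to reproduce published worked examples and to let tests
    substitute a reference smoother.
    """
    J = np.asarray(J, dtype=float)
    K = np.asarray(K, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M)
    _require_nonempty(M.size)
    smoother = smoother or SmootherSettings()
    if smoothed is None:
        if np.all(L == L[0]):
            # degenerate cohort (all predictions equal): the local fit
            # collapses to the intercept-only estimate mean(M)
            N = np.full(L.shape, float(np.mean(M)))
        else:
            # tiny cohorts cannot support the configured local degree;
            # fall back to the highest degree the sample size allows
            degree = min(smoother.degree, M.size - 2)
            local = smoother if degree == smoother.degree else SmootherSettings(
                span=smoother.span, degree=max(degree, 0), kernel=smoother.kernel)
            N = local_regression(L, M.astype(float), local)
        smoother_note = {"span": smoother.span, "degree": smoother.degree,
                         "kernel": smoother.kernel, "injected_smoothed": False}
    else:
        N = np.asarray(smoothed, dtype=float)
        if N.shape != L.shape:
            raise ValueError("injected smoothed vector must match L in length")
        smoother_note = {"injected_smoothed": True}

    e_stats = e_for_benefit(L, N)
    if M.size >= 2:
        c_stat = c_for_benefit_arrays(L, M)
    else:
        c_stat = None
    report = MetricReport(
        metrics={
            "citl": float(np.mean(M) - np.mean(L)),
            "citl_abs_smoothed": float(abs(np.mean(M) - np.mean(N))),
            "e_avg": e_stats.e_avg,
            "e50": e_stats.e50,
            "e90": e_stats.e90,
            "c_for_benefit": c_stat,
            "cross_entropy": cross_entropy_arrays(J, K, M, epsilon=epsilon),
            "brier": brier_arrays(J, K, M),
        },
        provenance={"n_pairs": int(M.size), "smoother": smoother_note,
                    "epsilon": epsilon},
    )
    report.smoothed = N
    return report


def evaluate(cohort: MatchedCohort,
             smoother: SmootherSettings | None = None,
             smoothed=None,
             epsilon: float = EPSILON) -> MetricReport:
    """All metrics of a matched cohort in one call.

    Smoothing is run once and shared by every calibration statistic; the
    fitted values are attached to the returned report as ``report.smoothed``.
    """
    return evaluate_arrays(cohort.J, cohort.K, cohort.L, cohort.M,
                           smoother=smoother, smoothed=smoothed, epsilon=epsilon)
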