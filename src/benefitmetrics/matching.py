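"""Greedy nearest-neighbor matching of the two trial arms.

Each patient in the smaller arm (the untreated arm in a balanced trial) is
paired with the nearest patient of the other arm by Mahalanobis distance on
the baseline covariates, by default without replacement.  Matching on
covariates — rather than on predicted effect — keeps the observed pairwise
treatment effects identical across candidate models, so their metrics are
directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .cohort import (ConfigurationError, DataError, MatchedCohort,
                     PatientRecord, make_pair)

__all__ = ["MatchSettings", "covariance_inverse", "mahalanobis", "match_cohort"]


@dataclass(frozen=True)
class MatchSettings:
    """Options for :func:`match_cohort`.

    replace
        Reuse partners (``True``) or pair each at most once (``False``,
        default).  Matching with replacement suits unbalanced arms.
    order
        Processing order of the to-be-matched arm: ``"input"`` (default) or
        ``"random"`` (requires ``seed``).
    covariance_scope
        Covariance matrix of the Mahalanobis metric; ``"pooled"`` estimates
        it from the covariates of all patients in both arms.
    """

    replace: bool = False
    order: str = "input"
    seed: int | None = None
    covariance_scope: str = "pooled"

    def __post_init__(self):
        if self.order not in ("input", "random"):
            raise ConfigurationError(f"order must be 'input' or 'random', got {self.order!r}")
        if self.order == "random" and self.seed is None:
            raise ConfigurationError("order='random' requires a seed")
        if self.covariance_scope != "pooled":
            raise ConfigurationError("only covariance_scope='pooled' is supported")


def _covariate_matrix(records: Sequence[PatientRecord]) -> np.ndarray:
    X = np.vstack([r.covariates for r in records])
    if X.shape[1] == 0:
        raise ConfigurationError("matching requires at least one covariate")
    return X


def covariance_inverse(records: Sequence[PatientRecord]) -> np.ndarray:
    """Inverse of the pooled sample covariance (denominator ``n-1``).

    Falls back to the Moore–Penrose pseudo-inverse, with a warning, when the
    covariance matrix is singular (e.g. collinear covariates).
    """
    if len(records) < 2:
        raise DataError("need at least two patients to estimate a covariance")
    X = _covariate_matrix(records)
    cov = np.atleast_2d(np.cov(X, rowvar=False, ddof=1))
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        warnings.warn("covariate covariance is singular; using the Moore-Penrose "
                      "pseudo-inverse for Mahalanobis distances", RuntimeWarning,
                      stacklevel=2)
        inv = np.linalg.pinv(cov)
    # symmetrize against round-off
    return (inv + inv.T) / 2.0


def mahalanobis(x_i, x_j, cov_inv: np.ndarray) -> float:
    """sqrt((x_i - x_j)' cov_inv (x_i - x_j)); symmetric and nonnegative."""
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    cov_inv = np.asarray(cov_inv)
    if x_i.shape != x_j.shape or x_i.shape[0] != cov_inv.shape[0]:
        raise ValueError(f"dimension mismatch: vectors {x_i.shape} and {x_j.shape}, "
                         f"matrix {cov_inv.shape}")
    d = x_i - x_j
    q = float(d @ cov_inv @ d)
    return float(np.sqrt(max(q, 0.0)))


def match_cohort(records: Sequence[PatientRecord],
                 settings: MatchSettings | None = None) -> MatchedCohort:
    """Pair the two arms greedily by nearest Mahalanobis distance.

    Without replacement (default) each partner is used at most once and the
    smaller arm drives the matching, so ``n_p = min(#treated, #untreated)``;
    with replacement every untreated patient is matched to its nearest
    treated patient and ``n_p = #untreated``.  Ties are broken by the lowest
    candidate index; the result is deterministic given the record order and
    settings.
    """
    settings = settings or MatchSettings()
    records = list(records)
    treated_idx = [i for i, r in enumerate(records) if r.treatment == 1]
    untreated_idx = [i for i, r in enumerate(records) if r.treatment == 0]
    if not treated_idx or not untreated_idx:
        raise DataError("both arms must be non-empty for matching")

    cov_inv = covariance_inverse(records)
    X = _covariate_matrix(records)

    if settings.replace:
        source_idx, target_idx = untreated_idx, treated_idx
        source_is_untreated = True
    else:
        # the smaller arm drives matching so every one of its patients pairs
        if len(untreated_idx) <= len(treated_idx):
            source_idx, target_idx = untreated_idx, treated_idx
            source_is_untreated = True
        else:
            source_idx, target_idx = treated_idx, untreated_idx
            source_is_untreated = False

    order = np.arange(len(source_idx))
    if settings.order == "random":
        order = np.random.default_rng(settings.seed).permutation(len(source_idx))

    D = cdist(X[source_idx], X[target_idx], metric="mahalanobis", VI=cov_inv)
    available = np.ones(len(target_idx), dtype=bool)

    pairs_with_pos = []
    for pos in order:
        row = D[pos]
        if settings.replace:
            j = int(np.argmin(row))
        else:
            masked = np.where(available, row, np.inf)
            j = int(np.argmin(masked))
            available[j] = False
        dist = float(row[j])
        src = records[source_idx[pos]]
        tgt = records[target_idx[j]]
        if source_is_untreated:
            pair = make_pair(treated=tgt, untreated=src, distance=dist)
        else:
            pair = make_pair(treated=src, untreated=tgt, distance=dist)
        pairs_with_pos.append((pos, pair))

    # pairs reported in the source arm's input order regardless of processing order
    pairs_with_pos.sort(key=lambda t: t[0])
    return MatchedCohort([p for _, p in pairs_with_pos])
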