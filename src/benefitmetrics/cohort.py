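"""Domain types for matched-pair evaluation of treatment-effect predictions.

The unit of analysis is a pair of one treated and one untreated trial
participant with similar baseline covariates.  For each pair the package
derives

* ``L`` — the *predicted pairwise treatment effect*: the untreated patient's
  predicted event risk under control minus the treated patient's predicted
  event risk under treatment, ``L = J - K`` with ``J = untreated.p0`` and
  ``K = treated.p1``;
* ``M`` — the *observed pairwise treatment effect*: ``+1`` (benefit) when the
  untreated patient had the event and the treated patient did not, ``-1``
  (harm) in the opposite case, and ``0`` (no effect) when the two outcomes
  agree.  The event is assumed unfavorable, so benefit means treatment
  prevented it.

All performance metrics operate on an ordered :class:`MatchedCohort` of such
pairs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "MatchedPair",
    "MatchedCohort",
    "BenefitProbabilities",
    "MetricReport",
    "DataError",
    "ConfigurationError",
    "load_cohort",
    "write_cohort",
    "make_pair",
    "observed_pairwise_effect",
    "table1_fixture",
]


class DataError(ValueError):
    """Raised when input data violates a contract (bad arm codes, empty arms…)."""


class ConfigurationError(ValueError):
    """Raised when settings or column mappings are invalid."""


def _check_prob(value: float, name: str) -> float:
    v = float(value)
    if not (0.0 <= v <= 1.0) or math.isnan(v):
        raise DataError(f"{name} must lie in [0, 1], got {value!r}")
    return v


def _check_binary(value, name: str) -> int:
    v = float(value)
    if v not in (0.0, 1.0):
        raise DataError(f"{name} must be 0 or 1, got {value!r}")
    return int(v)


@dataclass(frozen=True)
class PatientRecord:
    """One trial participant.

    Parameters
    ----------
    id : hashable
        Opaque identifier, unique within a cohort.
    treatment : int
        Arm indicator ``W``: 1 treated, 0 control.
    outcome : int
        Binary event indicator ``Y``; the event is the *unfavorable* outcome.
    covariates : ndarray
        Baseline covariate vector ``X`` (categoricals pre-encoded as numbers).
    p0, p1 : float
        Model-predicted event probabilities under control (``W=0``) and under
        treatment (``W=1``) respectively.
    """

    id: object
    treatment: int
    outcome: int
    covariates: np.ndarray
    p0: float
    p1: float

    def __post_init__(self):
        object.__setattr__(self, "treatment", _check_binary(self.treatment, "treatment"))
        object.__setattr__(self, "outcome", _check_binary(self.outcome, "outcome"))
        object.__setattr__(self, "p0", _check_prob(self.p0, "p0"))
        object.__setattr__(self, "p1", _check_prob(self.p1, "p1"))
        cov = np.asarray(self.covariates, dtype=float).ravel()
        if np.isnan(cov).any():
            raise DataError(
                f"patient {self.id!r} has missing covariate values; "
                "impute upstream (no imputation is performed here)"
            )
        object.__setattr__(self, "covariates", cov)


def observed_pairwise_effect(treated_outcome: int, untreated_outcome: int) -> int:
    """Observed pairwise treatment effect ``M`` from the two binary outcomes.

    ``+1`` (benefit) iff the untreated patient had the event and the treated
    patient did not; ``-1`` (harm) in the mirrored case; ``0`` otherwise.
    """
    if untreated_outcome == 1 and treated_outcome == 0:
        return 1
    if untreated_outcome == 0 and treated_outcome == 1:
        return -1
    return 0


@dataclass(frozen=True)
class MatchedPair:
    """One treated + one untreated patient with the derived pair quantities.

    ``m`` may be supplied explicitly (e.g. when reconstructing pairs whose
    outcomes are not carried along); :func:`make_pair` derives it from the two
    observed outcomes.
    """

    treated: PatientRecord
    untreated: PatientRecord
    distance: float
    m: int

    def __post_init__(self):
        if self.treated.treatment != 1:
            raise DataError("MatchedPair.treated must have treatment == 1")
        if self.untreated.treatment != 0:
            raise DataError("MatchedPair.untreated must have treatment == 0")
        if self.distance < 0 or math.isnan(self.distance):
            raise DataError("matching distance must be nonnegative")
        if self.m not in (-1, 0, 1):
            raise DataError(f"observed pairwise effect must be -1, 0 or 1, got {self.m!r}")

    @property
    def J(self) -> float:
        """Untreated patient's predicted risk under control."""
        return self.untreated.p0

    @property
    def K(self) -> float:
        """Treated patient's predicted risk under treatment."""
        return self.treated.p1

    @property
    def L(self) -> float:
        """Predicted pairwise treatment effect, ``J - K`` ∈ [-1, 1]."""
        return self.untreated.p0 - self.treated.p1

    @property
    def M(self) -> int:
        """Observed pairwise treatment effect ∈ {-1, 0, 1}."""
        return self.m


def make_pair(treated: PatientRecord, untreated: PatientRecord,
              distance: float = 0.0) -> MatchedPair:
    """Build a :class:`MatchedPair`, deriving ``M`` from the observed outcomes."""
    if treated.treatment != 1:
        raise DataError(f"expected a treated patient, got treatment={treated.treatment}")
    if untreated.treatment != 0:
        raise DataError(f"expected an untreated patient, got treatment={untreated.treatment}")
    m = observed_pairwise_effect(treated.outcome, untreated.outcome)
    return MatchedPair(treated=treated, untreated=untreated, distance=float(distance), m=m)


class MatchedCohort:
    """Ordered collection of matched pairs; the unit every metric operates on."""

    def __init__(self, pairs: Sequence[MatchedPair]):
        self.pairs = list(pairs)
        self._arrays: dict | None = None

    @property
    def n_p(self) -> int:
        return len(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __getitem__(self, i):
        return self.pairs[i]

    def _build_arrays(self) -> dict:
        if self._arrays is None:
            self._arrays = {
                "J": np.array([p.J for p in self.pairs], dtype=float),
                "K": np.array([p.K for p in self.pairs], dtype=float),
                "L": np.array([p.L for p in self.pairs], dtype=float),
                "M": np.array([p.M for p in self.pairs], dtype=int),
                "distance": np.array([p.distance for p in self.pairs], dtype=float),
            }
        return self._arrays

    @property
    def J(self) -> np.ndarray:
        return self._build_arrays()["J"]

    @property
    def K(self) -> np.ndarray:
        return self._build_arrays()["K"]

    @property
    def L(self) -> np.ndarray:
        return self._build_arrays()["L"]

    @property
    def M(self) -> np.ndarray:
        return self._build_arrays()["M"]

    @property
    def distances(self) -> np.ndarray:
        return self._build_arrays()["distance"]

    def subset(self, indices) -> "MatchedCohort":
        """Cohort formed from ``pairs[i]`` for each index (with repetition allowed)."""
        return MatchedCohort([self.pairs[i] for i in np.asarray(indices, dtype=int)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pair_id": np.arange(1, self.n_p + 1),
            "treated_id": [p.treated.id for p in self.pairs],
            "untreated_id": [p.untreated.id for p in self.pairs],
            "distance": self.distances,
            "j": self.J,
            "k": self.K,
            "L": self.L,
            "M": self.M,
        })

    def write_pairs(self, path) -> None:
        """Export pairs as CSV (pair_id, ids, distance, j, k, L, M)."""
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_pairs(cls, path) -> "MatchedCohort":
        """Rebuild a cohort from a pairs CSV written by :meth:`write_pairs`.

        Outcomes are not stored in the pairs file; placeholder outcomes
        consistent with each row's ``M`` are reconstructed so that every
        derived quantity the metrics use (J, K, L, M) round-trips exactly.
        """
        df = pd.read_csv(path)
        required = {"treated_id", "untreated_id", "distance", "j", "k", "L", "M"}
        missing = required - set(df.columns)
        if missing:
            raise ConfigurationError(f"pairs file is missing columns: {sorted(missing)}")
        pairs = []
        for row in df.itertuples(index=False):
            m = int(row.M)
            y_t, y_u = {1: (0, 1), -1: (1, 0), 0: (0, 0)}[m]
            treated = PatientRecord(id=row.treated_id, treatment=1, outcome=y_t,
                                    covariates=np.empty(0), p0=row.k, p1=row.k)
            untreated = PatientRecord(id=row.untreated_id, treatment=0, outcome=y_u,
                                      covariates=np.empty(0), p0=row.j, p1=row.j)
            pairs.append(MatchedPair(treated=treated, untreated=untreated,
                                     distance=float(row.distance), m=m))
        return cls(pairs)


@dataclass(frozen=True)
class BenefitProbabilities:
    """Predicted probabilities of the three observable pair classes.

    For a matched pair with independent outcomes, ``p_benefit = (1-K)·J``,
    ``p_none = (1-K)(1-J) + K·J`` and ``p_harm = K·(1-J)``; the three
    components always lie on the probability simplex.
    """

    p_benefit: float
    p_none: float
    p_harm: float

    def __post_init__(self):
        for name in ("p_benefit", "p_none", "p_harm"):
            v = getattr(self, name)
            if v < -1e-12:
                raise DataError(f"{name} must be nonnegative, got {v!r}")
        total = self.p_benefit + self.p_none + self.p_harm
        if abs(total - 1.0) > 1e-12:
            raise DataError(f"benefit probabilities must sum to 1, got {total!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_benefit, self.p_none, self.p_harm])


@dataclass
class MetricReport:
    """Named metric values with optional bootstrap intervals and provenance.

    ``metrics`` maps a metric name to its point estimate (``None`` when the
    metric is undefined on the cohort, e.g. C-for-benefit with no informative
    comparisons).  ``intervals`` maps names to ``(lower, upper, level)``
    percentile-bootstrap tuples; ``dropped`` counts resamples on which a
    metric was undefined.  Only ``lower <= upper`` is guaranteed — percentile
    intervals may exclude the point estimate in pathological resamples.
    """

    metrics: dict = field(default_factory=dict)
    intervals: dict = field(default_factory=dict)
    dropped: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.metrics[key]

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics,
            "intervals": {k: {"lower": v[0], "upper": v[1], "level": v[2]}
                          for k, v in self.intervals.items()},
            "dropped_resamples": self.dropped,
            "provenance": self.provenance,
        }

    def to_json(self, path=None, indent: int = 2):
        payload = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is None:
            return payload
        with open(path, "w") as fh:
            fh.write(payload + "\n")
        return None


# ---------------------------------------------------------------------------
# CSV input/output
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {"id": "id", "treatment": "treatment", "outcome": "outcome",
                    "p0": "p0", "p1": "p1"}


def load_cohort(path, covariates: Sequence[str] = (),
                column_map: Mapping[str, str] | None = None) -> list[PatientRecord]:
    """Read one :class:`PatientRecord` per CSV row, preserving row order.

    Parameters
    ----------
    path : str or file-like
        Comma-separated file with a header row ("." decimal separator, UTF-8).
    covariates : sequence of str
        Names of the covariate columns, in the order they should enter the
        covariate vector.
    column_map : mapping, optional
        Renames of the structural columns, e.g. ``{"treatment": "arm"}``.
        Keys are the canonical names ``id, treatment, outcome, p0, p1``.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(cols)
        if unknown:
            raise ConfigurationError(f"unknown column-map keys: {sorted(unknown)}")
        cols.update(column_map)
    df = pd.read_csv(path)
    needed = list(cols.values()) + list(covariates)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ConfigurationError(f"input file is missing columns: {missing}")
    records = []
    for i in range(len(df)):
        row = df.iloc[i]
        try:
            records.append(PatientRecord(
                id=row[cols["id"]],
                treatment=row[cols["treatment"]],
                outcome=row[cols["outcome"]],
                covariates=row[list(covariates)].to_numpy(dtype=float)
                if covariates else np.empty(0),
                p0=row[cols["p0"]],
                p1=row[cols["p1"]],
            ))
        except DataError as exc:
            raise DataError(f"row {i}: {exc}") from exc
    return records


def write_cohort(records: Iterable[PatientRecord], path,
                 covariates: Sequence[str] = ()) -> None:
    """Write patient records as CSV; inverse of :func:`load_cohort`."""
    records = list(records)
    if covariates:
        dim = len(records[0].covariates) if records else 0
        if len(covariates) != dim:
            raise ConfigurationError(
                f"{len(covariates)} covariate names given for dimension {dim}")
    rows = []
    for r in records:
        row = {"id": r.id, "treatment": r.treatment, "outcome": r.outcome,
               "p0": r.p0, "p1": r.p1}
        row.update({name: r.covariates[j] for j, name in enumerate(covariates)})
        rows.append(row)
    columns = ["id", "treatment", "outcome", "p0", "p1", *covariates]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Worked-example fixture
# ---------------------------------------------------------------------------

# Eight matched pairs of a small artificial trial sample, used throughout the
# docs and tests as the worked example.  Per pair: treated patient's
# (p0, p1, outcome), untreated patient's (p0, p1, outcome), and the published
# observed pairwise effect M.  Note the stored M values follow the source
# table verbatim (computed there as treated-minus-untreated outcome), which
# for pairs with unequal outcomes is the mirror of this package's own
# benefit-positive convention; see `observed_pairwise_effect` and the methods
# note.  The smoothed column N below is the reference loess fit of M on L.
_TABLE1 = [
    # (B, C, E), (F, G, I), M
    ((0.136, 0.283, 1), (0.162, 0.307, 1), 0),
    ((0.246, 0.343, 0), (0.218, 0.319, 1), -1),
    ((0.156, 0.219, 1), (0.142, 0.203, 0), 1),
    ((0.081, 0.083, 0), (0.098, 0.062, 0), 0),
    ((0.345, 0.212, 1), (0.299, 0.171, 0), 1),
    ((0.421, 0.390, 1), (0.561, 0.255, 1), 0),
    ((0.364, 0.201, 1), (0.243, 0.164, 1), 0),
    ((0.264, 0.199, 1), (0.345, 0.278, 0), 1),
]

TABLE1_SMOOTHED = np.array(
    [-0.412, -0.589, 0.901, -0.081, 0.937, 0.190, 0.217, 0.707])


def table1_fixture() -> MatchedCohort:
    """The eight-pair worked example, with the reference smoothed values.

    Returns a :class:`MatchedCohort` whose ``smoothed_reference`` attribute
    holds the published loess column N, so the calibration metrics can be
    reproduced without re-fitting the smoother.
    """
    pairs = []
    for i, ((b, c, e), (f_, g, ii), m) in enumerate(_TABLE1, start=1):
        treated = PatientRecord(id=f"T{i}", treatment=1, outcome=e,
                                covariates=np.empty(0), p0=b, p1=c)
        untreated = PatientRecord(id=f"U{i}", treatment=0, outcome=ii,
                                  covariates=np.empty(0), p0=f_, p1=g)
        pairs.append(MatchedPair(treated=treated, untreated=untreated,
                                 distance=0.0, m=m))
    cohort = MatchedCohort(pairs)
    cohort.smoothed_reference = TABLE1_SMOOTHED.copy()
    return cohort
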