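import numpy as np
import pytest

from benefitmetrics import MatchedCohort, MatchedPair, PatientRecord, table1_fixture


def build_cohort(J, K, M, distances=None):
    """MatchedCohort from raw pair vectors (outcomes chosen to realize M)."""
    J = np.asarray(J, dtype=float)
    K = np.asarray(K, dtype=float)
    M = np.asarray(M, dtype=int)
    distances = np.zeros_like(J) if distances is None else np.asarray(distances)
    pairs = []
    for i, (j, k, m, d) in enumerate(zip(J, K, M, distances)):
        y_t, y_u = {1: (0, 1), -1: (1, 0), 0: (0, 0)}[int(m)]
        treated = PatientRecord(id=f"t{i}", treatment=1, outcome=y_t,
                                covariates=np.empty(0), p0=k, p1=k)
        untreated = PatientRecord(id=f"u{i}", treatment=0, outcome=y_u,
                                  covariates=np.empty(0), p0=j, p1=j)
        pairs.append(MatchedPair(treated=treated, untreated=untreated,
                                 distance=float(d), m=int(m)))
    return MatchedCohort(pairs)


def random_cohort(rng, n_p):
    """Random cohort: J, K uniform, M drawn from the implied class probabilities."""
    J = rng.random(n_p)
    K = rng.random(n_p)
    probs = np.column_stack([(1 - K) * J, (1 - K) * (1 - J) + K * J, K * (1 - J)])
    M = np.array([rng.choice([1, 0, -1], p=p) for p in probs])
    return build_cohort(J, K, M)


@pytest.fixture
def table1():
    return table1_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def make_cohort():
    return build_cohort


@pytest.fixture
def make_random_cohort():
    return random_cohort


def make_patient(i, treatment, covariates, outcome=0, p0=0.5, p1=0.5):
    return PatientRecord(id=i, treatment=treatment, outcome=outcome,
                         covariates=np.asarray(covariates, dtype=float),
                         p0=p0, p1=p1)


@pytest.fixture
def patient_factory():
    return make_patient
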