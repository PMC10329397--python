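"""Model/Results facade over matching, smoothing, metrics and bootstrap.

`TreatmentEffectEvaluation` is constructed from patient-level trial data (or
an already-matched cohort) and its :meth:`~TreatmentEffectEvaluation.fit`
returns :class:`EvaluationResults` carrying the metric estimates, their
bootstrap intervals, diagnostics and a ``summary()`` table — the same
model/results split statsmodels users expect.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .bootstrap import bootstrap_metrics
from .cohort import (DataError, MatchedCohort, MetricReport, PatientRecord,
                     load_cohort)
from .matching import MatchSettings, match_cohort
from .metrics import evaluate, quantile_groups
from .smoothing import SmootherSettings, smoothed_curve

__all__ = ["TreatmentEffectEvaluation", "EvaluationResults"]

_METRIC_LABELS = {
    "citl": "Calibration-in-the-large (signed)",
    "citl_abs_smoothed": "Calibration-in-the-large |smoothed|",
    "e_avg": "E-avg-for-benefit",
    "e50": "E-50-for-benefit",
    "e90": "E-90-for-benefit",
    "c_for_benefit": "C-for-benefit",
    "cross_entropy": "Cross-entropy-for-benefit",
    "brier": "Brier-for-benefit",
}


class TreatmentEffectEvaluation:
    """Evaluation of a treatment-effect prediction model on RCT data.

    Parameters
    ----------
    records : sequence of PatientRecord, optional
        Patient-level data (both arms, with each patient's predicted risks
        under control ``p0`` and under treatment ``p1``).  Matching is run at
        fit time.
    pairs : MatchedCohort, optional
        An already-matched cohort; mutually exclusive with ``records``.
    match_settings, smoother_settings
        Matching and loess options (defaults: Mahalanobis matching without
        replacement; span 0.75, degree 2).

    Examples
    --------
    >>> from benefitmetrics import TreatmentEffectEvaluation, table1_fixture
    >>> cohort = table1_fixture()
    >>> res = TreatmentEffectEvaluation(pairs=cohort).fit()
    >>> round(res.metrics["brier"], 3)
    0.308
    """

    def __init__(self,
                 records: Sequence[PatientRecord] | None = None,
                 *,
                 pairs: MatchedCohort | None = None,
                 match_settings: MatchSettings | None = None,
                 smoother_settings: SmootherSettings | None = None):
        if (records is None) == (pairs is None):
            raise ValueError("provide exactly one of records= or pairs=")
        self.records = list(records) if records is not None else None
        self.pairs = pairs
        self.match_settings = match_settings or MatchSettings()
        self.smoother_settings = smoother_settings or SmootherSettings()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, covariates: Sequence[str],
                       column_map=None, **kwargs) -> "TreatmentEffectEvaluation":
        """Build from a patient-level DataFrame (id, treatment, outcome, p0, p1
        plus the named covariate columns)."""
        import io
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        records = load_cohort(buf, covariates=covariates, column_map=column_map)
        return cls(records, **kwargs)

    @classmethod
    def from_csv(cls, path, covariates: Sequence[str] = (), column_map=None,
                 **kwargs) -> "TreatmentEffectEvaluation":
        return cls(load_cohort(path, covariates=covariates, column_map=column_map),
                   **kwargs)

    def fit(self, bootstrap: int | None = None, level: float = 0.95,
            seed: int | None = None, smoothed=None) -> "EvaluationResults":
        """Match (if needed), smooth, compute all metrics, optionally bootstrap.

        ``smoothed`` injects a precomputed smoothed vector N in place of the
        loess fit (used for worked-example reproduction).
        """
        cohort = self.pairs
        if cohort is None:
            cohort = match_cohort(self.records, self.match_settings)
        if bootstrap:
            if smoothed is not None:
                raise ValueError("bootstrap resampling re-fits the smoother; "
                                 "an injected smoothed vector cannot be used")
            report = bootstrap_metrics(cohort, B=bootstrap, level=level,
                                       seed=seed, smoother=self.smoother_settings)
        else:
            report = evaluate(cohort, smoother=self.smoother_settings,
                              smoothed=smoothed)
        report.provenance.update({
            "matching": {"replace": self.match_settings.replace,
                         "order": self.match_settings.order,
                         "seed": self.match_settings.seed},
            "seed": seed,
        })
        return EvaluationResults(self, cohort, report)


class EvaluationResults:
    """Fitted metric values, bootstrap intervals and diagnostics."""

    def __init__(self, model: TreatmentEffectEvaluation,
                 cohort: MatchedCohort, report: MetricReport):
        self.model = model
        self.cohort = cohort
        self.report = report

    @property
    def metrics(self) -> dict:
        return self.report.metrics

    @property
    def intervals(self) -> dict:
        return self.report.intervals

    @property
    def n_pairs(self) -> int:
        return self.cohort.n_p

    def conf_int(self, name: str):
        """(lower, upper) percentile interval for one metric, if bootstrapped."""
        lo, hi, _ = self.report.intervals[name]
        return lo, hi

    def quantile_groups(self, n_groups: int = 4):
        """Calibration-plot dots: per quantile group of predicted effect,
        the mean predicted and mean observed pairwise effect."""
        return quantile_groups(self.cohort, n_groups)

    def calibration_curve(self, n_points: int = 100) -> pd.DataFrame:
        """Smoothed calibration curve on an even grid of predicted effects."""
        L = self.cohort.L
        grid = np.linspace(L.min(), L.max(), n_points)
        fitted = smoothed_curve(grid, L, self.cohort.M.astype(float),
                                self.model.smoother_settings)
        return pd.DataFrame({"x_grid": grid, "fitted": fitted})

    def summary(self) -> str:
        """Human-readable table of all metrics (3 decimals) with intervals."""
        lines = [
            "Treatment-effect prediction performance (matched pairs)",
            "=" * 66,
            f"Matched pairs: {self.n_pairs}",
        ]
        boot = self.report.provenance.get("bootstrap")
        if boot:
            lines.append(f"Bootstrap: B={boot['B']}, level={boot['level']}, "
                         f"seed={boot['seed']}")
        lines.append("-" * 66)
        for key, label in _METRIC_LABELS.items():
            value = self.metrics.get(key)
            txt = "undefined" if value is None else f"{value:8.3f}"
            ci = self.report.intervals.get(key)
            ci_txt = f"  [{ci[0]:.3f}, {ci[1]:.3f}]" if ci else ""
            lines.append(f"{label:<40s}{txt}{ci_txt}")
        lines.append("=" * 66)
        return "\n".join(lines)

    def to_json(self, path=None, indent: int = 2):
        return self.report.to_json(path, indent=indent)

    def __repr__(self):
        shown = {k: (round(v, 4) if isinstance(v, float) else v)
                 for k, v in self.metrics.items()}
        return f"<EvaluationResults n_pairs={self.n_pairs} metrics={shown}>"
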