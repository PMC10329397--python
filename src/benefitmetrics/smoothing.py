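"""Local polynomial regression (loess) of observed on predicted pairwise effect.

The smoother regresses the observed pairwise treatment effect ``M`` on the
predicted pairwise treatment effect ``L`` and evaluates the fit at every
observed ``L``, producing the smoothed calibration values ``N`` that the
E-for-benefit statistics compare against the diagonal of perfect calibration.

The estimator is the classical loess with tricube kernel and Gaussian family
(no robustness iterations): at each evaluation point a weighted least-squares
polynomial of the configured degree is fitted over the ``ceil(span * n)``
nearest neighbors, with weights ``w = (1 - (d/d_max)^3)^3``.  Evaluation is
exact at every requested point — no interpolation surface is used.  Repeated
x-values are aggregated analytically (the tricube weight depends on x only),
which makes evaluation on cohorts with heavily duplicated predictions — such
as the duplicated super-populations of the simulation study — cost
``O(u^2)`` in the number of *unique* x rather than ``O(n^2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import ConfigurationError, DataError

__all__ = ["SmootherSettings", "local_regression", "smoothed_curve"]


@dataclass(frozen=True)
class SmootherSettings:
    """Loess settings: ``span`` is the neighborhood fraction, ``degree`` the
    local polynomial degree.  Defaults (0.75, 2) are the conventional loess
    defaults."""

    span: float = 0.75
    degree: int = 2
    kernel: str = "tricube"

    def __post_init__(self):
        if not (0.0 < self.span <= 1.0):
            raise ConfigurationError(f"span must be in (0, 1], got {self.span!r}")
        if self.degree not in (0, 1, 2):
            raise ConfigurationError(f"degree must be 0, 1 or 2, got {self.degree!r}")
        if self.kernel != "tricube":
            raise ConfigurationError("only the tricube kernel is supported")


def _fit_at_points(x_eval: np.ndarray, x: np.ndarray, y: np.ndarray,
                   settings: SmootherSettings) -> np.ndarray:
    """Exact loess evaluation at ``x_eval``, aggregating duplicate x-values."""
    n = x.size
    q = int(np.ceil(settings.span * n))
    q = max(q, settings.degree + 1)

    # collapse duplicates: per unique x keep multiplicity and mean response
    xu, inverse, counts = np.unique(x, return_inverse=True, return_counts=True)
    ysum = np.bincount(inverse, weights=y, minlength=xu.size)
    ymean = ysum / counts

    # evaluation points may repeat too
    eu, eindex = np.unique(x_eval, return_inverse=True)

    fitted_u = np.empty(eu.size)
    warned = False
    for i, x0 in enumerate(eu):
        d = np.abs(xu - x0)
        order = np.argsort(d, kind="stable")
        csum = np.cumsum(counts[order])
        # bandwidth: distance to the q-th nearest data point (with multiplicity)
        dmax = d[order[np.searchsorted(csum, q)]] if csum[-1] >= q else d[order[-1]]
        if dmax == 0.0:
            at0 = d == 0.0
            fitted_u[i] = ysum[at0].sum() / counts[at0].sum()
            continue
        w = np.clip(1.0 - (d / dmax) ** 3, 0.0, None) ** 3
        mask = w > 0.0
        deg = settings.degree
        n_support = int(mask.sum())
        if n_support < deg + 1:
            if not warned:
                warnings.warn("local design is singular (too few distinct x in "
                              "the window); falling back to a lower local degree",
                              RuntimeWarning, stacklevel=3)
                warned = True
            deg = max(n_support - 1, 0)
        wm = w[mask] * counts[mask]          # tricube weight times multiplicity
        A = np.vander(xu[mask] - x0, deg + 1, increasing=True)
        sw = np.sqrt(wm)
        coef, *_ = np.linalg.lstsq(A * sw[:, None], ymean[mask] * sw, rcond=None)
        fitted_u[i] = coef[0]
    return fitted_u[eindex]


def _validate(x: np.ndarray, y: np.ndarray, settings: SmootherSettings) -> None:
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and of equal length")
    if x.size < settings.degree + 2:
        raise DataError(f"need at least degree + 2 = {settings.degree + 2} points, "
                        f"got {x.size}")
    if np.all(x == x[0]):
        raise DataError("x values are all identical; the smoother is undefined")


def local_regression(x, y, settings: SmootherSettings | None = None) -> np.ndarray:
    """Loess fitted values at each observed ``x`` (the smoothed column ``N``)."""
    settings = settings or SmootherSettings()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate(x, y, settings)
    return _fit_at_points(x, x, y, settings)


def smoothed_curve(x_grid, x, y, settings: SmootherSettings | None = None) -> np.ndarray:
    """Loess evaluated on an arbitrary grid inside the observed x-range.

    Intended for exporting plot data of the smoothed calibration curve.
    Extrapolation outside ``[min(x), max(x)]`` is refused.
    """
    settings = settings or SmootherSettings()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = np.asarray(x_grid, dtype=float)
    _validate(x, y, settings)
    if grid.size and (grid.min() < x.min() or grid.max() > x.max()):
        raise DataError("grid extends outside the observed x-range; "
                        "no extrapolation is performed")
    return _fit_at_points(grid, x, y, settings)
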