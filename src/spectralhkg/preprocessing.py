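"""Missing-data triage, shape-preserving interpolation, and trend removal.

Series with adjacent missing points, three or more missing points, or a
missing endpoint are dropped; one or two isolated interior gaps are filled by
monotone piecewise-cubic Hermite interpolation.  Complete series are then made
(first-order) stationary by least-squares projection onto five trend bases —
four monomials plus a logarithm — and the residual is kept.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.interpolate import PchipInterpolator

from .expression_io import ExpressionSeries, SeriesSet

__all__ = [
    "TriageReason",
    "TriageDecision",
    "BasisSpec",
    "DetrendResult",
    "triage_missing",
    "interpolate_missing",
    "basis_matrix",
    "detrend_values",
    "detrend",
    "preprocess_set",
]


class TriageReason(enum.Enum):
    COMPLETE = "complete"
    INTERPOLATE_1 = "interpolate_1"
    INTERPOLATE_2 = "interpolate_2"
    DROP_SUCCESSIVE = "drop_successive"
    DROP_THREE_OR_MORE = "drop_three_or_more"
    DROP_ENDPOINT = "drop_endpoint"


_KEEP_REASONS = {
    TriageReason.COMPLETE,
    TriageReason.INTERPOLATE_1,
    TriageReason.INTERPOLATE_2,
}


@dataclass(frozen=True)
class TriageDecision:
    keep: bool
    reason: TriageReason

    def __post_init__(self) -> None:
        if self.keep != (self.reason in _KEEP_REASONS):
            raise ValueError(f"inconsistent decision: keep={self.keep}, reason={self.reason}")


def triage_missing(series: ExpressionSeries) -> TriageDecision:
    """Decide whether a series is kept, interpolated, or dropped.

    Drop rules, in order of precedence: any two adjacent missing points;
    three or more missing points; a missing first or last point (the
    interpolator cannot extrapolate).
    """
    if len(series) < 3:
        raise ValueError("series too short for triage (need length >= 3)")
    missing = np.flatnonzero(series.missing_mask)
    if missing.size >= 2 and np.any(np.diff(missing) == 1):
        return TriageDecision(False, TriageReason.DROP_SUCCESSIVE)
    if missing.size >= 3:
        return TriageDecision(False, TriageReason.DROP_THREE_OR_MORE)
    if missing.size and (missing[0] == 0 or missing[-1] == len(series) - 1):
        return TriageDecision(False, TriageReason.DROP_ENDPOINT)
    if missing.size == 0:
        return TriageDecision(True, TriageReason.COMPLETE)
    reason = TriageReason.INTERPOLATE_1 if missing.size == 1 else TriageReason.INTERPOLATE_2
    return TriageDecision(True, reason)


def interpolate_missing(series: ExpressionSeries) -> ExpressionSeries:
    """Fill isolated interior gaps by monotone piecewise-cubic Hermite interpolation.

    Observed values are preserved exactly; the fill is shape-preserving, so on
    locally monotone data it never overshoots the bracketing observations.
    """
    mask = series.missing_mask
    if not mask.any():
        return series.replace_values(series.values.copy())
    if mask[0] or mask[-1]:
        raise ValueError(
            f"probe {series.probe_id!r}: missing endpoint — extrapolation undefined"
        )
    t = np.arange(1, len(series) + 1, dtype=float)
    observed = ~mask
    interpolator = PchipInterpolator(t[observed], series.values[observed])
    filled = series.values.copy()
    filled[mask] = interpolator(t[mask])
    return series.replace_values(filled)


@dataclass(frozen=True)
class BasisSpec:
    """Trend basis: monomials t**e for each exponent, plus ln(t) if ``log``."""

    exponents: tuple[int, ...] = (0, 1, 2, 3)
    log: bool = True

    @property
    def size(self) -> int:
        return len(self.exponents) + (1 if self.log else 0)


DEFAULT_BASIS = BasisSpec()


def basis_matrix(n_points: int, spec: BasisSpec = DEFAULT_BASIS) -> np.ndarray:
    """Evaluate the trend bases on the 1-based time grid t = 1..n_points."""
    t = np.arange(1, n_points + 1, dtype=float)
    cols = [t**e for e in spec.exponents]
    if spec.log:
        cols.append(np.log(t))
    return np.column_stack(cols)


@dataclass(frozen=True)
class DetrendResult:
    """Least-squares fit of the trend bases and the stationary residual."""

    residual: np.ndarray
    coefficients: np.ndarray
    fitted: np.ndarray


def detrend_values(
    values: np.ndarray, spec: BasisSpec = DEFAULT_BASIS
) -> DetrendResult:
    """Project out the trend bases, returning residual and coefficients.

    Columns are scaled to unit norm before the SVD-based least-squares solve
    so that the wildly different magnitudes of t**3 and ln(t) do not degrade
    conditioning; coefficients are reported on the original basis.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if np.isnan(x).any():
        raise ValueError("detrend requires a complete series (no missing values)")
    if x.size < DEFAULT_BASIS.size:
        raise ValueError(f"series too short to detrend (need >= {spec.size} points)")
    basis = basis_matrix(x.size, spec)
    scale = np.linalg.norm(basis, axis=0)
    if np.any(scale == 0):
        raise ValueError("degenerate (all-zero) basis column")
    beta, _, rank, _ = np.linalg.lstsq(basis / scale, x, rcond=None)
    if rank < basis.shape[1]:
        raise np.linalg.LinAlgError("trend basis is rank-deficient on this grid")
    coefficients = beta / scale
    fitted = basis @ coefficients
    return DetrendResult(residual=x - fitted, coefficients=coefficients, fitted=fitted)


def detrend(series: ExpressionSeries, spec: BasisSpec = DEFAULT_BASIS) -> DetrendResult:
    """Detrend a complete :class:`ExpressionSeries`."""
    if series.missing_mask.any():
        raise ValueError(f"probe {series.probe_id!r}: cannot detrend with missing values")
    return detrend_values(series.values, spec)


def preprocess_set(
    series_set: SeriesSet | Iterable[ExpressionSeries],
    spec: BasisSpec = DEFAULT_BASIS,
) -> tuple[SeriesSet, Counter]:
    """Triage, interpolate, and detrend every series; report triage counts.

    Returns the kept series (values replaced by the detrended residual) and a
    counter keyed by :class:`TriageReason` value.
    """
    kept: list[ExpressionSeries] = []
    report: Counter = Counter()
    for series in series_set:
        decision = triage_missing(series)
        report[decision.reason.value] += 1
        if not decision.keep:
            continue
        complete = interpolate_missing(series)
        result = detrend(complete, spec)
        kept.append(complete.replace_values(result.residual))
    return SeriesSet(kept), report
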