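"""Discrete Fourier transform and power-spectrum feature extraction.

A real series of odd length N has conjugate-symmetric spectrum, so only
(N+1)/2 components are independent: the DC term plus one member of each
conjugate pair.  For the reference length of 47 points this gives the 24
power-spectrum features used by the classifier.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .expression_io import ExpressionSeries, SeriesSet

__all__ = [
    "SpectralFeatureVector",
    "FeatureMatrix",
    "dft",
    "n_independent_components",
    "power_features",
    "featurize",
    "write_features",
]


def dft(series: np.ndarray) -> np.ndarray:
    """Unnormalised forward DFT: X_k = sum_n x_n * exp(-2*pi*i*k*n/N)."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("input must be one-dimensional")
    if x.size == 0:
        raise ValueError("cannot transform an empty series")
    if np.isnan(x).any():
        raise ValueError("input contains missing values")
    return np.fft.fft(x)


def n_independent_components(n_points: int) -> int:
    """Number of spectrum components not tied to another by conjugation."""
    if n_points <= 0:
        raise ValueError("n_points must be positive")
    if n_points % 2 == 0:
        raise ValueError("even-length series not supported (no clean conjugate pairing)")
    return (n_points + 1) // 2


def power_features(series: np.ndarray) -> np.ndarray:
    """Power spectrum |X_k|**2 for the independent components k = 0..(N-1)/2."""
    x = np.asarray(series, dtype=float)
    n_keep = n_independent_components(x.size)
    spectrum = dft(x)
    return np.abs(spectrum[:n_keep]) ** 2


@dataclass(frozen=True)
class SpectralFeatureVector:
    probe_id: str
    power: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "power", np.asarray(self.power, dtype=float))
        if (self.power < 0).any():
            raise ValueError("power components must be non-negative")


@dataclass(frozen=True)
class FeatureMatrix:
    """Probe-aligned feature matrix: row i is the power spectrum of probe i."""

    probe_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "probe_ids", tuple(self.probe_ids))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 2 or self.values.shape[0] != len(self.probe_ids):
            raise ValueError("values must have one row per probe id")

    def __len__(self) -> int:
        return len(self.probe_ids)

    def rows_for(self, probe_ids) -> np.ndarray:
        index = {p: i for i, p in enumerate(self.probe_ids)}
        return np.array([index[p] for p in probe_ids], dtype=int)


def featurize(series_set: SeriesSet) -> FeatureMatrix:
    """Power features for every series, preserving input order.

    All series must be complete (preprocessed); any missing value is an error.
    """
    probe_ids: list[str] = []
    rows: list[np.ndarray] = []
    n_feat: int | None = None
    for series in series_set:
        if series.missing_mask.any():
            raise ValueError(
                f"probe {series.probe_id!r} has missing values; preprocess first"
            )
        feats = power_features(series.values)
        if n_feat is None:
            n_feat = feats.size
        elif feats.size != n_feat:
            raise ValueError("series of differing lengths in one feature matrix")
        probe_ids.append(series.probe_id)
        rows.append(feats)
    values = np.vstack(rows) if rows else np.empty((0, n_feat or 0))
    return FeatureMatrix(probe_ids=tuple(probe_ids), values=values)


def write_features(features: FeatureMatrix, path) -> None:
    """Export the feature matrix as TSV (probe_id + one column per component)."""
    n_feat = features.values.shape[1]
    with open(str(path), "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["probe_id"] + [f"power_{k}" for k in range(n_feat)])
        for probe_id, row in zip(features.probe_ids, features.values):
            writer.writerow([probe_id] + [repr(float(v)) for v in row])
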