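"""Shared fixtures: synthetic pools and feature matrices reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from spectralhkg import preprocessing, spectral_features
from spectralhkg.synthetic_fixtures import GeneratorConfig, generate_labeled_pools


@pytest.fixture(scope="session")
def steady_cfg() -> GeneratorConfig:
    return GeneratorConfig(noise_sd=0.3)


@pytest.fixture(scope="session")
def periodic_cfg() -> GeneratorConfig:
    return GeneratorConfig(noise_sd=0.3, periodic_components=((3.0, 1.0, 0.0),))


@pytest.fixture(scope="session")
def labeled_pools(steady_cfg, periodic_cfg):
    """Medium synthetic dataset: (series_set, partition, truth)."""
    return generate_labeled_pools(
        n_standard=60,
        n_putative_true=30,
        n_putative_false=30,
        n_nonhkg_true=200,
        n_nonhkg_false=8,
        steady_cfg=steady_cfg,
        periodic_cfg=periodic_cfg,
        seed=7,
    )


@pytest.fixture(scope="session")
def pooled_features(labeled_pools):
    """Preprocessed feature matrix aligned with the labeled pools."""
    series_set, partition, truth = labeled_pools
    cleaned, _ = preprocessing.preprocess_set(series_set)
    features = spectral_features.featurize(cleaned)
    return features, partition, truth, cleaned.probe_to_gene


def make_series(values, probe_id="P1", gene_id="G1"):
    """Build an ExpressionSeries from a list with None marking missing points."""
    from spectralhkg.expression_io import ExpressionSeries

    arr = np.array([np.nan if v is None else float(v) for v in values])
    mask = np.isnan(arr)
    return ExpressionSeries(probe_id=probe_id, gene_id=gene_id, values=arr, missing_mask=mask)
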