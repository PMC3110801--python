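"""Triage, monotone Hermite interpolation, and five-basis detrending."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_series
from oracles import monotone_hermite_interpolate
from spectralhkg.preprocessing import (
    BasisSpec,
    TriageDecision,
    TriageReason,
    basis_matrix,
    detrend,
    detrend_values,
    interpolate_missing,
    preprocess_set,
    triage_missing,
)
from spectralhkg.expression_io import SeriesSet
from spectralhkg.spectral_features import power_features
from spectralhkg.synthetic_fixtures import GeneratorConfig, generate_steady_series


def _series_with_missing(missing, n=47, seed=0, probe_id="P1"):
    rng = np.random.default_rng(seed)
    values = rng.normal(size=n)
    values[list(missing)] = np.nan
    return make_series(values, probe_id=probe_id)


class TestTriage:
    def test_complete(self):
        decision = triage_missing(_series_with_missing([]))
        assert decision == TriageDecision(True, TriageReason.COMPLETE)

    def test_adjacent_missing_dropped(self):
        decision = triage_missing(_series_with_missing([10, 11]))
        assert decision == TriageDecision(False, TriageReason.DROP_SUCCESSIVE)

    def test_three_separated_missing_dropped(self):
        decision = triage_missing(_series_with_missing([5, 20, 40]))
        assert decision == TriageDecision(False, TriageReason.DROP_THREE_OR_MORE)

    def test_two_separated_kept(self):
        decision = triage_missing(_series_with_missing([5, 20]))
        assert decision == TriageDecision(True, TriageReason.INTERPOLATE_2)

    def test_one_missing_kept(self):
        decision = triage_missing(_series_with_missing([17]))
        assert decision == TriageDecision(True, TriageReason.INTERPOLATE_1)

    def test_missing_first_point_dropped(self):
        decision = triage_missing(_series_with_missing([0]))
        assert decision == TriageDecision(False, TriageReason.DROP_ENDPOINT)

    def test_missing_last_point_dropped(self):
        decision = triage_missing(_series_with_missing([46]))
        assert decision == TriageDecision(False, TriageReason.DROP_ENDPOINT)

    def test_successive_takes_precedence_over_count(self):
        decision = triage_missing(_series_with_missing([3, 4, 20, 30]))
        assert decision.reason is TriageReason.DROP_SUCCESSIVE

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            triage_missing(make_series([1.0, 2.0]))

    def test_inconsistent_decision_rejected(self):
        with pytest.raises(ValueError):
            TriageDecision(True, TriageReason.DROP_SUCCESSIVE)


class TestInterpolation:
    def test_complete_series_unchanged(self):
        series = _series_with_missing([])
        result = interpolate_missing(series)
        np.testing.assert_array_equal(result.values, series.values)

    def test_monotone_gap_no_overshoot(self):
        series = make_series([1.0, 2.0, None, 4.0])
        filled = interpolate_missing(series).values[2]
        assert 2.0 <= filled <= 4.0

    def test_missing_endpoint_rejected(self):
        with pytest.raises(ValueError, match="endpoint"):
            interpolate_missing(_series_with_missing([0]))

    def test_observed_values_preserved_exactly(self):
        series = _series_with_missing([5, 20], seed=3)
        result = interpolate_missing(series)
        observed = ~series.missing_mask
        np.testing.assert_array_equal(result.values[observed], series.values[observed])
        assert not result.missing_mask.any()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_monotone_hermite_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=47)
        gap = int(rng.integers(1, 46))
        series_values = values.copy()
        series_values[gap] = np.nan
        series = make_series(series_values)
        filled = interpolate_missing(series).values[gap]
        t = [float(i + 1) for i in range(47) if i != gap]
        y = [values[i] for i in range(47) if i != gap]
        expected = monotone_hermite_interpolate(t, y, float(gap + 1))
        assert filled == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000), gap=st.integers(1, 45))
    def test_no_overshoot_on_monotone_series(self, seed, gap):
        rng = np.random.default_rng(seed)
        values = np.cumsum(rng.uniform(0.01, 1.0, size=47))  # strictly increasing
        series_values = values.copy()
        series_values[gap] = np.nan
        filled = interpolate_missing(make_series(series_values)).values[gap]
        assert values[gap - 1] <= filled <= values[gap + 1]


class TestDetrend:
    def test_input_in_basis_span_gives_zero_residual(self):
        t = np.arange(1, 48, dtype=float)
        result = detrend_values(3.0 + 0.2 * t)
        assert np.abs(result.residual).max() < 1e-8

    def test_log_component_in_span(self):
        t = np.arange(1, 48, dtype=float)
        result = detrend_values(1.5 * np.log(t) - 0.4 * t**2)
        assert np.abs(result.residual).max() < 1e-8

    def test_residual_mean_zero(self):
        rng = np.random.default_rng(5)
        result = detrend_values(rng.normal(size=47))
        assert abs(result.residual.mean()) < 1e-8

    @pytest.mark.parametrize("seed", range(5))
    def test_residual_orthogonal_to_basis(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=47) * 10
        result = detrend_values(x)
        basis = basis_matrix(47)
        for j in range(basis.shape[1]):
            b = basis[:, j] / np.linalg.norm(basis[:, j])
            assert abs(result.residual @ b) < 1e-6 * np.linalg.norm(x)

    def test_residual_identity_reconstruction(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=47)
        result = detrend_values(x)
        basis = basis_matrix(47)
        np.testing.assert_allclose(
            result.residual, x - basis @ result.coefficients, atol=1e-10
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        once = detrend_values(rng.normal(size=47)).residual
        twice = detrend_values(once).residual
        np.testing.assert_allclose(twice, once, atol=1e-8)

    def test_sinusoid_power_preserved(self):
        t = np.arange(1, 48, dtype=float)
        tone = np.sin(2 * np.pi * 5 * t / 47)
        x = tone + 0.1 * t
        residual = detrend_values(x).residual
        residual_power = power_features(residual)[5]
        # oracle: direct projection of the pure tone onto the basis complement
        basis = basis_matrix(47)
        proj = basis @ np.linalg.solve(basis.T @ basis, basis.T @ tone)
        oracle_power = power_features(tone - proj)[5]
        tone_power = power_features(tone)[5]
        assert residual_power == pytest.approx(oracle_power, rel=1e-9)
        # the five bases absorb ~16% of the tone's power at this frequency;
        # the bulk survives detrending
        assert residual_power / tone_power == pytest.approx(0.8393, abs=1e-3)
        assert residual_power / tone_power > 0.8

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            detrend(_series_with_missing([5]))

    def test_custom_basis(self):
        t = np.arange(1, 21, dtype=float)
        spec = BasisSpec(exponents=(0, 1), log=False)
        result = detrend_values(2.0 - 0.3 * t, spec)
        assert result.coefficients.size == 2
        assert np.abs(result.residual).max() < 1e-8


class TestPreprocessSet:
    def test_composition_counts(self):
        series = [
            make_series(np.arange(47.0), probe_id="A"),
            _series_with_missing([10, 11], probe_id="B"),
            _series_with_missing([20], probe_id="C"),
        ]
        out, report = preprocess_set(SeriesSet(series))
        assert len(out) == 2
        assert report == {"complete": 1, "drop_successive": 1, "interpolate_1": 1}

    def test_empty_set(self):
        out, report = preprocess_set(SeriesSet([]))
        assert len(out) == 0
        assert report == {}

    def test_output_series_are_detrended_residuals(self):
        series = make_series(np.arange(47.0) * 0.5 + 2.0)
        out, _ = preprocess_set(SeriesSet([series]))
        assert np.abs(out[0].values).max() < 1e-8  # linear trend removed entirely

    def test_kept_fraction_matches_independent_missingness_closed_form(self):
        n, rate, n_series = 47, 0.03, 3000
        cfg = GeneratorConfig(
            n_points=n, noise_sd=0.2, missing=(0, "iid"), missing_rate=rate
        )
        rng = np.random.default_rng(123)
        series = [
            generate_steady_series(cfg, probe_id=f"P{i}", rng=rng)
            for i in range(n_series)
        ]
        out, _ = preprocess_set(SeriesSet(series))
        kept_fraction = len(out) / n_series
        # closed form: keep iff 0 missing, or 1-2 interior non-adjacent missing
        q = 1.0 - rate
        interior = n - 2
        p0 = q**n
        p1 = interior * rate * q ** (n - 1)
        n_pairs = math.comb(interior, 2) - (interior - 1)  # non-adjacent interior pairs
        p2 = n_pairs * rate**2 * q ** (n - 2)
        p_keep = p0 + p1 + p2
        tolerance = 4 * math.sqrt(p_keep * (1 - p_keep) / n_series)
        assert abs(kept_fraction - p_keep) < tolerance
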