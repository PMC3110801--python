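"""Seeded synthetic data generators for every pipeline stage.

Steady series emulate housekeeping-like expression (trend + Gaussian noise);
periodic series add cell-cycle-like sinusoids (default frequency index 3 —
three cycles across the sampling window).  Pool generators plant known true
and false annotations in the putative and non-HKG pools, and the tissue
matrix generator plants low-CV and high-CV gene populations, so ground truth
is always available for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .evaluation import TissueMatrix
from .expression_io import ExpressionSeries, ProbePartition, SeriesSet
from .preprocessing import DEFAULT_BASIS, BasisSpec, basis_matrix

__all__ = [
    "GeneratorConfig",
    "generate_steady_series",
    "generate_periodic_series",
    "generate_labeled_pools",
    "generate_tissue_matrix",
]

MISSING_PATTERNS = ("none", "separated", "successive", "endpoint", "iid")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters for one synthetic expression series.

    ``trend`` holds coefficients over the preprocessing trend basis (padded
    with zeros); ``periodic_components`` is a list of (frequency index k,
    amplitude, phase) tuples; ``missing`` is (n_missing, pattern).  For the
    "iid" pattern each point is missing independently with probability
    ``missing_rate`` and n_missing is ignored.
    """

    n_points: int = 47
    time_step: float = 1.0
    trend: tuple[float, ...] = ()
    periodic_components: tuple[tuple[float, float, float], ...] = ()
    noise_sd: float = 0.0
    missing: tuple[int, str] = (0, "none")
    missing_rate: float = 0.0
    seed: int = 0
    basis: BasisSpec = DEFAULT_BASIS

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.trend) > self.basis.size:
            raise ValueError(f"trend has more than {self.basis.size} coefficients")
        n_missing, pattern = self.missing
        if pattern not in MISSING_PATTERNS:
            raise ValueError(f"unknown missing pattern {pattern!r}")
        if n_missing < 0:
            raise ValueError("n_missing must be non-negative")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        for k, _amp, _phase in self.periodic_components:
            if not 1 <= k <= self.n_points // 2:
                raise ValueError(
                    f"frequency index {k} outside [1, {self.n_points // 2}]"
                )


def _trend_values(config: GeneratorConfig) -> np.ndarray:
    if not config.trend:
        return np.zeros(config.n_points)
    coeffs = np.zeros(config.basis.size)
    coeffs[: len(config.trend)] = config.trend
    return basis_matrix(config.n_points, config.basis) @ coeffs


def _apply_missing(
    n_points: int, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    n_missing, pattern = config.missing
    mask = np.zeros(n_points, dtype=bool)
    if pattern == "none" or (pattern != "iid" and n_missing == 0):
        return mask
    if pattern == "iid":
        return rng.random(n_points) < config.missing_rate
    if pattern == "separated":
        # non-adjacent interior positions: pick from every other interior index
        candidates = np.arange(1, n_points - 1, 2)
        if n_missing > candidates.size:
            raise ValueError(f"cannot place {n_missing} separated interior gaps")
        mask[rng.choice(candidates, size=n_missing, replace=False)] = True
        return mask
    if pattern == "successive":
        run = max(2, n_missing)
        if run > n_points - 2:
            raise ValueError("successive run too long for series")
        start = int(rng.integers(1, n_points - run))
        mask[start: start + run] = True
        return mask
    # endpoint: first point, then the last if two are requested
    mask[0] = True
    if n_missing >= 2:
        mask[-1] = True
    return mask


def _finish_series(
    x: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
    probe_id: str,
    gene_id: str,
) -> ExpressionSeries:
    mask = _apply_missing(config.n_points, config, rng)
    x = x.copy()
    x[mask] = np.nan
    return ExpressionSeries(
        probe_id=probe_id,
        gene_id=gene_id,
        values=x,
        missing_mask=mask,
        time_step=config.time_step,
    )


def _base_signal(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    x = _trend_values(config)
    if config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd, size=config.n_points)
    else:
        # keep the generator stream aligned between noisy and noiseless runs
        rng.normal(0.0, 1.0, size=config.n_points)
    return x


def generate_steady_series(
    config: GeneratorConfig,
    probe_id: str = "P0",
    gene_id: str = "G0",
    rng: np.random.Generator | None = None,
) -> ExpressionSeries:
    """HKG-like series: trend plus Gaussian noise, no periodic component."""
    if config.periodic_components:
        raise ValueError("steady series must have no periodic components")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    x = _base_signal(config, rng)
    return _finish_series(x, config, rng, probe_id, gene_id)


def generate_periodic_series(
    config: GeneratorConfig,
    probe_id: str = "P0",
    gene_id: str = "G0",
    rng: np.random.Generator | None = None,
) -> ExpressionSeries:
    """Cell-cycle-like series: trend + noise + sum of sinusoids.

    With all amplitudes zero and the same seed this degenerates exactly to
    :func:`generate_steady_series` output (noise is drawn before the tones).
    """
    if not config.periodic_components:
        raise ValueError("periodic series needs at least one periodic component")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    x = _base_signal(config, rng)
    t = np.arange(1, config.n_points + 1, dtype=float)
    for k, amplitude, phase in config.periodic_components:
        x = x + amplitude * np.sin(2 * np.pi * k * t / config.n_points + phase)
    return _finish_series(x, config, rng, probe_id, gene_id)


def _randomize_phases(
    config: GeneratorConfig, rng: np.random.Generator
) -> GeneratorConfig:
    comps = tuple(
        (k, amp, float(rng.uniform(0, 2 * np.pi)))
        for k, amp, _phase in config.periodic_components
    )
    return replace(config, periodic_components=comps)


def generate_labeled_pools(
    n_standard: int,
    n_putative_true: int,
    n_putative_false: int,
    n_nonhkg_true: int,
    n_nonhkg_false: int,
    steady_cfg: GeneratorConfig,
    periodic_cfg: GeneratorConfig,
    seed: int,
) -> tuple[SeriesSet, ProbePartition, dict[str, bool]]:
    """Build labelled probe pools with planted mis-annotations.

    The standard pool is all steady; the putative pool mixes steady probes
    (true HKGs) with periodic decoys (false annotations); the non-HKG pool
    mixes periodic probes (true non-HKGs, count ``n_nonhkg_true``) with a
    minority of steady probes (missed HKGs, count ``n_nonhkg_false``).
    Periodic probes get independently random phases.  Returns the series,
    the partition, and a probe -> is-truly-HKG map.  One probe per gene.
    """
    for name, n in (
        ("n_standard", n_standard),
        ("n_putative_true", n_putative_true),
        ("n_putative_false", n_putative_false),
        ("n_nonhkg_true", n_nonhkg_true),
        ("n_nonhkg_false", n_nonhkg_false),
    ):
        if n < 0:
            raise ValueError(f"{name} must be >= 0")
    rng = np.random.default_rng(seed)
    series: list[ExpressionSeries] = []
    truth: dict[str, bool] = {}
    standard, putative, non_hkg = set(), set(), set()

    def add(pool: set, steady: bool, tag: str, count: int) -> None:
        for i in range(count):
            probe_id = f"{tag}{i:05d}"
            gene_id = f"GENE_{tag}{i:05d}"
            if steady:
                s = generate_steady_series(steady_cfg, probe_id, gene_id, rng)
            else:
                cfg = _randomize_phases(periodic_cfg, rng)
                s = generate_periodic_series(cfg, probe_id, gene_id, rng)
            series.append(s)
            pool.add(probe_id)
            truth[probe_id] = steady

    add(standard, True, "STD", n_standard)
    add(putative, True, "PUT_T", n_putative_true)
    add(putative, False, "PUT_F", n_putative_false)
    add(non_hkg, False, "NON_T", n_nonhkg_true)
    add(non_hkg, True, "NON_F", n_nonhkg_false)
    partition = ProbePartition(
        standard=frozenset(standard),
        putative=frozenset(putative),
        non_hkg=frozenset(non_hkg),
    )
    return SeriesSet(series), partition, truth


def generate_tissue_matrix(
    n_hkg: int,
    n_specific: int,
    n_tissues: int,
    hkg_cv: float,
    specific_cv: float,
    base_mean: float,
    seed: int,
) -> tuple[TissueMatrix, dict[str, bool]]:
    """Tissue matrix with planted low-CV (HKG) and high-CV (specific) genes.

    Each gene draws a mean near ``base_mean`` and tissue values from
    Normal(mean_g, (cv_class * mean_g)^2).  Returns the matrix and a
    gene -> is-HKG map.
    """
    if hkg_cv < 0 or specific_cv < 0:
        raise ValueError("CVs must be non-negative")
    if base_mean <= 0:
        raise ValueError("base_mean must be positive")
    if n_tissues < 2:
        raise ValueError("need at least two tissues")
    rng = np.random.default_rng(seed)
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    truth: dict[str, bool] = {}
    for tag, count, cv, is_hkg in (
        ("HKG", n_hkg, hkg_cv, True),
        ("SPEC", n_specific, specific_cv, False),
    ):
        for i in range(count):
            gene = f"{tag}{i:04d}"
            mean_g = base_mean * (1.0 + 0.05 * rng.normal())
            row = rng.normal(mean_g, cv * abs(mean_g), size=n_tissues) if cv > 0 else np.full(n_tissues, mean_g)
            gene_ids.append(gene)
            rows.append(row)
            truth[gene] = is_hkg
    values = np.vstack(rows) if rows else np.empty((0, n_tissues))
    tissue_ids = tuple(f"T{j:03d}" for j in range(n_tissues))
    return TissueMatrix(gene_ids=tuple(gene_ids), tissue_ids=tissue_ids, values=values), truth
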