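"""Bootstrap voting: repeated SVM rounds with resampled negative sets.

Every round trains on all standard-pool probes (positives) against a fresh
random sample of non-HKG probes (negatives), then scores every putative-pool
and non-HKG-pool probe; a probe's vote count is the number of rounds that
called it an HKG.  Negatives used in a round's training set are still scored
by that round's model, keeping all counts on a common 0..rounds scale.

Gene selection applies pool-specific thresholds to each gene's best probe
count: putative-pool genes need count >= putative_cutoff (inclusive),
non-HKG-pool genes need count > nonhkg_cutoff (strict), and standard-pool
genes are selected unconditionally (they are training positives each round).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np

from .discrimination import ClassifierSpec, train_classifier
from .expression_io import ProbePartition
from .spectral_features import FeatureMatrix

__all__ = [
    "VoteTally",
    "HkgPrediction",
    "run_voting",
    "ballot_percent",
    "select_hkgs",
    "count_histogram",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VoteTally:
    """Per-probe HKG vote counts over the bootstrap rounds."""

    rounds: int
    counts: dict[str, int]
    eligibility: dict[str, int]

    def __post_init__(self) -> None:
        if self.rounds < 0:
            raise ValueError("rounds must be non-negative")
        for probe, count in self.counts.items():
            elig = self.eligibility.get(probe, 0)
            if not 0 <= count <= elig <= self.rounds:
                raise ValueError(
                    f"probe {probe!r}: require 0 <= count ({count}) <= "
                    f"eligibility ({elig}) <= rounds ({self.rounds})"
                )


@dataclass(frozen=True)
class HkgPrediction:
    """Gene-level call: best probe vote count and the selection decision."""

    gene_id: str
    best_probe_id: str
    best_count: int
    ballot_percent: float
    source_pool: str
    selected: bool


def run_voting(
    features: FeatureMatrix,
    partition: ProbePartition,
    rounds: int,
    n_neg: int,
    spec: ClassifierSpec,
    seed: int,
    standardize: bool = True,
) -> VoteTally:
    """Tally HKG votes over ``rounds`` bootstrap classification rounds."""
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    probe_set = set(features.probe_ids)
    standard = sorted(partition.standard & probe_set)
    non_hkg = sorted(partition.non_hkg & probe_set)
    putative = sorted(partition.putative & probe_set)
    if not standard:
        raise ValueError("standard pool is empty")
    if len(non_hkg) <= n_neg:
        raise ValueError(
            f"non-HKG pool ({len(non_hkg)}) must exceed n_neg ({n_neg})"
        )
    pos_rows = features.rows_for(standard)
    neg_pool_rows = features.rows_for(non_hkg)
    scored_probes = putative + non_hkg
    scored_rows = features.rows_for(scored_probes)
    X = features.values
    X_scored = X[scored_rows]
    rng = np.random.default_rng(seed)
    votes = np.zeros(len(scored_probes), dtype=int)
    next_log = 1
    for r in range(1, rounds + 1):
        neg_rows = rng.choice(neg_pool_rows, size=n_neg, replace=False)
        clf = train_classifier(X[pos_rows], X[neg_rows], spec, standardize)
        votes += clf.predict(X_scored)
        if r == next_log:
            logger.info("voting round %d/%d", r, rounds)
            next_log *= 2
    counts = {p: int(v) for p, v in zip(scored_probes, votes)}
    eligibility = {p: rounds for p in scored_probes}
    return VoteTally(rounds=rounds, counts=counts, eligibility=eligibility)


def ballot_percent(count: int, rounds: int) -> float:
    """100 * count / rounds, rounded half-up to two decimals."""
    if rounds <= 0:
        raise ValueError("rounds must be positive")
    if not 0 <= count <= rounds:
        raise ValueError(f"count {count} outside [0, {rounds}]")
    percent = Decimal(100 * count) / Decimal(rounds)
    return float(percent.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def select_hkgs(
    tally: VoteTally,
    partition: ProbePartition,
    putative_cutoff: int,
    nonhkg_cutoff: int,
    probe_gene_map: Mapping[str, str],
) -> list[HkgPrediction]:
    """Aggregate probe votes to genes and apply the pool-specific thresholds.

    A gene's score is the maximum count over its probes; its source pool is
    the pool of that best-scoring probe.  Results are sorted by descending
    count, then gene id.
    """
    for cutoff, name in ((putative_cutoff, "putative_cutoff"), (nonhkg_cutoff, "nonhkg_cutoff")):
        if not 0 <= cutoff <= tally.rounds:
            raise ValueError(f"{name} {cutoff} outside [0, {tally.rounds}]")
    for probe in tally.counts:
        if probe not in partition.all_probes:
            raise KeyError(f"probe {probe!r} in tally but absent from partition")
    genes: dict[str, list[str]] = {}
    for probe in sorted(partition.all_probes):
        gene = probe_gene_map.get(probe)
        if gene is None:
            raise KeyError(f"probe {probe!r} has no gene mapping")
        genes.setdefault(gene, []).append(probe)
    predictions: list[HkgPrediction] = []
    for gene, probes in genes.items():
        # max count wins; deterministic probe-id tiebreak
        best_probe = max(probes, key=lambda p: (tally.counts.get(p, 0), p))
        best_count = tally.counts.get(best_probe, 0)
        pool = partition.pool_of(best_probe)
        if pool == "standard":
            selected = True
        elif pool == "putative":
            selected = best_count >= putative_cutoff
        else:
            selected = best_count > nonhkg_cutoff
        predictions.append(
            HkgPrediction(
                gene_id=gene,
                best_probe_id=best_probe,
                best_count=best_count,
                ballot_percent=ballot_percent(best_count, tally.rounds),
                source_pool=pool,
                selected=selected,
            )
        )
    predictions.sort(key=lambda p: (-p.best_count, p.gene_id))
    return predictions


def count_histogram(
    tally: VoteTally, pool: frozenset[str] | set[str], min_count: int = 0
) -> dict[int, int]:
    """Frequencies of vote counts >= min_count among probes of one pool."""
    hist: Counter = Counter(
        count
        for probe, count in tally.counts.items()
        if probe in pool and count >= min_count
    )
    return dict(hist)
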