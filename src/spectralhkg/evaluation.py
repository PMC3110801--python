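"""Gene-set evaluation: expression stability across tissues and exon conservation.

Stability is measured by the coefficient of variation (sample SD / mean) of a
gene's expression across tissue columns; a candidate HKG set is summarised by
its median CV.  Conservation scores average per-base exon scores within each
mRNA, then average unweighted across a gene's mRNAs.
"""

from __future__ import annotations

import csv
import logging
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "UndefinedCvError",
    "TissueMatrix",
    "CvProfile",
    "coefficient_of_variation",
    "cv_profile",
    "median_cv",
    "conservation_score",
    "read_tissue_matrix",
    "write_cv_profile",
]

logger = logging.getLogger(__name__)

#: genes whose |mean| falls below this get an undefined CV (SD/mean blows up)
MEAN_EPSILON = 1e-6


class UndefinedCvError(ValueError):
    """Raised when the mean is too close to zero for SD/mean to be meaningful."""


@dataclass(frozen=True)
class TissueMatrix:
    """Gene x tissue log2 expression values (one row per gene, post-averaging)."""

    gene_ids: tuple[str, ...]
    tissue_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "tissue_ids", tuple(self.tissue_ids))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.gene_ids), len(self.tissue_ids)):
            raise ValueError("values shape must be (n_genes, n_tissues)")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids (average probes per gene first)")
        if np.isnan(self.values).any():
            raise ValueError("tissue matrix must not contain missing values")


@dataclass(frozen=True)
class CvProfile:
    """Per-gene CV map plus the genes excluded for near-zero mean."""

    cv: dict[str, float]
    excluded_genes: tuple[str, ...]


def coefficient_of_variation(values: Sequence[float], epsilon: float = MEAN_EPSILON) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    mean = float(x.mean())
    if abs(mean) < epsilon:
        raise UndefinedCvError(f"|mean| = {abs(mean):.3g} below epsilon {epsilon:g}")
    return float(x.std(ddof=1)) / mean


def cv_profile(matrix: TissueMatrix, epsilon: float = MEAN_EPSILON) -> CvProfile:
    """Compute each gene's CV across tissues; list near-zero-mean genes separately."""
    if len(matrix.tissue_ids) < 2:
        raise ValueError("need at least two tissues")
    cv: dict[str, float] = {}
    excluded: list[str] = []
    for gene, row in zip(matrix.gene_ids, matrix.values):
        try:
            cv[gene] = coefficient_of_variation(row, epsilon)
        except UndefinedCvError:
            excluded.append(gene)
    if excluded:
        logger.info("%d genes excluded from CV profile (|mean| < %g)", len(excluded), epsilon)
    return CvProfile(cv=cv, excluded_genes=tuple(excluded))


def median_cv(gene_set: Iterable[str], profile: CvProfile) -> float:
    """Median CV of the set's genes that have a defined CV.

    Genes absent from the profile are ignored (their count is logged); an
    even number of CVs yields the mean of the two middle values.
    """
    genes = set(gene_set)
    cvs = [profile.cv[g] for g in genes if g in profile.cv]
    n_absent = len(genes) - len(cvs)
    if n_absent:
        logger.info("median_cv: %d of %d genes absent from profile", n_absent, len(genes))
    if not cvs:
        raise ValueError("no gene in the set has a defined CV")
    return float(statistics.median(cvs))


def conservation_score(mrna_exon_scores: Sequence[Sequence[float]]) -> float:
    """Mean per-base exon score per mRNA, averaged unweighted across mRNAs."""
    if len(mrna_exon_scores) == 0:
        raise ValueError("need at least one mRNA")
    means = []
    for scores in mrna_exon_scores:
        arr = np.asarray(scores, dtype=float)
        if arr.size == 0:
            raise ValueError("each mRNA needs at least one base score")
        means.append(float(arr.mean()))
    return float(np.mean(means))


def read_tissue_matrix(path) -> TissueMatrix:
    """Read a TSV tissue matrix (gene rows, tissue columns, log2 values).

    Rows sharing a gene id (multiple probes) are averaged into one row.
    """
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    order: list[str] = []
    with open(str(path), "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or len(header) < 3:
            raise ValueError(f"{path}: need a header with gene id + >= 2 tissue columns")
        tissue_ids = tuple(h.strip() for h in header[1:])
        for lineno, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            if len(row) != len(header):
                raise ValueError(f"{path}: line {lineno}: expected {len(header)} columns")
            gene = row[0].strip()
            try:
                values = np.array([float(v) for v in row[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric value") from exc
            if gene in sums:
                sums[gene] += values
                counts[gene] += 1
            else:
                sums[gene] = values
                counts[gene] = 1
                order.append(gene)
    values = np.vstack([sums[g] / counts[g] for g in order]) if order else np.empty((0, len(tissue_ids)))
    return TissueMatrix(gene_ids=tuple(order), tissue_ids=tissue_ids, values=values)


def write_cv_profile(profile: CvProfile, path) -> None:
    """Export per-gene CVs as TSV; excluded genes get an empty CV cell."""
    with open(str(path), "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", "cv"])
        for gene, value in sorted(profile.cv.items()):
            writer.writerow([gene, repr(float(value))])
        for gene in profile.excluded_genes:
            writer.writerow([gene, ""])
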