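"""I/O for expression time-series matrices, gene lists, and prediction tables.

Expression matrices are tab-separated with the first two columns holding the
probe identifier and the gene symbol, followed by one numeric column per time
point.  PCL-style annotation decorations (a header row, a ``GWEIGHT`` column,
an ``EWEIGHT`` row) are recognised and skipped.  Empty or ``NA`` cells mark
missing observations.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "ExpressionSeries",
    "SeriesSet",
    "ProbePartition",
    "PredictionRecord",
    "read_series_matrix",
    "read_gene_list",
    "partition_probes",
    "write_predictions",
    "read_predictions",
]

_MISSING_TOKENS = {"", "na", "nan", "null", "none"}

PREDICTION_COLUMNS = (
    "gene_id",
    "best_probe_id",
    "vote_count",
    "ballot_percent",
    "source_pool",
    "selected",
)


@dataclass
class ExpressionSeries:
    """One probe's expression time course on a uniform sampling grid.

    ``values`` holds log-ratio expression values with ``nan`` at missing
    positions; ``missing_mask`` flags the same positions explicitly.
    """

    probe_id: str
    gene_id: str
    values: np.ndarray
    missing_mask: np.ndarray
    time_step: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.values.shape != self.missing_mask.shape:
            raise ValueError(
                f"probe {self.probe_id!r}: values length {self.values.size} "
                f"!= mask length {self.missing_mask.size}"
            )
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    @property
    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    def replace_values(self, values: np.ndarray, missing_mask=None) -> "ExpressionSeries":
        """Return a copy with new values (and optionally a new mask)."""
        if missing_mask is None:
            missing_mask = np.zeros_like(np.asarray(values, dtype=float), dtype=bool)
        return ExpressionSeries(
            probe_id=self.probe_id,
            gene_id=self.gene_id,
            values=np.asarray(values, dtype=float),
            missing_mask=missing_mask,
            time_step=self.time_step,
        )


class SeriesSet:
    """An ordered collection of :class:`ExpressionSeries` with unique probe ids."""

    def __init__(self, series: Iterable[ExpressionSeries]):
        self._series: list[ExpressionSeries] = list(series)
        seen: set[str] = set()
        for s in self._series:
            if s.probe_id in seen:
                raise ValueError(f"duplicate probe_id {s.probe_id!r}")
            seen.add(s.probe_id)
        self._by_probe = {s.probe_id: s for s in self._series}

    def __len__(self) -> int:
        return len(self._series)

    def __iter__(self) -> Iterator[ExpressionSeries]:
        return iter(self._series)

    def __getitem__(self, index: int) -> ExpressionSeries:
        return self._series[index]

    def get(self, probe_id: str) -> ExpressionSeries:
        return self._by_probe[probe_id]

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self._by_probe

    @property
    def probe_ids(self) -> list[str]:
        return [s.probe_id for s in self._series]

    @property
    def probe_to_gene(self) -> dict[str, str]:
        return {s.probe_id: s.gene_id for s in self._series}


@dataclass(frozen=True)
class ProbePartition:
    """Disjoint assignment of probes to the standard / putative / non-HKG pools."""

    standard: frozenset[str]
    putative: frozenset[str]
    non_hkg: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "standard", frozenset(self.standard))
        object.__setattr__(self, "putative", frozenset(self.putative))
        object.__setattr__(self, "non_hkg", frozenset(self.non_hkg))
        if (
            self.standard & self.putative
            or self.standard & self.non_hkg
            or self.putative & self.non_hkg
        ):
            raise ValueError("partition pools must be pairwise disjoint")

    @property
    def all_probes(self) -> frozenset[str]:
        return self.standard | self.putative | self.non_hkg

    def pool_of(self, probe_id: str) -> str:
        if probe_id in self.standard:
            return "standard"
        if probe_id in self.putative:
            return "putative"
        if probe_id in self.non_hkg:
            return "non_hkg"
        raise KeyError(f"probe {probe_id!r} not in partition")


@dataclass(frozen=True)
class PredictionRecord:
    """One row of a predictions table (see :func:`write_predictions`)."""

    gene_id: str
    best_probe_id: str
    vote_count: int
    ballot_percent: float
    source_pool: str
    selected: bool


def _parse_cell(token: str, path: str, lineno: int) -> tuple[float, bool]:
    token = token.strip()
    if token.lower() in _MISSING_TOKENS:
        return math.nan, True
    try:
        value = float(token)
    except ValueError as exc:
        raise ValueError(f"{path}: line {lineno}: non-numeric cell {token!r}") from exc
    if math.isnan(value):
        return math.nan, True
    return value, False


def _looks_like_header(value_cells: Sequence[str]) -> bool:
    for cell in value_cells:
        cell = cell.strip()
        if cell.lower() in _MISSING_TOKENS:
            continue
        try:
            float(cell)
        except ValueError:
            return True
    return False


def read_series_matrix(path, expected_length: int) -> SeriesSet:
    """Parse a tab-separated (PCL-compatible) expression matrix.

    Parameters
    ----------
    path:
        File whose rows are ``probe_id <TAB> gene_id <TAB> v1 ... vN``.
    expected_length:
        Required number of value columns per row; a row with any other count
        raises :class:`ValueError` naming the offending line.
    """
    if expected_length <= 0:
        raise ValueError("expected_length must be positive")
    path = str(path)
    series: list[ExpressionSeries] = []
    gweight_col: int | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and len(fields) >= 3 and _looks_like_header(fields[2:]):
                # PCL header row: note a GWEIGHT column so data rows drop it.
                upper = [f.strip().upper() for f in fields]
                if "GWEIGHT" in upper:
                    gweight_col = upper.index("GWEIGHT")
                continue
            if fields[0].strip().upper() == "EWEIGHT":
                continue
            if gweight_col is not None and len(fields) > gweight_col:
                fields = fields[:gweight_col] + fields[gweight_col + 1:]
            if len(fields) - 2 != expected_length:
                raise ValueError(
                    f"{path}: line {lineno}: expected {expected_length} value "
                    f"columns, found {len(fields) - 2}"
                )
            probe_id = fields[0].strip()
            gene_id = fields[1].strip()
            if not probe_id:
                raise ValueError(f"{path}: line {lineno}: empty probe id")
            values = np.empty(expected_length)
            mask = np.zeros(expected_length, dtype=bool)
            for j, cell in enumerate(fields[2:]):
                values[j], mask[j] = _parse_cell(cell, path, lineno)
            series.append(
                ExpressionSeries(
                    probe_id=probe_id, gene_id=gene_id, values=values, missing_mask=mask
                )
            )
    try:
        return SeriesSet(series)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def read_gene_list(path) -> set[str]:
    """Read a plain-text gene list (one symbol per line, blanks ignored)."""
    with open(str(path), "r", encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


def partition_probes(
    series: SeriesSet,
    list1: Iterable[str],
    list2: Iterable[str],
    list3: Iterable[str],
) -> ProbePartition:
    """Assign each probe to a pool by how many reference lists hold its gene.

    Membership is tested on upper-cased gene symbols.  A probe whose gene
    appears in all three lists is *standard*, in one or two is *putative*,
    and in none (or has no gene symbol) is *non-HKG*.
    """
    folded = [{g.strip().upper() for g in lst} for lst in (list1, list2, list3)]
    standard, putative, non_hkg = set(), set(), set()
    for s in series:
        gene = s.gene_id.strip().upper()
        n_hits = sum(gene in lst for lst in folded) if gene else 0
        if n_hits == 3:
            standard.add(s.probe_id)
        elif n_hits >= 1:
            putative.add(s.probe_id)
        else:
            non_hkg.add(s.probe_id)
    return ProbePartition(
        standard=frozenset(standard),
        putative=frozenset(putative),
        non_hkg=frozenset(non_hkg),
    )


def write_predictions(result: Sequence, path) -> None:
    """Write predictions as a TSV sorted by descending vote count.

    ``result`` items need attributes ``gene_id``, ``best_probe_id``,
    ``best_count`` (or ``vote_count``), ``ballot_percent``, ``source_pool``
    and ``selected``.
    """
    rows = sorted(
        result,
        key=lambda r: (-getattr(r, "best_count", getattr(r, "vote_count", 0)), r.gene_id),
    )
    with open(str(path), "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PREDICTION_COLUMNS)
        for r in rows:
            count = getattr(r, "best_count", getattr(r, "vote_count", None))
            writer.writerow(
                [
                    r.gene_id,
                    r.best_probe_id,
                    int(count),
                    f"{float(r.ballot_percent):.2f}",
                    r.source_pool,
                    "true" if r.selected else "false",
                ]
            )


def read_predictions(path) -> list[PredictionRecord]:
    """Parse a file written by :func:`write_predictions` (round-trip inverse)."""
    records: list[PredictionRecord] = []
    with open(str(path), "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != PREDICTION_COLUMNS:
            raise ValueError(f"{path}: unexpected predictions header {header!r}")
        for row in reader:
            if len(row) != len(PREDICTION_COLUMNS):
                raise ValueError(f"{path}: malformed predictions row {row!r}")
            records.append(
                PredictionRecord(
                    gene_id=row[0],
                    best_probe_id=row[1],
                    vote_count=int(row[2]),
                    ballot_percent=float(row[3]),
                    source_pool=row[4],
                    selected=row[5] == "true",
                )
            )
    return records
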