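"""Core containers shared across the pipeline.

The pipeline passes around a small number of typed objects: an expression
matrix tagged with its scale (linear intensities vs log2), a ranked gene
list, a candidate panel (the GA search space), a per-measure archive of
generation-best GA solutions, and confusion counts for the fitness
measures.  All tabular payloads are pandas objects so that indexing,
alignment and TSV round-trips go through one well-tested code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LINEAR = "linear"
LOG2 = "log2"

#: the four informative measures usable as GA fitness, in canonical order
MEASURES = ("acc", "mcc", "f1", "hybrid")


class ValidationError(ValueError):
    """Raised when an input object violates a documented invariant."""


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with a scale tag.

    Parameters
    ----------
    data
        DataFrame indexed by gene id, columns are sample ids.
    scale
        Either ``"linear"`` (non-negative intensities) or ``"log2"``.
    """

    data: pd.DataFrame
    scale: str = LOG2

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise ValidationError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate gene identifiers")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate sample identifiers")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValidationError("expression values must be finite")
        if self.scale == LINEAR and values.size and (values < 0).any():
            raise ValidationError("linear-scale intensities must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class RankedGeneList:
    """Genes ordered by a per-gene statistic, descending.

    ``table`` has one row per gene, index = gene id, single column
    ``statistic``; the row order is the ranking (head = most overexpressed
    in the positive class).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        stat = self.table["statistic"].to_numpy()
        if np.any(np.diff(stat) > 0):
            raise ValidationError("statistics must be non-increasing in rank order")
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate gene identifiers in ranked list")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def statistic(self) -> pd.Series:
        return self.table["statistic"]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class EnrichmentResult:
    """Running-sum enrichment of one gene set against a ranked list."""

    set_name: str
    ec_score: float
    hit_positions: np.ndarray  # 0-based ranks of set members in the list


@dataclass
class CandidatePanel:
    """Ordered candidate genes, each tagged by its tail of origin.

    The panel defines the GA chromosome: bit *j* of a solution refers to
    ``table.index[j]``.  ``direction`` is ``"over"`` for head-of-list
    (overexpressed in the positive class) genes and ``"under"`` for
    tail-of-list genes.
    """

    table: pd.DataFrame  # index gene_id; columns: direction, statistic

    def __post_init__(self) -> None:
        bad = set(self.table["direction"]) - {"over", "under"}
        if bad:
            raise ValidationError(f"unknown panel directions: {sorted(bad)}")
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate gene identifiers in panel")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def directions(self) -> pd.Series:
        return self.table["direction"]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SolutionRecord:
    """One generation-best GA solution: bit vector plus its fitness."""

    bits: np.ndarray
    fitness: float


@dataclass
class SolutionArchive:
    """Per-measure generation-best solutions accumulated over GA repeats.

    ``records[measure]`` holds every generation-best record in the order
    collected (repeats x generations of them for a full run).  ``ranked``
    deduplicates identical bit vectors (first occurrence kept) and sorts by
    fitness descending.
    """

    panel_size: int
    records: dict[str, list[SolutionRecord]] = field(default_factory=dict)

    def add(self, measure: str, record: SolutionRecord) -> None:
        if record.bits.shape != (self.panel_size,):
            raise ValidationError("record bit-vector length does not match panel size")
        self.records.setdefault(measure, []).append(record)

    def ranked(self, measure: str, top_k: int | None = 10) -> list[SolutionRecord]:
        """Deduplicated records ranked by fitness descending.

        Ties keep first-collected order; with fewer than ``top_k`` unique
        solutions all of them are returned (the shortfall is visible from
        the result length).
        """
        seen: set[bytes] = set()
        unique: list[SolutionRecord] = []
        for rec in self.records.get(measure, []):
            key = np.packbits(rec.bits).tobytes()
            if key not in seen:
                seen.add(key)
                unique.append(rec)
        unique.sort(key=lambda r: -r.fitness)  # stable: ties keep collection order
        return unique if top_k is None else unique[:top_k]

    def shortfalls(self, top_k: int = 10) -> dict[str, int]:
        """Measures with fewer than ``top_k`` unique solutions, and how many."""
        out = {}
        for measure in self.records:
            n = len(self.ranked(measure, top_k))
            if n < top_k:
                out[measure] = n
        return out

    @property
    def measures(self) -> tuple[str, ...]:
        return tuple(self.records)


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table for a binary classifier (positive class = GBM)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValidationError("confusion table must contain at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ClassBalance:
    """Positive/negative sample counts; ``delta`` weights specificity."""

    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if self.n_neg < 1 or self.n_pos < 0:
            raise ValidationError("need n_neg >= 1 and n_pos >= 0")

    @property
    def delta(self) -> float:
        return self.n_pos / self.n_neg
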