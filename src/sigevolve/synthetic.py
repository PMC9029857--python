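"""Synthetic two-class microarray-like data with planted differential genes.

Emulates the kind of data the pipeline targets — log2 microarray
intensities for two tumor classes (positive class = GBM-like) — without
any download.  A configurable number of genes is planted as over- or
underexpressed in the positive class by a fixed log2 mean shift; all other
genes share their class means.  Noise is independent Gaussian in log2
space, which is a reasonable first-order model of log microarray
intensities; probe-level structure and batch effects are deliberately not
simulated.

A matching gene-set collection generator produces REACTOME-like sets, a
configurable fraction of which is enriched for the planted genes, so the
set-based screening stage can be exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import LINEAR, LOG2, ExpressionMatrix, ValidationError
from . import io as sio

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "gen_two_class_expression",
    "gen_gene_sets",
    "to_linear",
    "write_fixture_bundle",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of the two-class expression simulation.

    Defaults mirror the study design the generator emulates: 228
    positive-class (GBM) vs 148 negative-class (lower-grade glioma)
    samples, with 50 + 50 planted differential genes at a 2.0 log2-unit
    shift over unit-variance noise around a log2 baseline of 8.
    """

    n_pos: int = 228
    n_neg: int = 148
    n_genes: int = 2000
    n_up: int = 50
    n_down: int = 50
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pos", "n_neg", "n_genes", "n_up", "n_down"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_up + self.n_down > self.n_genes:
            raise ValidationError("n_up + n_down must not exceed n_genes")
        if not self.noise_sd > 0:
            raise ValidationError("noise_sd must be > 0")
        if self.n_pos + self.n_neg < 1:
            raise ValidationError("n_pos + n_neg must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Which gene ids were planted as over-/underexpressed."""

    planted_up: frozenset[str]
    planted_down: frozenset[str]

    def __post_init__(self) -> None:
        if self.planted_up & self.planted_down:
            raise ValidationError("planted_up and planted_down must be disjoint")

    @property
    def planted(self) -> frozenset[str]:
        return self.planted_up | self.planted_down


def _gene_ids(n: int) -> list[str]:
    width = max(6, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def gen_two_class_expression(
    design: SimulationDesign,
) -> tuple[ExpressionMatrix, pd.Series, GroundTruth]:
    """Simulate a log2 expression matrix, labels and the planted truth.

    Returns
    -------
    matrix
        log2-scale ``ExpressionMatrix`` with ``n_genes`` rows and
        ``n_pos + n_neg`` columns (positive-class columns first).
    labels
        int series over samples, 1 = positive class, 0 = negative.
    truth
        the planted over/under gene-id sets.
    """
    rng = np.random.default_rng(design.seed)
    genes = _gene_ids(design.n_genes)
    samples = [f"S{i + 1:04d}" for i in range(design.n_pos + design.n_neg)]
    labels = pd.Series(
        [1] * design.n_pos + [0] * design.n_neg, index=samples, name="label"
    )

    planted = rng.choice(design.n_genes, size=design.n_up + design.n_down, replace=False)
    up_idx, down_idx = planted[: design.n_up], planted[design.n_up :]

    means = np.full((design.n_genes, len(samples)), design.baseline_mean)
    pos_cols = np.flatnonzero(labels.to_numpy() == 1)
    means[np.ix_(up_idx, pos_cols)] += design.effect_size
    means[np.ix_(down_idx, pos_cols)] -= design.effect_size

    values = means + rng.normal(0.0, design.noise_sd, size=means.shape)
    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), LOG2)
    truth = GroundTruth(
        planted_up=frozenset(genes[i] for i in up_idx),
        planted_down=frozenset(genes[i] for i in down_idx),
    )
    return matrix, labels, truth


def to_linear(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Exponentiate a log2 matrix to the linear-intensity scale."""
    if matrix.scale != LOG2:
        raise ValidationError("to_linear expects a log2-scale matrix")
    return ExpressionMatrix(np.exp2(matrix.data), LINEAR)


def gen_gene_sets(
    gene_ids,
    truth: GroundTruth,
    n_sets: int = 50,
    size_min: int = 15,
    size_max: int = 50,
    enriched_fraction: float = 0.3,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Generate a REACTOME-like gene-set collection.

    A fraction ``enriched_fraction`` of sets draws at least half of its
    members from the planted genes (capped by how many planted genes
    exist); the rest of each set, and all of every non-enriched set, is
    drawn uniformly without replacement from the gene universe.
    """
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ValidationError("empty gene universe")
    if not (0 < size_min <= size_max <= len(gene_ids)):
        raise ValidationError("need 0 < size_min <= size_max <= len(gene_ids)")
    rng = np.random.default_rng(seed)
    planted = sorted(truth.planted & set(gene_ids))
    others = sorted(set(gene_ids) - set(planted))
    n_enriched = round(enriched_fraction * n_sets)

    sets: dict[str, list[str]] = {}
    width = max(3, len(str(n_sets)))
    for k in range(n_sets):
        size = int(rng.integers(size_min, size_max + 1))
        if k < n_enriched and planted:
            n_from_planted = min(math.ceil(size / 2), len(planted))
            chosen = list(rng.choice(planted, size=n_from_planted, replace=False))
            pool = others if len(others) >= size - n_from_planted else gene_ids
            remainder = [g for g in pool if g not in chosen]
            chosen += list(rng.choice(remainder, size=size - n_from_planted, replace=False))
        else:
            chosen = list(rng.choice(gene_ids, size=size, replace=False))
        sets[f"SET{k + 1:0{width}d}"] = chosen
    return sets


def write_fixture_bundle(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    sets: dict[str, list[str]],
    out_dir,
) -> dict[str, str]:
    """Write expression TSV + labels CSV + GMT (+ manifest) to ``out_dir``.

    Returns the mapping of artifact name to file path.  The files
    round-trip losslessly through the readers in :mod:`sigevolve.io`.
    """
    from pathlib import Path

    if matrix.data.empty:
        raise ValidationError("refusing to write an empty expression matrix")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": str(out / "expression.tsv"),
        "labels": str(out / "labels.csv"),
        "gene_sets": str(out / "gene_sets.gmt"),
    }
    sio.write_expression_tsv(matrix, paths["expression"])
    sio.write_labels_csv(labels, paths["labels"])
    sio.write_gmt(sets, paths["gene_sets"])
    return paths
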