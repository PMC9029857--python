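"""Selective scoring and signature extraction from GA solution archives.

Each candidate gene j receives a selective score

    r_j = (1/4) * sum over the 4 measures of
          [ (1/10) * sum_{q=1..10} f_j^q + (1/5) * sum_{q=1..5} f_j^q + f_j^1 ]

where f_j^q is gene j's inclusion bit in the q-th ranked (deduplicated)
solution under that measure.  The three nested averages weight agreement
among the top 10, top 5 and single best solution, so r_j ranges over
[0, 3] and equals 3 only for a gene present in every counted solution of
every measure.  Genes with r_j >= 2 (default) form the signature; two
independent runs (e.g. two dataset designs) are combined by union with an
explicit intersection listing.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import (
    MEASURES,
    CandidatePanel,
    ExpressionMatrix,
    SolutionArchive,
    ValidationError,
)

__all__ = [
    "selective_scores",
    "extract_signature",
    "combine_runs",
    "export_heatmap_matrix",
]

DEFAULT_THRESHOLD = 2.0
_DEPTHS = (10, 5, 1)


def selective_scores(
    archive: SolutionArchive, gene_ids=None, measures: tuple[str, ...] = MEASURES
) -> pd.DataFrame:
    """Per-gene selective scores from an archive's ranked solutions.

    Returns a DataFrame indexed by panel gene (ids if given, else panel
    positions) with one column per measure (that measure's contribution,
    in [0, 3]) and a ``score`` column holding r_j, their mean.  Ranks
    missing from a short archive contribute 0.
    """
    if not archive.records:
        raise ValidationError("empty solution archive")
    short = archive.shortfalls(max(_DEPTHS))
    if short:
        warnings.warn(
            f"fewer than {max(_DEPTHS)} unique solutions for {short}; "
            "missing ranks contribute 0",
            stacklevel=2,
        )
    n = archive.panel_size
    if gene_ids is not None and len(gene_ids) != n:
        raise ValidationError("gene_ids length does not match panel size")
    index = pd.Index(gene_ids) if gene_ids is not None else pd.RangeIndex(n)

    per_measure = {}
    for measure in measures:
        top = archive.ranked(measure, max(_DEPTHS))
        bits = np.zeros((max(_DEPTHS), n))
        for q, rec in enumerate(top):
            bits[q] = rec.bits
        per_measure[measure] = sum(bits[:d].sum(axis=0) / d for d in _DEPTHS)

    table = pd.DataFrame(per_measure, index=index)
    table["score"] = table[list(measures)].mean(axis=1)
    return table


def extract_signature(
    scores: pd.DataFrame,
    panel: CandidatePanel,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Genes scoring at or above the threshold, with their panel direction.

    Sorted by score descending, ties by gene id; an empty signature is a
    legitimate result.
    """
    if not 0 <= threshold <= 3:
        raise ValidationError("threshold must be in [0, 3]")
    table = scores.copy()
    if isinstance(table.index, pd.RangeIndex):
        table.index = panel.gene_ids
    kept = table.loc[table["score"] >= threshold, ["score"]]
    kept["direction"] = panel.directions.reindex(kept.index)
    kept = kept.sort_values(["score", "direction"], ascending=[False, True], kind="stable")
    kept = kept.iloc[np.lexsort((kept.index.to_numpy(), -kept["score"].to_numpy()))]
    return kept


def combine_runs(sig_a: pd.DataFrame, sig_b: pd.DataFrame) -> dict:
    """Union/intersection report for two signature runs.

    Returns a dict with the union ``table`` (per-gene score and direction
    per run, membership flags, direction-conflict flag), the
    ``intersection`` gene list and per-run over/under counts.  A gene
    selected with opposite directions in the two runs is flagged, never
    dropped.
    """
    union = sorted(set(sig_a.index) | set(sig_b.index))
    table = pd.DataFrame(index=pd.Index(union, name="gene_id"))
    table["in_a"] = table.index.isin(sig_a.index)
    table["in_b"] = table.index.isin(sig_b.index)
    table["score_a"] = sig_a["score"].reindex(table.index)
    table["score_b"] = sig_b["score"].reindex(table.index)
    table["direction_a"] = sig_a["direction"].reindex(table.index)
    table["direction_b"] = sig_b["direction"].reindex(table.index)
    table["direction"] = table["direction_a"].fillna(table["direction_b"])
    both = table.in_a & table.in_b
    table["conflict"] = both & (table.direction_a != table.direction_b)

    def _counts(sig: pd.DataFrame) -> dict:
        vc = sig["direction"].value_counts()
        return {"over": int(vc.get("over", 0)), "under": int(vc.get("under", 0))}

    return {
        "table": table,
        "intersection": list(table.index[both]),
        "union_size": len(table),
        "intersection_size": int(both.sum()),
        "counts": {"a": _counts(sig_a), "b": _counts(sig_b)},
        "conflicts": list(table.index[table.conflict]),
    }


def export_heatmap_matrix(
    matrix: ExpressionMatrix,
    signature: pd.DataFrame,
    labels: pd.Series,
) -> pd.DataFrame:
    """Signature-gene submatrix arranged for heatmap display.

    Rows are the signature genes, overexpressed block first; columns are
    grouped positive class then negative; each row is z-scaled (mean 0,
    sd 1 across samples).
    """
    missing = [g for g in signature.index if g not in matrix.gene_ids]
    if missing:
        raise ValidationError(f"signature genes absent from matrix: {missing}")
    order = list(signature.index[signature["direction"] == "over"]) + list(
        signature.index[signature["direction"] != "over"]
    )
    labels = labels.reindex(matrix.sample_ids)
    cols = list(matrix.sample_ids[labels == 1]) + list(matrix.sample_ids[labels == 0])
    sub = matrix.data.loc[order, cols]
    centered = sub.sub(sub.mean(axis=1), axis=0)
    sd = sub.std(axis=1, ddof=0).replace(0.0, 1.0)
    return centered.div(sd, axis=0)
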