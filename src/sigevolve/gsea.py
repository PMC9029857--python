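"""GSEA-style candidate screening.

Genes are ranked by the signal-to-noise ratio between the two phenotype
classes, (mu_pos - mu_neg) / (sigma_pos + sigma_neg), with the usual
standard-deviation floor to keep low-variance genes from dominating.
Each gene set is then walked down the ranked list with a running sum that
rises at set members (weighted by |statistic|^w, normalized to total 1)
and falls by 1/(N - |S|) at non-members; the enrichment (EC) score is the
maximum value the running sum attains.  The screening output is a
candidate panel: the top and bottom n genes of the ranked list (tagged
"over"/"under"), optionally restricted to members of positively enriched
sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    LOG2,
    CandidatePanel,
    EnrichmentResult,
    ExpressionMatrix,
    RankedGeneList,
    ValidationError,
)

__all__ = ["signal_to_noise", "rank_genes", "enrichment_score", "screen_candidates"]

# GSEA's variance stabilisation for the signal-to-noise statistic
SD_MIN_FRACTION = 0.2   # sigma floored at this fraction of |mean|
SD_MIN_ABSOLUTE = 0.2   # and never below this absolute value


def _floored_sd(values: np.ndarray, axis: int) -> np.ndarray:
    sd = values.std(axis=axis, ddof=1)
    mean = values.mean(axis=axis)
    return np.maximum(sd, np.maximum(SD_MIN_FRACTION * np.abs(mean), SD_MIN_ABSOLUTE))


def signal_to_noise(matrix: ExpressionMatrix, labels: pd.Series) -> pd.Series:
    """Per-gene signal-to-noise statistic; positive = up in the positive class.

    Both classes need at least 2 samples for a standard deviation.
    """
    if matrix.scale != LOG2:
        raise ValidationError("signal_to_noise expects log2-scale expression")
    labels = labels.reindex(matrix.sample_ids)
    if labels.isna().any():
        raise ValidationError("labels missing for some samples")
    y = labels.to_numpy().astype(int)
    values = matrix.data.to_numpy()
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValidationError(
            f"each class needs >= 2 samples (got {n_pos} positive, {n_neg} negative)"
        )
    pos, neg = values[:, y == 1], values[:, y == 0]
    stat = (pos.mean(axis=1) - neg.mean(axis=1)) / (
        _floored_sd(pos, 1) + _floored_sd(neg, 1)
    )
    return pd.Series(stat, index=matrix.gene_ids, name="statistic")


def rank_genes(statistic: pd.Series) -> RankedGeneList:
    """Order genes by statistic descending; ties broken by gene id."""
    order = np.lexsort((statistic.index.to_numpy(), -statistic.to_numpy()))
    table = statistic.iloc[order].rename("statistic").to_frame()
    return RankedGeneList(table)


def enrichment_score(
    ranked: RankedGeneList,
    gene_set,
    weight_exponent: float = 1.0,
    set_name: str = "",
    max_abs: bool = False,
) -> EnrichmentResult:
    """Running-sum enrichment of ``gene_set`` against the ranked list.

    With ``weight_exponent`` 0 the increment at every member is 1/|S|
    (the unweighted statistic); the default 1 weights members by the
    magnitude of their ranking statistic.  The EC score is the signed
    maximum of the running sum, or the maximum-deviation value when
    ``max_abs`` is set.
    """
    members = set(gene_set) & set(ranked.gene_ids)
    if not members:
        raise ValidationError(f"gene set {set_name!r} has no genes in the ranked universe")
    n = len(ranked)
    if len(members) == n:
        raise ValidationError("gene set covers the whole universe; EC score undefined")

    is_member = ranked.gene_ids.isin(members)
    stat = ranked.statistic.to_numpy()
    weights = np.abs(stat[is_member]) ** weight_exponent
    total = weights.sum()
    steps = np.full(n, -1.0 / (n - len(members)))
    if total > 0:
        steps[is_member] = weights / total
    else:  # all member weights zero (e.g. statistic exactly 0): fall back to equal steps
        steps[is_member] = 1.0 / len(members)
    running = np.cumsum(steps)
    if max_abs:
        ec = float(running[np.argmax(np.abs(running))])
    else:
        ec = float(running.max())
    return EnrichmentResult(
        set_name=set_name, ec_score=ec, hit_positions=np.flatnonzero(is_member)
    )


def screen_candidates(
    ranked: RankedGeneList,
    gene_sets: dict[str, list[str]] | None = None,
    n_per_tail: int = 50,
    restrict_to_sets: bool = True,
    weight_exponent: float = 1.0,
) -> CandidatePanel:
    """Pick the top/bottom ``n_per_tail`` genes as the candidate panel.

    Head genes are tagged ``over`` (overexpressed in the positive class),
    tail genes ``under``.  With ``restrict_to_sets`` on, only genes that
    belong to at least one gene set with positive EC score are eligible —
    the set-based screening analogue of restricting to annotated pathway
    genes.  Raises when fewer eligible genes exist than requested.
    """
    if len(ranked) < 2 * n_per_tail:
        raise ValidationError(
            f"ranked list has {len(ranked)} genes; need >= {2 * n_per_tail}"
        )
    if restrict_to_sets:
        if not gene_sets:
            raise ValidationError("restrict_to_sets requires a gene-set collection")
        eligible: set[str] = set()
        for name, members in gene_sets.items():
            if not set(members) & set(ranked.gene_ids):
                continue
            res = enrichment_score(ranked, members, weight_exponent, set_name=name)
            if res.ec_score > 0:
                eligible.update(set(members) & set(ranked.gene_ids))
    else:
        eligible = set(ranked.gene_ids)

    mask = ranked.gene_ids.isin(eligible)
    idx = np.flatnonzero(mask)
    if idx.size < 2 * n_per_tail:
        raise ValidationError(
            f"only {idx.size} eligible genes for a panel of {2 * n_per_tail} "
            f"(short by {2 * n_per_tail - idx.size})"
        )
    head, tail = idx[:n_per_tail], idx[-n_per_tail:]
    rows = ranked.table.iloc[np.concatenate([head, tail])].copy()
    rows["direction"] = ["over"] * n_per_tail + ["under"] * n_per_tail
    return CandidatePanel(rows[["direction", "statistic"]])
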