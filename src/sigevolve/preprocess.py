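"""Array normalization: per-sample trimmed-mean linear scaling and log2.

Raw microarray intensities are first brought onto a common scale by
multiplying each sample (array) by the factor that sets its two-sided
trimmed mean to a fixed target intensity — the linear-scaling step of
MAS5-style processing, applied here at the gene level (target 500, trim
2% by convention).  Values are then log2-transformed with a floor of 1 so
that zero intensities map to 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import trim_mean

from .datatypes import LINEAR, LOG2, ExpressionMatrix, ValidationError

__all__ = ["linear_scale", "log2_transform"]

DEFAULT_TARGET_INTENSITY = 500.0
DEFAULT_TRIM_FRACTION = 0.02
DEFAULT_LOG_FLOOR = 1.0


def linear_scale(
    matrix: ExpressionMatrix,
    target_intensity: float = DEFAULT_TARGET_INTENSITY,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
) -> ExpressionMatrix:
    """Scale each sample so its two-sided trimmed mean equals the target.

    Purely multiplicative per sample, hence idempotent and rank-preserving
    within each sample.  A sample whose trimmed mean is zero (e.g. an
    all-zero array) has no defined scale factor and raises.
    """
    if matrix.scale != LINEAR:
        raise ValidationError("linear_scale expects a linear-scale matrix")
    if not 0 <= trim_fraction < 0.5:
        raise ValidationError("trim_fraction must be in [0, 0.5)")
    if not target_intensity > 0:
        raise ValidationError("target_intensity must be > 0")

    trimmed = trim_mean(matrix.data.to_numpy(), trim_fraction, axis=0)
    zero = np.flatnonzero(trimmed <= 0)
    if zero.size:
        bad = matrix.sample_ids[zero[0]]
        raise ValidationError(f"sample {bad!r} has non-positive trimmed mean; scale factor undefined")
    factors = target_intensity / trimmed
    scaled = matrix.data * factors  # broadcasts over columns
    return ExpressionMatrix(scaled, LINEAR)


def log2_transform(
    matrix: ExpressionMatrix, floor: float = DEFAULT_LOG_FLOOR
) -> ExpressionMatrix:
    """log2(max(value, floor)); flips the scale tag to log2.

    Applying it to an already-log2 matrix raises (double-transform guard).
    """
    if matrix.scale == LOG2:
        raise ValidationError("matrix is already on the log2 scale")
    if not floor > 0:
        raise ValidationError("floor must be > 0")
    values = np.log2(np.maximum(matrix.data, floor))
    return ExpressionMatrix(pd.DataFrame(values, index=matrix.gene_ids, columns=matrix.sample_ids), LOG2)
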