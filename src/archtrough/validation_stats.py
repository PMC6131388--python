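"""Agreement statistics: dice coefficient and intraclass correlation.

The ICC form is fixed to the two-way random, absolute-agreement,
single-measure coefficient ICC(2,1): targets and raters are both treated
as random samples, and systematic offsets between raters count against
agreement - the appropriate choice when the measurements are coordinates
that must coincide, not merely correlate.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dice", "icc"]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) of two same-shape binary masks.

    Two empty masks are in perfect agreement (1.0).
    """
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def icc(table: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``table`` is an (n targets x k raters) matrix with no missing cells.
    From the two-way ANOVA mean squares (rows MSR, columns MSC, residual
    MSE)::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    x = np.asarray(table, float)
    if x.ndim != 2:
        raise ValueError("ratings table must be 2-D (targets x raters)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 targets and 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings table contains missing or non-finite cells")
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("zero total variance: ICC undefined")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("degenerate ANOVA decomposition: ICC undefined")
    return float((msr - mse) / denom)
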