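"""Expressed-and-variable gene selection.

Two filters applied in sequence before any clustering:

1. background — keep a gene iff its maximum log2 value across samples reaches
   the background threshold (default 1.2). Using the max (rather than the
   mean) keeps subgroup-specific markers that are silent elsewhere.
2. variability — among background-passing genes, keep those whose relative
   interquartile range RIQR = max(Q3 − Q2, Q2 − Q1) / Q2 reaches the
   variability threshold (default 0.75). Quartiles use linear interpolation
   between order statistics at rank (n − 1)·p.

RIQR is a *relative* spread: a gene must vary by a large fraction of its own
median to survive, which favours on/off marker genes over uniformly high,
mildly wobbling ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

RIQR_FORMULAS = ("symmetric", "methods", "figure")


def _riqr_from_quartiles(q1, q2, q3, formula: str = "symmetric"):
    q1, q2, q3 = (np.asarray(q, dtype=float) for q in (q1, q2, q3))
    if formula == "symmetric":
        spread = np.maximum(q3 - q2, q2 - q1)
    elif formula == "methods":   # literal transcription variant A
        spread = np.maximum(q3 - q2, q1 - q3)
    elif formula == "figure":    # literal transcription variant B
        spread = np.maximum(q3 - q2, q1 - q2)
    else:
        raise ValueError(f"unknown RIQR formula {formula!r}; choose from {RIQR_FORMULAS}")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(q2 == 0, np.nan, spread / np.where(q2 == 0, 1.0, q2))
    return out


def riqr(values, formula: str = "symmetric") -> float:
    """Relative IQR of one gene's values across samples.

    Returns NaN (undefined) when the median is zero. Requires ≥ 3 values so
    all three quartiles are informative.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("riqr requires a 1-D vector of length >= 3")
    q1, q2, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # linear interpolation at (n-1)p
    return float(_riqr_from_quartiles(q1, q2, q3, formula))


def gene_filter_report(
    matrix: ExpressionMatrix,
    background: float = 1.2,
    riqr_threshold: float = 0.75,
    background_stat: str = "max",
    riqr_formula: str = "symmetric",
) -> pd.DataFrame:
    """Per-gene filter statistics and pass flags, one row per input gene."""
    if matrix.n_samples < 3:
        raise ValueError("filtering requires at least 3 samples per gene")
    X = matrix.values.to_numpy(dtype=float)
    q1, q2, q3 = np.quantile(X, [0.25, 0.5, 0.75], axis=1)
    if background_stat == "max":
        level = X.max(axis=1)
    elif background_stat == "mean":
        level = X.mean(axis=1)
    else:
        raise ValueError(f"unknown background statistic {background_stat!r}")
    r = _riqr_from_quartiles(q1, q2, q3, riqr_formula)
    passed_bg = level >= background
    # undefined RIQR (median 0) fails variability but never aborts a run
    passed_var = passed_bg & ~np.isnan(r) & (r >= riqr_threshold)
    return pd.DataFrame(
        {
            "max_log2": X.max(axis=1),
            "q1": q1,
            "q2": q2,
            "q3": q3,
            "riqr": r,
            "passed_background": passed_bg,
            "passed_variability": passed_var,
        },
        index=matrix.gene_ids,
    )


def apply_filters(
    matrix: ExpressionMatrix,
    background: float = 1.2,
    riqr_threshold: float = 0.75,
    background_stat: str = "max",
    riqr_formula: str = "symmetric",
):
    """Apply both filters; return (filtered matrix, full report).

    The output matrix holds exactly the genes with both flags true, in their
    original order. Raises if no gene survives, since downstream clustering
    would be undefined.
    """
    report = gene_filter_report(
        matrix, background, riqr_threshold, background_stat, riqr_formula
    )
    keep = report.index[report["passed_variability"]]
    if len(keep) == 0:
        raise ValueError(
            "no genes survive filtering; review the background "
            f"({background}) and RIQR ({riqr_threshold}) thresholds"
        )
    return matrix.subset_genes(keep), report
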