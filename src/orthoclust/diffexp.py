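"""Per-gene two-group Welch tests, BH adjustment, fold change and signatures.

Fold change is the difference of group means of log2 expression, so the
default cut |FC| >= 1.2 corresponds to a linear ratio of 2**1.2 ≈ 2.30.
Significance defaults to the BH-adjusted q <= 0.05; the raw-p variant used in
some figure legends is available via ``adjust=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float
    degenerate: bool = False


def welch_test(a, b) -> WelchResult:
    """Welch's unequal-variance t-test, two-sided.

    t = (ā − b̄) / sqrt(s²_a/n_a + s²_b/n_b), with Welch–Satterthwaite df.
    When both sample variances are zero the statistic is undefined; by
    convention p = 1 if the means agree, else p = 0, flagged as degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_test requires at least 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return WelchResult(0.0, np.nan, 1.0, degenerate=True)
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return WelchResult(sign * np.inf, np.nan, 0.0, degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def _welch_rows(A: np.ndarray, B: np.ndarray):
    """Row-wise Welch tests: A (genes × n_a) vs B (genes × n_b)."""
    res = stats.ttest_ind(A, B, axis=1, equal_var=False)
    t = np.array(res.statistic, dtype=float)
    df = np.array(res.df, dtype=float)
    p = np.array(res.pvalue, dtype=float)
    va = A.var(axis=1, ddof=1)
    vb = B.var(axis=1, ddof=1)
    degen = (va == 0) & (vb == 0)
    if degen.any():
        mean_diff = A[degen].mean(axis=1) - B[degen].mean(axis=1)
        means_equal = mean_diff == 0
        with np.errstate(invalid="ignore"):
            t[degen] = np.where(means_equal, 0.0, np.sign(mean_diff) * np.inf)
        p[degen] = np.where(means_equal, 1.0, 0.0)
        df[degen] = np.nan
    return t, df, p, degen


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _resolve_labels(matrix: ExpressionMatrix, labels) -> pd.Series:
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    labels = pd.Series(labels)
    labels = labels.loc[labels.index.intersection(matrix.sample_ids)]
    return labels.astype(str)


def differential_table(
    matrix: ExpressionMatrix,
    labels,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    min_abs_fc: float = 1.2,
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-gene Welch test of group_a vs group_b with BH adjustment.

    ``labels`` maps sample ids to group labels. fc = mean_a − mean_b on the
    log2 scale. ``passes`` requires significance (q, or raw p when
    ``adjust=False``) at ``alpha`` and |fc| >= ``min_abs_fc``.
    """
    labels = _resolve_labels(matrix, labels)
    samples_a = labels.index[labels == str(group_a)]
    samples_b = labels.index[labels == str(group_b)]
    for name, s in ((group_a, samples_a), (group_b, samples_b)):
        if len(s) < 2:
            raise ValueError(f"group {name!r} has {len(s)} sample(s); need >= 2")
    A = matrix.values[samples_a].to_numpy(dtype=float)
    B = matrix.values[samples_b].to_numpy(dtype=float)
    t, df, p, degen = _welch_rows(A, B)
    q = bh_adjust(p)
    fc = A.mean(axis=1) - B.mean(axis=1)
    crit = q if adjust else p
    passes = (crit <= alpha) & (np.abs(fc) >= min_abs_fc)
    return pd.DataFrame(
        {
            "mean_a": A.mean(axis=1),
            "mean_b": B.mean(axis=1),
            "fc": fc,
            "t": t,
            "df": df,
            "p": p,
            "q": q,
            "degenerate": degen,
            "passes": passes,
        },
        index=matrix.gene_ids,
    )


@dataclass
class SignatureSet:
    """Per-group lists of specifically overexpressed genes, plus thresholds."""

    signatures: dict
    alpha: float
    min_fc: float
    adjusted: bool

    def counts(self) -> dict:
        return {g: len(v) for g, v in self.signatures.items()}


def group_signatures(
    matrix: ExpressionMatrix,
    labels,
    alpha: float = 0.05,
    min_fc: float = 1.2,
    adjust: bool = True,
) -> SignatureSet:
    """Genes whose higher expression specifically defines each group.

    A gene belongs to signature(G) iff in *every* pairwise Welch comparison
    of G against each other group it is significant with fc >= +min_fc in
    G's favour. Each pairwise comparison is BH-adjusted on its own.
    Signatures of different groups are necessarily disjoint.
    """
    labels = _resolve_labels(matrix, labels)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("group_signatures requires at least 2 groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    # one table per unordered pair, reused with a sign flip
    tables = {}
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            tables[(ga, gb)] = differential_table(
                matrix, labels, ga, gb, alpha=alpha, min_abs_fc=min_fc, adjust=adjust
            )
    signatures = {}
    for g in groups:
        member = pd.Series(True, index=matrix.gene_ids)
        for h in groups:
            if h == g:
                continue
            tab, sign = (tables[(g, h)], 1.0) if (g, h) in tables else (tables[(h, g)], -1.0)
            crit = tab["q"] if adjust else tab["p"]
            member &= (crit <= alpha) & (sign * tab["fc"] >= min_fc)
        signatures[g] = list(matrix.gene_ids[member])
    return SignatureSet(signatures, alpha=alpha, min_fc=min_fc, adjusted=adjust)


def ddct(
    ct_target_sample: float,
    ct_control_sample: float,
    ct_target_calibrator: float,
    ct_control_calibrator: float,
) -> float:
    """Relative quantity by the 2^−ΔΔCt method.

    ΔΔCt = (Ct_target − Ct_control)_sample − (Ct_target − Ct_control)_calibrator,
    where the control is the internal-control gene.
    """
    ddct_val = (ct_target_sample - ct_control_sample) - (
        ct_target_calibrator - ct_control_calibrator
    )
    return float(2.0 ** (-ddct_val))
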