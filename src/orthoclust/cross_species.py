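"""Cross-species comparison: AGDEX agreement and centroid correlation.

The agreement-of-differential-expression (AGDEX) statistic compares, between
two species, the per-gene differential vectors d = mean(tumour group) −
mean(reference tissue) over 1:1-matched orthologs, as their cosine:

    score = Σ dA_i·dB_i / sqrt(Σ dA_i² · Σ dB_i²)  ∈ [−1, 1].

Significance comes from a permutation null (random permutation of one
vector over the ortholog index), two-sided with the add-one rule so p is
never zero; small cases are enumerated exhaustively.

Centroid correlation relates tumour-group mean profiles to reference
stem/progenitor profiles by plain Pearson r over a shared gene universe.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, OrthologMap, to_1to1

logger = logging.getLogger(__name__)

EXHAUSTIVE_LIMIT = 8  # n! permutations are enumerated up to this length


@dataclass
class DiffVector:
    """Per-gene mean log2 difference of a tumour group vs a reference tissue."""

    gene_ids: pd.Index
    d: np.ndarray
    species: str
    group: str
    reference: str

    def as_series(self) -> pd.Series:
        return pd.Series(self.d, index=self.gene_ids)


def diff_vector(
    matrix: ExpressionMatrix,
    tumour_samples,
    reference_samples,
    group: str = "",
    reference: str = "",
) -> DiffVector:
    """d_g = mean over tumour samples − mean over reference samples, per gene."""
    tumour_samples = list(tumour_samples)
    reference_samples = list(reference_samples)
    if not tumour_samples or not reference_samples:
        raise ValueError("both tumour and reference sample sets must be non-empty")
    for side, s in (("tumour", tumour_samples), ("reference", reference_samples)):
        if len(s) < 2:
            logger.info("diff_vector: %s side has a single sample", side)
    t = matrix.values[tumour_samples].to_numpy(dtype=float).mean(axis=1)
    r = matrix.values[reference_samples].to_numpy(dtype=float).mean(axis=1)
    return DiffVector(matrix.gene_ids, t - r, matrix.species, str(group), str(reference))


def match_orthologs(dA: DiffVector, dB: DiffVector, omap: OrthologMap):
    """Pair two diff vectors through a 1:1 ortholog map.

    Keeps exactly the pairs with both genes present, ordered by the
    species-A identifier. Returns (a, b, pairs) with matched numpy vectors.
    """
    reduced = to_1to1(omap)
    if len(reduced) != len(omap.pairs.drop_duplicates()):
        raise ValueError("ortholog map must be reduced to 1:1 before matching")
    pairs = reduced.pairs
    in_a = pairs["gene_a"].isin(dA.gene_ids)
    in_b = pairs["gene_b"].isin(dB.gene_ids)
    dropped = int((~(in_a & in_b)).sum())
    if dropped:
        logger.info("match_orthologs: dropped %d pair(s) absent from a vector", dropped)
    kept = pairs.loc[in_a & in_b].sort_values("gene_a", kind="stable").reset_index(drop=True)
    if len(kept) == 0:
        raise ValueError("no ortholog pairs matched between the two diff vectors")
    a = dA.as_series().loc[kept["gene_a"]].to_numpy()
    b = dB.as_series().loc[kept["gene_b"]].to_numpy()
    return a, b, kept


def agdex_score(a, b) -> float:
    """Cosine agreement of two matched differential vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("vectors must be 1-D, equal length >= 2")
    na = float(np.dot(a, a))
    nb = float(np.dot(b, b))
    if na == 0.0 or nb == 0.0:
        logger.warning("agdex_score undefined: an all-zero vector")
        return float("nan")
    return float(np.dot(a, b) / math.sqrt(na * nb))


def agdex_permutation_p(a, b, n_perm: int = 1000, seed: int = 0) -> float:
    """Two-sided permutation p-value for the agreement score.

    The null permutes b over the ortholog index; p uses the add-one rule
    (1 + #{|score_perm| >= |score_obs|}) / (N + 1). Up to 8 genes the n!
    permutations are enumerated exhaustively instead of sampled.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs = abs(agdex_score(a, b))
    if math.isnan(obs):
        return float("nan")
    if a.size <= EXHAUSTIVE_LIMIT:
        count = 0
        total = 0
        for perm in itertools.permutations(range(a.size)):
            total += 1
            if abs(agdex_score(a, b[list(perm)])) >= obs - 1e-12:
                count += 1
        return (1 + count) / (total + 1)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if abs(agdex_score(a, rng.permutation(b))) >= obs - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


@dataclass
class AgdexResult:
    """Agreement score and permutation significance for one group pair."""

    group_a: str
    group_b: str
    score: float
    n_orthologs: int
    p_perm: float
    n_perm: int
    seed: int


def agdex_pair(
    dA: DiffVector, dB: DiffVector, omap: OrthologMap, n_perm: int = 1000, seed: int = 0
) -> AgdexResult:
    a, b, pairs = match_orthologs(dA, dB, omap)
    return AgdexResult(
        group_a=dA.group,
        group_b=dB.group,
        score=agdex_score(a, b),
        n_orthologs=len(pairs),
        p_perm=agdex_permutation_p(a, b, n_perm=n_perm, seed=seed),
        n_perm=n_perm,
        seed=seed,
    )


def agdex_matrix(
    matrix_a: ExpressionMatrix,
    groups_a: dict,
    reference_a,
    matrix_b: ExpressionMatrix,
    groups_b: dict,
    reference_b,
    omap: OrthologMap,
    n_perm: int = 1000,
    seed: int = 0,
):
    """AGDEX score/p for every (group_a, group_b) pair.

    ``groups_*`` map group label -> list of tumour sample ids; ``reference_*``
    are the reference-tissue sample ids of each species. Returns
    (score DataFrame, p DataFrame, list of AgdexResult).
    """
    vecs_a = {
        g: diff_vector(matrix_a, s, reference_a, group=g, reference="reference")
        for g, s in groups_a.items()
    }
    vecs_b = {
        g: diff_vector(matrix_b, s, reference_b, group=g, reference="reference")
        for g, s in groups_b.items()
    }
    rows = sorted(groups_a)
    cols = sorted(groups_b)
    scores = pd.DataFrame(index=rows, columns=cols, dtype=float)
    pvals = pd.DataFrame(index=rows, columns=cols, dtype=float)
    results = []
    for i, ga in enumerate(rows):
        for j, gb in enumerate(cols):
            try:
                res = agdex_pair(
                    vecs_a[ga], vecs_b[gb], omap,
                    n_perm=n_perm, seed=int(seed) + 1000 * i + j,
                )
            except ValueError as exc:
                raise ValueError(f"AGDEX failed for pair ({ga}, {gb}): {exc}") from exc
            scores.loc[ga, gb] = res.score
            pvals.loc[ga, gb] = res.p_perm
            results.append(res)
    return scores, pvals, results


def centroid_correlation(
    tumour_matrix: ExpressionMatrix,
    tumour_groups: dict,
    reference_matrix: ExpressionMatrix,
    reference_sets: dict,
    gene_ids=None,
    zscore: bool = False,
) -> pd.DataFrame:
    """Pearson r between tumour-group centroids and reference-set centroids.

    Centroids are mean log2 profiles over the shared gene universe (the
    intersection of the two matrices' genes, optionally restricted to
    ``gene_ids`` — typically the expressed-and-variable genes). ``zscore``
    standardises each gene across the pooled centroids first, an option for
    cross-platform comparisons.
    """
    shared = tumour_matrix.gene_ids.intersection(reference_matrix.gene_ids)
    if gene_ids is not None:
        shared = shared.intersection(pd.Index(gene_ids))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared gene(s); need >= 3")
    cent_t = {
        g: tumour_matrix.values.loc[shared, list(s)].mean(axis=1)
        for g, s in tumour_groups.items()
    }
    cent_r = {
        t: reference_matrix.values.loc[shared, list(s)].mean(axis=1)
        for t, s in reference_sets.items()
    }
    T = pd.DataFrame(cent_t)
    R = pd.DataFrame(cent_r)
    if zscore:
        pooled = pd.concat([T, R], axis=1)
        mu = pooled.mean(axis=1)
        sd = pooled.std(axis=1).replace(0.0, 1.0)
        T = T.sub(mu, axis=0).div(sd, axis=0)
        R = R.sub(mu, axis=0).div(sd, axis=0)
    out = pd.DataFrame(index=list(T.columns), columns=list(R.columns), dtype=float)
    for g in T.columns:
        for t in R.columns:
            out.loc[g, t] = float(np.corrcoef(T[g], R[t])[0, 1])
    return out
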