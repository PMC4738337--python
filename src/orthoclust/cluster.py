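"""Unsupervised subgrouping: hierarchical, consensus (PAC), NMF (cophenetic).

Three mutually confirming methods, reported side by side rather than fused:

* average-linkage (UPGMA) hierarchical clustering on Pearson correlation
  distance d = 1 − r between sample profiles;
* consensus clustering — repeated subsampling of samples, each subsample
  clustered hierarchically; the consensus matrix entry M(i, j) is the
  fraction of co-sampled subsamples in which i and j co-cluster; the number
  of groups k is chosen by minimising the proportion of ambiguous clustering
  PAC_k = CDF_k(upper) − CDF_k(lower) over consensus entries;
* non-negative matrix factorization V ≈ WH minimising the Kullback–Leibler
  divergence by multiplicative updates, with random restarts; sample groups
  read from the argmax row of H; k chosen by maximising the cophenetic
  correlation of the across-run connectivity consensus.

`ConsensusClustering` and `NmfSubgrouper` are scikit-learn style estimators
(samples × features input, fitted attributes with trailing underscores); the
module-level functions wrap them for the genes × samples ExpressionMatrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, cut_tree, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-12


# ---------------------------------------------------------------------------
# distances and UPGMA


def pearson_distance(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlation distance 1 − r between sample profiles."""
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("pearson_distance requires at least 2 samples")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = matrix.sample_ids[int(np.argmax(sd == 0))]
        raise ValueError(f"sample {bad!r} has zero variance across genes")
    d = 1.0 - np.corrcoef(X, rowvar=False)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(d, index=matrix.sample_ids, columns=matrix.sample_ids)


def _labels_from_distance(d: np.ndarray, k: int) -> np.ndarray:
    """UPGMA tree of a square distance matrix cut to exactly k groups."""
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    if k == n:
        return np.arange(n)
    Z = linkage(squareform(d, checks=False), method="average")
    return cut_tree(Z, n_clusters=k).ravel()


def average_linkage_cut(distance: pd.DataFrame, k: int) -> pd.Series:
    """Cut the UPGMA tree of a labelled distance matrix into exactly k groups."""
    d = np.asarray(distance, dtype=float)
    return pd.Series(_labels_from_distance(d, k), index=distance.index, name="cluster")


# ---------------------------------------------------------------------------
# PAC


def pac(consensus: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous clustering of a consensus matrix.

    Empirical CDF over the strictly-upper-triangular entries; returns
    CDF(upper) − CDF(lower). 0 means every pair is unambiguous (entries at
    0 or 1), 1 means maximal ambiguity.
    """
    if not 0 <= lower < upper <= 1:
        raise ValueError("need 0 <= lower < upper <= 1")
    M = np.asarray(consensus, dtype=float)
    if M.ndim == 1:                      # pre-extracted entry distribution
        if M.size < 1:
            raise ValueError("need at least one consensus entry")
        tri = M
    elif M.ndim == 2 and M.shape[0] == M.shape[1] and M.shape[0] >= 2:
        tri = M[np.triu_indices_from(M, k=1)]
    else:
        raise ValueError("consensus matrix must be square, at least 2x2")
    cdf_upper = np.count_nonzero(tri <= upper) / tri.size
    cdf_lower = np.count_nonzero(tri <= lower) / tri.size
    return float(cdf_upper - cdf_lower)


def _argbest(scores: dict, minimize: bool) -> int:
    ks = sorted(scores)
    vals = np.array([scores[k] for k in ks], dtype=float)
    best = vals.min() if minimize else vals.max()
    winners = [k for k, v in zip(ks, vals) if v == best]
    if len(winners) > 1:
        logger.info("model-selection tie among k=%s; choosing smallest", winners)
    return winners[0]


def select_k_pac(pac_by_k: dict) -> int:
    """argmin of PAC over k; ties broken toward smaller k (logged)."""
    return _argbest(pac_by_k, minimize=True)


def select_k_cophenetic(cophenetic_by_k: dict) -> int:
    """argmax of the cophenetic correlation over k; ties toward smaller k."""
    return _argbest(cophenetic_by_k, minimize=False)


# ---------------------------------------------------------------------------
# consensus clustering


class ConsensusClustering(ClusterMixin, BaseEstimator):
    """Subsampling-based consensus clustering with PAC model selection.

    For each candidate k, `n_resamples` subsamples of ceil(p_item·n) samples
    are drawn without replacement; each is clustered by UPGMA on Pearson
    distance and cut at k. The consensus matrix divides co-clustering counts
    by co-sampling counts; final labels come from re-clustering 1 − M; PAC
    picks the k with the cleanest (least ambiguous) consensus.

    Parameters
    ----------
    k_range : iterable of int, default range(2, 8)
    n_resamples : int, default 1000
    p_item : float, default 0.8
        Fraction of samples per subsample; no feature subsampling.
    pac_lower, pac_upper : floats, default 0.1 / 0.9
        The ambiguity window of the PAC statistic.
    random_state : int, default 0

    Attributes
    ----------
    consensus_matrices_ : dict k -> (n, n) ndarray
    pac_ : dict k -> float
    labels_per_k_ : dict k -> (n,) int ndarray
    best_k_ : int
    labels_ : (n,) int ndarray  (labels at best_k_)
    """

    def __init__(
        self,
        k_range=range(2, 8),
        n_resamples: int = 1000,
        p_item: float = 0.8,
        pac_lower: float = 0.1,
        pac_upper: float = 0.9,
        random_state: int = 0,
    ):
        self.k_range = k_range
        self.n_resamples = n_resamples
        self.p_item = p_item
        self.pac_lower = pac_lower
        self.pac_upper = pac_upper
        self.random_state = random_state

    def fit(self, X, y=None):
        """Fit on X of shape (n_samples, n_features)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        n = X.shape[0]
        ks = sorted(set(int(k) for k in self.k_range))
        if not ks or ks[0] < 2:
            raise ValueError("k_range must contain integers >= 2")
        if ks[-1] >= n:
            raise ValueError(f"max(k_range)={ks[-1]} must be < n_samples={n}")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if not 0 < self.p_item <= 1:
            raise ValueError("p_item must lie in (0, 1]")
        m = int(np.ceil(self.p_item * n))

        self.consensus_matrices_ = {}
        self.pac_ = {}
        self.labels_per_k_ = {}
        self.n_never_cosampled_ = {}
        for k in ks:
            rng = np.random.default_rng([int(self.random_state), k])
            co_cluster = np.zeros((n, n))
            co_sampled = np.zeros((n, n))
            for _ in range(self.n_resamples):
                idx = np.sort(rng.choice(n, size=m, replace=False))
                sub = X[idx]
                d = 1.0 - np.corrcoef(sub)
                np.fill_diagonal(d, 0.0)
                d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
                lab = _labels_from_distance(d, k)
                co_sampled[np.ix_(idx, idx)] += 1.0
                same = lab[:, None] == lab[None, :]
                co_cluster[np.ix_(idx, idx)] += same
            never = int(np.count_nonzero(co_sampled[np.triu_indices(n, 1)] == 0))
            if never:
                warnings.warn(
                    f"k={k}: {never} sample pair(s) never co-sampled in "
                    f"{self.n_resamples} resamples; their consensus is set to 0",
                    stacklevel=2,
                )
            with np.errstate(invalid="ignore", divide="ignore"):
                M = np.where(co_sampled > 0, co_cluster / co_sampled, 0.0)
            np.fill_diagonal(M, 1.0)
            M = (M + M.T) / 2.0
            self.consensus_matrices_[k] = M
            self.labels_per_k_[k] = _labels_from_distance(1.0 - M, k)
            self.pac_[k] = pac(M, self.pac_lower, self.pac_upper)
            self.n_never_cosampled_[k] = never

        self.best_k_ = select_k_pac(self.pac_)
        self.labels_ = self.labels_per_k_[self.best_k_]
        self.n_features_in_ = X.shape[1]
        return self


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, PAC curve, labels and the selected k."""

    sample_ids: pd.Index
    consensus_matrices: dict
    pac: dict
    labels_per_k: dict
    selected_k: int
    labels: pd.Series
    n_resamples: int
    p_item: float
    seed: int
    n_never_cosampled: dict = field(default_factory=dict)


def consensus_cluster(
    matrix: ExpressionMatrix,
    k_range=range(2, 8),
    n_resamples: int = 1000,
    p_item: float = 0.8,
    seed: int = 0,
    pac_lower: float = 0.1,
    pac_upper: float = 0.9,
) -> ConsensusResult:
    """Consensus clustering of an ExpressionMatrix's samples (genes × samples in)."""
    est = ConsensusClustering(
        k_range=k_range,
        n_resamples=n_resamples,
        p_item=p_item,
        pac_lower=pac_lower,
        pac_upper=pac_upper,
        random_state=seed,
    ).fit(matrix.values.to_numpy(dtype=float).T)
    return ConsensusResult(
        sample_ids=matrix.sample_ids,
        consensus_matrices=est.consensus_matrices_,
        pac=est.pac_,
        labels_per_k={k: pd.Series(v, index=matrix.sample_ids) for k, v in est.labels_per_k_.items()},
        selected_k=est.best_k_,
        labels=pd.Series(est.labels_, index=matrix.sample_ids, name="cluster"),
        n_resamples=n_resamples,
        p_item=p_item,
        seed=seed,
        n_never_cosampled=est.n_never_cosampled_,
    )


# ---------------------------------------------------------------------------
# NMF


def _mu_kl_nmf(V: np.ndarray, k: int, rng, max_iter: int, tol: float):
    """One run of multiplicative-update NMF under the KL divergence.

    Standard alternating updates; the KL objective is guaranteed
    non-increasing at every step. Returns (W, H, objective trace).
    """
    g, n = V.shape
    W = rng.uniform(_EPS, 1.0, size=(g, k))
    H = rng.uniform(_EPS, 1.0, size=(k, n))
    trace = []
    prev = np.inf
    for it in range(max_iter):
        WH = W @ H + _EPS
        H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + _EPS)
        WH = W @ H + _EPS
        W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + _EPS)
        WH = W @ H + _EPS
        obj = float(np.sum(np.where(V > 0, V * np.log(np.where(V > 0, V, 1.0) / WH), 0.0) - V + WH))
        trace.append(obj)
        if it >= 10 and prev - obj <= tol * max(abs(prev), 1.0):
            break
        prev = obj
    return W, H, np.asarray(trace)


@dataclass
class NmfResult:
    """Best-run factors and across-run stability for one candidate k."""

    k: int
    W: np.ndarray
    H: np.ndarray
    connectivity_consensus: np.ndarray
    cophenetic: float
    objective_traces: list
    labels: np.ndarray
    n_runs: int
    seed: int


def _connectivity(labels: np.ndarray) -> np.ndarray:
    return (labels[:, None] == labels[None, :]).astype(float)


def _cophenetic_correlation(consensus: np.ndarray) -> float:
    """Correlation between 1 − consensus and its UPGMA tree distances."""
    d = squareform(1.0 - consensus, checks=False)
    if np.allclose(d.std(), 0.0):
        # perfectly flat consensus: tree distances carry no information;
        # report 1 when structure is exact (all 0 or all 1), else 0
        return 1.0 if np.allclose(d, d.round()) else 0.0
    Z = linkage(d, method="average")
    c, _ = cophenet(Z, d)
    return float(c)


def nmf_factorize(
    V,
    k: int,
    n_runs: int = 30,
    max_iter: int = 500,
    tol: float = 1e-9,
    seed: int = 0,
    clip_negative: bool = False,
) -> NmfResult:
    """KL-NMF of a non-negative genes × samples matrix with random restarts.

    Per run, samples are assigned to the argmax row of H; the connectivity
    consensus (mean co-assignment over runs) summarises stability, and its
    cophenetic correlation is the model-selection score for k. Negative
    entries are an error unless ``clip_negative`` (log2 intensities are
    expected non-negative; silent shifting would change the KL geometry).
    """
    if isinstance(V, ExpressionMatrix):
        V = V.values.to_numpy(dtype=float)
    V = np.asarray(V, dtype=float)
    if np.any(V < 0):
        if clip_negative:
            V = np.clip(V, 0.0, None)
        else:
            raise ValueError(
                "NMF input has negative entries; pass clip_negative=True to clip at 0"
            )
    if not 1 <= k < min(V.shape):
        raise ValueError(f"k={k} must satisfy 1 <= k < min(shape)={min(V.shape)}")
    n = V.shape[1]
    best = None
    traces = []
    consensus = np.zeros((n, n))
    for run in range(n_runs):
        rng = np.random.default_rng(int(seed) + run)
        W, H, trace = _mu_kl_nmf(V, k, rng, max_iter, tol)
        traces.append(trace)
        labels = H.argmax(axis=0)
        consensus += _connectivity(labels)
        if best is None or trace[-1] < best[2]:
            best = (W, H, trace[-1], labels)
    consensus /= n_runs
    W, H, _, labels = best
    return NmfResult(
        k=k,
        W=W,
        H=H,
        connectivity_consensus=consensus,
        cophenetic=_cophenetic_correlation(consensus),
        objective_traces=traces,
        labels=labels,
        n_runs=n_runs,
        seed=seed,
    )


class NmfSubgrouper(ClusterMixin, BaseEstimator):
    """NMF subgrouping over a range of k with cophenetic model selection.

    scikit-learn interface: fit on (n_samples, n_features); internally the
    transposed matrix is factorised so samples index the columns of H.

    Attributes
    ----------
    results_ : dict k -> NmfResult
    cophenetic_ : dict k -> float
    best_k_ : int
    labels_ : (n_samples,) int ndarray — argmax-of-H labels of the best run
        at best_k_.
    """

    def __init__(
        self,
        k_range=range(2, 8),
        n_runs: int = 30,
        max_iter: int = 500,
        tol: float = 1e-9,
        clip_negative: bool = False,
        random_state: int = 0,
    ):
        self.k_range = k_range
        self.n_runs = n_runs
        self.max_iter = max_iter
        self.tol = tol
        self.clip_negative = clip_negative
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        V = X.T  # genes x samples
        ks = sorted(set(int(k) for k in self.k_range))
        self.results_ = {}
        self.cophenetic_ = {}
        for k in ks:
            res = nmf_factorize(
                V,
                k,
                n_runs=self.n_runs,
                max_iter=self.max_iter,
                tol=self.tol,
                seed=int(self.random_state) * 1000 + k * 100,
                clip_negative=self.clip_negative,
            )
            self.results_[k] = res
            self.cophenetic_[k] = res.cophenetic
        self.best_k_ = select_k_cophenetic(self.cophenetic_)
        self.labels_ = self.results_[self.best_k_].labels
        self.n_features_in_ = X.shape[1]
        return self
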