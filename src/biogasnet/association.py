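"""Pairwise association measures for the co-occurrence ensemble.

Five measures are scored for every unordered pair of taxa across the replicate
samples: Pearson, Spearman and Kendall correlation plus Bray-Curtis and
(symmetrized) Kullback-Leibler dissimilarity.  Correlations signal co-presence
when positive and mutual exclusion when negative; dissimilarities signal
co-presence when *below* their permutation-null mean and exclusion when above.

KL divergence needs probability distributions: each taxon's vector across
samples is turned into one by adding a pseudocount (1e-6) to every cell and
normalizing to sum 1; the divergence is symmetrized as
``(KL(p||q) + KL(q||p)) / 2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

METHODS = ("pearson", "spearman", "kendall", "braycurtis", "kl")
CORRELATION_METHODS = frozenset({"pearson", "spearman", "kendall"})
DISSIMILARITY_METHODS = frozenset({"braycurtis", "kl"})

COPRESENCE = "copresence"
EXCLUSION = "exclusion"

KL_PSEUDOCOUNT = 1e-6


@dataclass(frozen=True)
class MethodScore:
    """Score of one association method on one unordered taxon pair."""

    pair: tuple
    method: str
    score: float
    direction: str


def _as_matrix(X: pd.DataFrame) -> np.ndarray:
    """features x samples array from a samples x features frame."""
    return np.ascontiguousarray(X.to_numpy(dtype=float).T)


def _kl_distributions(V: np.ndarray) -> np.ndarray:
    P = V + KL_PSEUDOCOUNT
    return P / P.sum(axis=1, keepdims=True)


def score_matrix(V: np.ndarray, method: str) -> np.ndarray:
    """Full symmetric score matrix for feature-row matrix ``V`` (features x samples).

    Entries are NaN where the score is undefined (constant vector under a
    correlation method).  The diagonal is not meaningful.
    """
    n_feat = V.shape[0]
    if method == "pearson":
        sd = V.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.corrcoef(V)
        M[sd == 0, :] = np.nan
        M[:, sd == 0] = np.nan
        return M
    if method == "spearman":
        R = np.apply_along_axis(stats.rankdata, 1, V)
        return score_matrix(R, "pearson")
    if method == "kendall":
        M = np.full((n_feat, n_feat), np.nan)
        const = V.std(axis=1) == 0
        for i in range(n_feat):
            M[i, i] = 1.0
            for j in range(i + 1, n_feat):
                if const[i] or const[j]:
                    continue
                tau = stats.kendalltau(V[i], V[j]).statistic
                M[i, j] = M[j, i] = tau
        return M
    if method == "braycurtis":
        return squareform(pdist(V, metric="braycurtis"))
    if method == "kl":
        P = _kl_distributions(V)
        # symmetrized KL for all pairs via log-matrix products
        logP = np.log(P)
        cross = P @ logP.T                       # cross[i, j] = sum_s p_i log p_j
        self_ent = np.einsum("ij,ij->i", P, logP)
        kl = self_ent[:, None] - cross           # KL(p_i || p_j)
        return (kl + kl.T) / 2.0
    raise ValueError(f"unknown association method {method!r}")


def permutation_null_matrix(
    V: np.ndarray, method: str, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean dissimilarity matrix under independent row permutations.

    For each permutation round every row is shuffled independently along the
    sample axis and the cross-dissimilarity between original and shuffled rows
    is accumulated; the average estimates the null (no-association) value of
    the measure for each pair.
    """
    if method not in DISSIMILARITY_METHODS:
        raise ValueError("permutation null is defined for dissimilarity methods only")
    n_feat, n_samp = V.shape
    acc = np.zeros((n_feat, n_feat))
    for _ in range(n_perm):
        W = np.empty_like(V)
        for i in range(n_feat):
            W[i] = V[i, rng.permutation(n_samp)]
        if method == "braycurtis":
            D = _braycurtis_cross(V, W)
        else:
            D = _kl_cross(V, W)
        acc += (D + D.T) / 2.0
    return acc / n_perm


def _braycurtis_cross(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """D[i, j] = Bray-Curtis(A_i, B_j)."""
    num = np.abs(A[:, None, :] - B[None, :, :]).sum(axis=2)
    den = (A[:, None, :] + B[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, 0.0)


def _kl_cross(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """D[i, j] = symmetrized KL between distributions of A_i and B_j."""
    P, Q = _kl_distributions(A), _kl_distributions(B)
    logP, logQ = np.log(P), np.log(Q)
    entP = np.einsum("ij,ij->i", P, logP)
    entQ = np.einsum("ij,ij->i", Q, logQ)
    kl_pq = entP[:, None] - P @ logQ.T
    kl_qp = entQ[None, :] - (Q @ logP.T).T
    return (kl_pq + kl_qp) / 2.0


def pair_score(x: np.ndarray, y: np.ndarray, method: str) -> float:
    """Association score of a single pair of sample vectors."""
    V = np.vstack([np.asarray(x, dtype=float), np.asarray(y, dtype=float)])
    return float(score_matrix(V, method)[0, 1])


def pairwise_scores(
    X: pd.DataFrame,
    method: str,
    n_null: int = 100,
    seed: int = 0,
    null_means: np.ndarray | None = None,
) -> list[MethodScore]:
    """Score all unordered feature pairs of an abundance table with one method.

    For dissimilarity methods the direction of each pair is set against the
    permutation-mean null value (``n_null`` rounds, seeded); a precomputed
    ``null_means`` matrix may be supplied instead.  Pairs whose score is
    undefined (constant vector under a correlation) are skipped and logged.
    """
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples for association scoring")
    if method not in METHODS:
        raise ValueError(f"unknown association method {method!r}")
    V = _as_matrix(X)
    M = score_matrix(V, method)
    if method in DISSIMILARITY_METHODS:
        if null_means is None:
            rng = np.random.default_rng(seed)
            null_means = permutation_null_matrix(V, method, n_null, rng)
    features = list(X.columns)
    out: list[MethodScore] = []
    n_skipped = 0
    for i in range(len(features)):
        for j in range(i + 1, len(features)):
            s = M[i, j]
            if np.isnan(s):
                n_skipped += 1
                continue
            pair = tuple(sorted((features[i], features[j])))
            if method in CORRELATION_METHODS:
                direction = COPRESENCE if s > 0 else EXCLUSION
            else:
                direction = COPRESENCE if s < null_means[i, j] else EXCLUSION
            out.append(MethodScore(pair=pair, method=method, score=float(s),
                                   direction=direction))
    if n_skipped:
        logger.info("%s: skipped %d pair(s) with undefined score", method, n_skipped)
    return out
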