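"""Ensemble co-occurrence network inference with bootstrap significance.

The inference chain (CoNet-style) over a species-level replicate table:

1. prevalence filter — only taxa seen in >= 60% of the samples are scored;
2. five association measures (Pearson, Spearman, Kendall, Bray-Curtis,
   symmetrized KL) score every remaining pair;
3. per method the strongest ``n_top`` co-presence and ``n_bottom`` exclusion
   pairs become candidates (defaults 2,500 each, capped by the pair count);
4. an edge survives when at least ``min_support`` methods picked the same pair
   with the same direction (majority direction; ties drop the edge);
5. each supporting method gets a p-value for the observed score against a
   Normal fit to its resampling null distribution (independent column
   permutations, 100 iterations; the null center is 0 for correlations and
   the permutation mean for dissimilarities), two-sided by default; a
   bootstrap distribution of the score (column resampling, same iteration
   count) guards stability: a degenerate bootstrap (sd = 0) short-circuits
   the p-value to 0 (off-null) or 1 (at the null);
6. the per-method p-values are merged with Brown's method for dependent
   p-values (covariance of -2 ln p pooled empirically across edges);
7. Benjamini-Hochberg across edges; edges with q < alpha form the network.

All randomness descends from one master seed through named substreams, so
results do not depend on evaluation order.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .abundance import check_abundance_frame
from .association import (
    COPRESENCE,
    CORRELATION_METHODS,
    DISSIMILARITY_METHODS,
    EXCLUSION,
    METHODS,
    MethodScore,
    _as_matrix,
    pairwise_scores,
    permutation_null_matrix,
    score_matrix,
)

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300
_MAX_REDRAWS = 10


@dataclass
class EdgeRecord:
    """One unordered taxon pair surviving the ensemble with its significance."""

    pair: tuple
    direction: str
    support: int
    methods: tuple
    method_pvalues: dict = field(default_factory=dict)
    merged_p: float = np.nan
    q: float = np.nan

    @property
    def sign(self) -> int:
        return 1 if self.direction == COPRESENCE else -1


# ---------------------------------------------------------------------------
# candidate selection and consensus
# ---------------------------------------------------------------------------

def select_candidates(
    scores: list[MethodScore], n_top: int = 2500, n_bottom: int = 2500
) -> dict[str, list[tuple]]:
    """Per method, keep the strongest co-presence / exclusion candidate pairs.

    Correlations rank co-presence by largest signed score and exclusion by
    smallest; dissimilarities the other way round (small = similar).  Ties at
    the rank boundary break lexicographically by pair id.  Returns
    ``{method: [(pair, direction), ...]}``.
    """
    if n_top < 1 or n_bottom < 1:
        raise ValueError("n_top and n_bottom must be >= 1")
    by_method: dict[str, list[MethodScore]] = {}
    for s in scores:
        by_method.setdefault(s.method, []).append(s)
    out: dict[str, list[tuple]] = {}
    for method, method_scores in by_method.items():
        strong_high = method in CORRELATION_METHODS  # high score = strong copresence
        picked: list[tuple] = []
        for direction, n_take in ((COPRESENCE, n_top), (EXCLUSION, n_bottom)):
            cands = [s for s in method_scores if s.direction == direction]
            descending = strong_high == (direction == COPRESENCE)
            cands.sort(key=lambda s: ((-s.score if descending else s.score), s.pair))
            picked.extend((s.pair, direction) for s in cands[:n_take])
        out[method] = picked
    return out


def support_filter(
    candidates: dict[str, list[tuple]], min_support: int = 3
) -> list[EdgeRecord]:
    """Keep pairs picked by >= ``min_support`` methods in the same direction.

    The edge direction is the majority direction among the methods that
    selected the pair; a direction tie means no consensus and drops the edge.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    votes: dict[tuple, dict[str, list[str]]] = {}
    for method, picks in candidates.items():
        for pair, direction in picks:
            votes.setdefault(pair, {}).setdefault(direction, []).append(method)
    edges = []
    for pair in sorted(votes):
        by_dir = votes[pair]
        n_cop = len(by_dir.get(COPRESENCE, ()))
        n_exc = len(by_dir.get(EXCLUSION, ()))
        if n_cop == n_exc:
            continue
        direction = COPRESENCE if n_cop > n_exc else EXCLUSION
        methods = tuple(sorted(by_dir[direction]))
        if len(methods) >= min_support:
            edges.append(EdgeRecord(pair=pair, direction=direction,
                                    support=len(methods), methods=methods))
    return edges


# ---------------------------------------------------------------------------
# bootstrap p-values
# ---------------------------------------------------------------------------

def _substream(seed: int, *tokens) -> np.random.Generator:
    """Deterministic named substream of the master seed (order-independent)."""
    key = "|".join(str(t) for t in tokens).encode()
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(key)])
    )


def _correlation_null_sd(method: str, n_samples: int) -> float:
    """Exact sd of a correlation score under the permutation null.

    For Pearson and Spearman the permutation variance is exactly
    ``1 / (n - 1)`` whatever the marginals; for Kendall's tau it is
    ``2 (2n + 5) / (9 n (n - 1))`` (tie corrections ignored — abundance data
    tie only at dropout zeros).
    """
    if method == "kendall":
        n = n_samples
        return float(np.sqrt(2.0 * (2 * n + 5) / (9.0 * n * (n - 1))))
    return float(1.0 / np.sqrt(n_samples - 1))


def _normal_tail_p(observed: float, center: float, null_sd: float,
                   boot_sd: float, direction: str, method: str,
                   two_sided: bool = True) -> float:
    """P-value of an observed score against its Normal-fit resampling null.

    ``center``/``null_sd`` parameterize the null distribution (from column
    permutations); the p-value is the null mass at or beyond the observed
    score — two-sided by default, or one-sided past the tail that contradicts
    the stated effect direction.  A degenerate bootstrap distribution
    (``boot_sd = 0``, e.g. a perfectly monotone pair) short-circuits to 0
    off the null center and 1 at it; a degenerate null does the same.
    """
    if boot_sd <= 1e-12 or null_sd <= 1e-12:
        return 0.0 if abs(observed - center) > 1e-12 else 1.0
    if two_sided:
        return float(min(1.0, 2.0 * stats.norm.sf(abs(observed - center) / null_sd)))
    if method in CORRELATION_METHODS:
        effect = observed - center if direction == COPRESENCE else center - observed
    else:
        effect = center - observed if direction == COPRESENCE else observed - center
    return float(stats.norm.sf(effect / null_sd))


def _permutation_scores(
    V: np.ndarray,
    pairs_idx: list[tuple[int, int]],
    method: str,
    iterations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null score distribution, ``iterations x len(pairs_idx)``.

    Every involved taxon's sample vector is permuted independently in each
    round, destroying any pairwise alignment while preserving the marginals.
    """
    needed = sorted({i for ij in pairs_idx for i in ij})
    col_of = {i: k for k, i in enumerate(needed)}
    sub_pairs = [(col_of[i], col_of[j]) for i, j in pairs_idx]
    out = np.empty((iterations, len(pairs_idx)))
    base = V[needed]
    for t in range(iterations):
        W = rng.permuted(base, axis=1)
        M = score_matrix(W, method)
        out[t] = [M[i, j] for i, j in sub_pairs]
    return out


def _bootstrap_scores(
    V: np.ndarray,
    pairs_idx: list[tuple[int, int]],
    method: str,
    iterations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bootstrap score distribution, ``iterations x len(pairs_idx)``.

    Samples (columns) are resampled with replacement; all requested pairs share
    each resample.  For correlation methods a resample that leaves a needed
    taxon constant is redrawn (at most 10 times, then an error is raised).
    """
    n_samp = V.shape[1]
    needed = sorted({i for ij in pairs_idx for i in ij})
    col_of = {i: k for k, i in enumerate(needed)}
    sub_pairs = [(col_of[i], col_of[j]) for i, j in pairs_idx]
    base = V[needed]
    out = np.empty((iterations, len(pairs_idx)))
    check_const = method in CORRELATION_METHODS
    for t in range(iterations):
        for attempt in range(_MAX_REDRAWS + 1):
            idx = rng.integers(0, n_samp, n_samp)
            W = base[:, idx]
            if not check_const or not np.any(W.std(axis=1) == 0):
                break
        else:
            raise RuntimeError(
                f"{method}: taxon constant under resampling after {_MAX_REDRAWS} redraws"
            )
        M = score_matrix(W, method)
        out[t] = [M[i, j] for i, j in sub_pairs]
    return out


def bootstrap_pvalue(
    X: pd.DataFrame,
    pair: tuple,
    method: str,
    iterations: int = 100,
    seed: int = 0,
    direction: str | None = None,
    two_sided: bool = True,
) -> float:
    """Resampling p-value for one (pair, method).

    The null distribution of the score is estimated by ``iterations``
    independent column permutations and fit with a Normal; the p-value is the
    null mass at or beyond the observed score (two-sided by default).  For
    correlations the null center is fixed at 0; for dissimilarities it is the
    permutation mean.  A bootstrap distribution (column resampling, same
    iteration count, same seed stream) guards stability: if it is degenerate
    (sd = 0, e.g. a perfectly monotone pair) the p-value short-circuits to 0
    away from the null center and 1 at it.  ``direction`` (for the one-sided
    variant) defaults to the direction of the observed score.
    """
    if iterations < 2:
        raise ValueError("iterations must be >= 2")
    a, b = pair
    V = _as_matrix(X[[a, b]])
    rng = _substream(seed, method, *sorted(map(str, pair)))
    observed = float(score_matrix(V, method)[0, 1])
    if np.isnan(observed):
        raise ValueError(f"score undefined for pair {pair!r} under {method}")
    if method in CORRELATION_METHODS:
        center = 0.0
        null_sd = _correlation_null_sd(method, V.shape[1])
    else:
        perm = _permutation_scores(V, [(0, 1)], method, iterations, rng)[:, 0]
        center = float(perm.mean())
        null_sd = float(perm.std(ddof=0))
    if direction is None:
        if method in CORRELATION_METHODS:
            direction = COPRESENCE if observed > 0 else EXCLUSION
        else:
            direction = COPRESENCE if observed < center else EXCLUSION
    boot = _bootstrap_scores(V, [(0, 1)], method, iterations, rng)[:, 0]
    return _normal_tail_p(observed, center, null_sd, float(boot.std(ddof=0)),
                          direction, method, two_sided=two_sided)


# ---------------------------------------------------------------------------
# Brown's method and BH
# ---------------------------------------------------------------------------

def brown_merge(pvals, cov: np.ndarray | None = None) -> float:
    """Combine dependent p-values with Brown's extension of Fisher's method.

    With ``X = -2 sum(ln p_i)`` over k p-values, Brown approximates
    ``X ~ c * chi2_f`` where ``E[X] = 2k``, ``Var[X] = 4k + 2 sum_{i<j}
    cov_ij`` (``cov_ij`` the covariance of the ``-2 ln p`` terms),
    ``c = Var / (2 E)`` and ``f = 2 E^2 / Var``.  A zero covariance matrix
    (or ``cov=None``) reduces exactly to Fisher's method.  Zero p-values are
    clamped to 1e-300 and logged.
    """
    if isinstance(pvals, dict):
        pvals = list(pvals.values())
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to merge")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (p == 0).any():
        logger.warning("brown_merge: clamped %d zero p-value(s) to %.0e",
                       int((p == 0).sum()), P_FLOOR)
        p = np.clip(p, P_FLOOR, 1.0)
    k = p.size
    X = float(-2.0 * np.log(p).sum())
    if k == 1:
        return float(p[0])
    expected = 2.0 * k
    var = 4.0 * k
    if cov is not None:
        cov = np.asarray(cov, dtype=float)
        if cov.shape != (k, k) or not np.allclose(cov, cov.T):
            raise ValueError("cov must be a symmetric k x k matrix")
        iu = np.triu_indices(k, 1)
        var += 2.0 * float(cov[iu].sum())
    var = max(var, 1e-12)
    c = var / (2.0 * expected)
    f = 2.0 * expected**2 / var
    return float(stats.chi2.sf(X / c, f))


def bh_adjust(pvals, alpha: float = 0.05):
    """Benjamini-Hochberg step-up: returns (q-values, keep mask at q < alpha)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q < alpha


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

class CooccurrenceNetwork(BaseEstimator):
    """Ensemble co-occurrence network estimator (scikit-learn style).

    ``fit(X)`` runs the whole chain on a samples x taxa relative-abundance
    table restricted to the replicates of one methanogenic pathway class.

    Parameters mirror the published defaults: 60% prevalence, 2,500 top and
    bottom candidate edges per method, MinSupport 3 of 5 methods,
    100 bootstrap iterations, BH at alpha = 0.05.

    Attributes
    ----------
    graph_ : networkx.Graph
        Retained edges with ``sign`` (+1 co-presence / -1 exclusion),
        ``support``, ``merged_p`` and ``q`` attributes.
    edges_ : pandas.DataFrame
        Every support-filtered candidate edge with per-method p-values,
        Brown-merged p, q and the keep flag.
    n_candidates_tested_ : int
        Number of edges that entered significance testing.
    """

    def __init__(
        self,
        methods: tuple = METHODS,
        min_prevalence: float = 0.6,
        n_top: int = 2500,
        n_bottom: int = 2500,
        min_support: int = 3,
        bootstrap_iterations: int = 100,
        alpha: float = 0.05,
        seed: int = 0,
    ):
        self.methods = methods
        self.min_prevalence = min_prevalence
        self.n_top = n_top
        self.n_bottom = n_bottom
        self.min_support = min_support
        self.bootstrap_iterations = bootstrap_iterations
        self.alpha = alpha
        self.seed = seed

    # -- stages -------------------------------------------------------------

    def _score_all(self, X: pd.DataFrame):
        V = _as_matrix(X)
        scores: list[MethodScore] = []
        nulls: dict[str, np.ndarray] = {}
        for method in self.methods:
            null_means = None
            if method in DISSIMILARITY_METHODS:
                rng = _substream(self.seed, "null", method)
                null_means = permutation_null_matrix(
                    V, method, self.bootstrap_iterations, rng
                )
                nulls[method] = null_means
            scores.extend(
                pairwise_scores(X, method, null_means=null_means,
                                n_null=self.bootstrap_iterations, seed=self.seed)
            )
        return V, scores, nulls

    def _edge_pvalues(self, X, V, edges):
        col_of = {c: i for i, c in enumerate(X.columns)}
        for method in self.methods:
            todo = [e for e in edges if method in e.methods]
            if not todo:
                continue
            pairs_idx = [(col_of[e.pair[0]], col_of[e.pair[1]]) for e in todo]
            rng = _substream(self.seed, "pvalue", method)
            if method in CORRELATION_METHODS:
                centers = np.zeros(len(todo))
                null_sd = np.full(len(todo),
                                  _correlation_null_sd(method, V.shape[1]))
            else:
                perm = _permutation_scores(V, pairs_idx, method,
                                           self.bootstrap_iterations, rng)
                centers = perm.mean(axis=0)
                null_sd = perm.std(axis=0, ddof=0)
            boot = _bootstrap_scores(V, pairs_idx, method,
                                     self.bootstrap_iterations, rng)
            M_obs = score_matrix(V, method)
            boot_sd = boot.std(axis=0, ddof=0)
            for e, (i, j), c0, ns, bs in zip(todo, pairs_idx, centers,
                                             null_sd, boot_sd):
                p = _normal_tail_p(float(M_obs[i, j]), float(c0), float(ns),
                                   float(bs), e.direction, method)
                e.method_pvalues[method] = max(p, P_FLOOR)

    def _pooled_covariance(self, edges) -> pd.DataFrame:
        """Covariance of -2 ln p between methods, pooled across edges.

        The between-method dependence is estimated as the Spearman correlation
        of the p-value vectors across all candidate edges (robust to the
        near-zero p-values of strong edges) and mapped to the covariance of
        the ``-2 ln p`` terms with the Kost-McDermott polynomial
        ``3.263 r + 0.710 r^2 + 0.027 r^3``, which is exact at the
        independence (0) and total-dependence (4) limits.
        """
        table = pd.DataFrame(
            [dict(e.method_pvalues) for e in edges]
        )
        cov = pd.DataFrame(0.0, index=list(self.methods), columns=list(self.methods))
        for mi in table.columns:
            for mj in table.columns:
                if mi == mj:
                    continue
                both = table[[mi, mj]].dropna()
                if len(both) < 3:
                    continue
                r = stats.spearmanr(both[mi], both[mj]).statistic
                if np.isnan(r):
                    continue
                cov.loc[mi, mj] = 3.263 * r + 0.710 * r**2 + 0.027 * r**3
        return cov.clip(-4.0, 4.0)

    # -- estimator API ------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None):
        check_abundance_frame(X)
        if X.shape[0] < 3:
            raise ValueError("need at least 3 replicate samples to infer a network")
        X = X.loc[:, (X > 0).sum(axis=0)
                  >= int(np.ceil(self.min_prevalence * X.shape[0]))]
        self.prevalence_kept_ = list(X.columns)

        n_pairs = X.shape[1] * (X.shape[1] - 1) // 2
        n_top = min(self.n_top, max(n_pairs, 1))
        n_bottom = min(self.n_bottom, max(n_pairs, 1))

        V, scores, _ = self._score_all(X)
        candidates = select_candidates(scores, n_top=n_top, n_bottom=n_bottom)
        edges = support_filter(candidates, min_support=self.min_support)
        self.n_candidates_tested_ = len(edges)

        self._edge_pvalues(X, V, edges)
        cov = self._pooled_covariance(edges)
        for e in edges:
            ms = list(e.method_pvalues)
            sub = cov.loc[ms, ms].to_numpy() if len(ms) > 1 else None
            e.merged_p = brown_merge(e.method_pvalues, cov=sub)
        qvals, keep = bh_adjust([e.merged_p for e in edges], alpha=self.alpha)
        for e, q in zip(edges, qvals):
            e.q = float(q)

        self.edge_records_ = edges
        self.edges_ = self._edges_frame(edges, keep)
        self.graph_ = self._build_graph(edges, keep)
        self.method_covariance_ = cov
        return self

    def _edges_frame(self, edges, keep) -> pd.DataFrame:
        rows = []
        for e, kept in zip(edges, keep):
            row = {
                "species_a": e.pair[0], "species_b": e.pair[1],
                "direction": e.direction, "sign": e.sign, "support": e.support,
                "merged_p": e.merged_p, "q": e.q, "kept": bool(kept),
            }
            for m in self.methods:
                row[f"p_{m}"] = e.method_pvalues.get(m, np.nan)
            rows.append(row)
        cols = (["species_a", "species_b", "direction", "sign", "support"]
                + [f"p_{m}" for m in self.methods] + ["merged_p", "q", "kept"])
        return pd.DataFrame(rows, columns=cols)

    def _build_graph(self, edges, keep) -> nx.Graph:
        G = nx.Graph()
        for e, kept in zip(edges, keep):
            if kept:
                G.add_edge(*e.pair, sign=e.sign, direction=e.direction,
                           support=e.support, merged_p=e.merged_p, q=e.q)
        return G


def infer_network(X: pd.DataFrame, **params):
    """Run the full ensemble chain; returns ``(graph, edges DataFrame)``."""
    est = CooccurrenceNetwork(**params).fit(X)
    return est.graph_, est.edges_
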