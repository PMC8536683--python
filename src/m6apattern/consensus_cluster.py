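"""Resampling-based consensus clustering with automatic cluster-number
selection by the CDF delta-area rule.

Samples are repeatedly subsampled (default 1000 resamples at 80% of
samples), the gene-standardized submatrix is clustered by k-means, and the
fraction of co-assignments among co-sampled pairs forms the consensus
matrix. Final assignments come from average-linkage hierarchical clustering
of 1 - consensus. The number of clusters is chosen where the relative
increase of the area under the consensus CDF flattens out.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io_formats import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class ConsensusResult:
    k_range: list[int]
    consensus: dict[int, np.ndarray]
    assignments: dict[int, np.ndarray]
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    pac: dict[int, float]
    stable_ks: list[int]
    chosen_k: int
    sample_ids: list[str]


def _kmeans_pp_init(X: np.ndarray, x2: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = np.maximum(x2 + (centers[0] ** 2).sum() - 2.0 * X @ centers[0], 0.0)
    for j in range(1, k):
        tot = d2.sum()
        probs = d2 / tot if tot > 0 else np.full(n, 1.0 / n)
        centers[j] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(
            d2, np.maximum(x2 + (centers[j] ** 2).sum() - 2.0 * X @ centers[j], 0.0)
        )
    return centers


def _lloyd(
    X: np.ndarray, x2: np.ndarray, centers: np.ndarray, max_iter: int = 100
) -> tuple[np.ndarray, float]:
    k = centers.shape[0]
    labels = np.full(X.shape[0], -1)
    eye = np.arange(k)
    for _ in range(max_iter):
        d2 = x2[:, None] + (centers**2).sum(axis=1)[None, :] - 2.0 * (X @ centers.T)
        new_labels = d2.argmin(axis=1)
        if (new_labels == labels).all():
            break
        labels = new_labels
        onehot = labels == eye[:, None]  # k x n
        counts = onehot.sum(axis=1)
        sums = onehot @ X
        nonempty = counts > 0
        centers[nonempty] = sums[nonempty] / counts[nonempty, None]
    inertia = float(np.maximum(d2[np.arange(X.shape[0]), labels], 0.0).sum())
    return labels, inertia


def kmeans(
    X: np.ndarray, k: int, n_restarts: int = 10, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Best-of-``n_restarts`` Lloyd k-means with k-means++ initialization.

    Small dedicated implementation: the consensus procedure issues tens of
    thousands of tiny fits per run, so per-call overhead matters more than
    asymptotics here.
    """
    rng = rng or np.random.default_rng()
    x2 = (X**2).sum(axis=1)
    best_labels, best_inertia = None, np.inf
    for _ in range(n_restarts):
        centers = _kmeans_pp_init(X, x2, k, rng)
        labels, inertia = _lloyd(X, x2, centers)
        if inertia < best_inertia:
            best_labels, best_inertia = labels, inertia
    return best_labels


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of off-diagonal consensus entries."""
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = np.sort(consensus[iu])
    n = vals.size
    # step-function CDF integrated over [0, 1]
    xs = np.concatenate([vals, [1.0]])
    cdf = np.arange(1, n + 1) / n
    widths = np.diff(xs)
    return float((cdf * widths).sum())


def consensus_cluster(
    m: ExpressionMatrix,
    panel: Sequence[str],
    k_range: Sequence[int] = range(2, 7),
    n_resamples: int = 1000,
    item_fraction: float = 0.8,
    seed: int = 0,
    delta_area_threshold: float = 0.1,
    pac_threshold: float = 0.2,
    n_restarts: int = 10,
) -> ConsensusResult:
    """Consensus-cluster samples on ``panel`` genes.

    Genes are z-scored with full-cohort mean/sd (stabilizes subsample
    clustering), then for each k and each resample ceil(item_fraction*n)
    samples are drawn without replacement and clustered; consensus_ij is the
    co-assignment fraction among co-samplings. Pairs never co-sampled get
    consensus 0 with a warning.

    Cluster-number selection: the CDF area and its relative change
    (delta-area) are recorded for the stability curve, but the chosen k is
    the largest k whose consensus stays unambiguous from the smallest k up:
    a k is "stable" while its PAC — the proportion of off-diagonal consensus
    entries in the ambiguous band (0.1, 0.9) — is at most ``pac_threshold``.
    PAC discriminates planted structure from null data far more sharply than
    the delta-area elbow, whose shape is dominated by the mechanical growth
    of the CDF area with k. If no k is stable (structureless data), the
    delta-area elbow rule decides: the k preceding the first relative change
    below ``delta_area_threshold``, else the k with maximal delta-area.
    """
    k_range = sorted(set(int(k) for k in k_range))
    missing = [g for g in panel if g not in m.values.index]
    if missing:
        raise KeyError(f"panel genes absent from matrix: {missing}")
    if not (0.0 < item_fraction <= 1.0):
        raise ValueError("item_fraction must lie in (0, 1]")
    n = len(m.sample_ids)
    m_sub = int(np.ceil(item_fraction * n))
    if max(k_range) >= m_sub:
        raise ValueError(f"k={max(k_range)} >= subsample size {m_sub}")
    if min(k_range) < 2 or max(k_range) > n // 3:
        raise ValueError(f"k_range must lie within [2, {n // 3}]")

    X = m.values.loc[list(panel)].to_numpy().T  # samples x genes
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    X = (X - mu) / sd

    rng = np.random.default_rng(seed)
    consensus: dict[int, np.ndarray] = {}
    assignments: dict[int, np.ndarray] = {}
    cdf_area: dict[int, float] = {}
    for k in k_range:
        co = np.zeros((n, n))
        together = np.zeros((n, n))
        for _ in range(n_resamples):
            idx = rng.choice(n, size=m_sub, replace=False)
            labels = kmeans(X[idx], k, n_restarts=n_restarts, rng=rng)
            same = (labels[:, None] == labels[None, :]).astype(float)
            co[np.ix_(idx, idx)] += same
            together[np.ix_(idx, idx)] += 1.0
        never = together == 0
        if never[np.triu_indices(n, k=1)].any():
            warnings.warn(
                "some sample pairs were never co-sampled; their consensus is 0",
                stacklevel=2,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            cons = np.where(never, 0.0, co / np.where(never, 1.0, together))
        np.fill_diagonal(cons, 1.0)
        cons = (cons + cons.T) / 2.0
        consensus[k] = cons
        Z = linkage(squareform(1.0 - cons, checks=False), method="average")
        assignments[k] = fcluster(Z, t=k, criterion="maxclust")
        cdf_area[k] = _cdf_area(cons)

    delta_area: dict[int, float] = {}
    for i, k in enumerate(k_range):
        if i == 0:
            delta_area[k] = cdf_area[k]
        else:
            prev = cdf_area[k_range[i - 1]]
            delta_area[k] = (cdf_area[k] - prev) / prev if prev > 0 else 0.0

    pac: dict[int, float] = {}
    for k in k_range:
        iu = np.triu_indices(n, k=1)
        vals = consensus[k][iu]
        pac[k] = float(((vals > 0.1) & (vals < 0.9)).mean())
    stable_ks = [k for k in k_range if pac[k] <= pac_threshold]

    chosen_k = None
    for k in k_range:  # longest stable prefix
        if k in stable_ks:
            chosen_k = k
        else:
            break
    if chosen_k is None:
        # structureless: fall back to the delta-area elbow
        for i, k in enumerate(k_range[1:], start=1):
            if delta_area[k] < delta_area_threshold:
                chosen_k = k_range[i - 1]
                break
        if chosen_k is None:
            deltas = np.array([delta_area[k] for k in k_range])
            chosen_k = k_range[int(np.argmax(deltas))]

    return ConsensusResult(
        k_range=k_range,
        consensus=consensus,
        assignments=assignments,
        cdf_area=cdf_area,
        delta_area=delta_area,
        pac=pac,
        stable_ks=stable_ks,
        chosen_k=chosen_k,
        sample_ids=m.sample_ids,
    )


def adjusted_rand_index(a: Sequence, b: Sequence) -> float:
    """Adjusted Rand index between two labelings, via the contingency-table
    formula; 1 for identical partitions, ~0 at chance."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(contingency, (ai, bi), 1)

    def comb2(x: np.ndarray) -> np.ndarray:
        return x * (x - 1) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    total = comb2(np.array([a.size]))[0]
    expected = sum_a * sum_b / total if total > 0 else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0 if sum_ij == expected else 0.0
    return float((sum_ij - expected) / (max_index - expected))
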