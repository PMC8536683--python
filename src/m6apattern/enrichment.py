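"""Per-sample gene-set scoring.

``ssgsea`` is the single-sample enrichment score of Barbie-style rank-
weighted running sums (used here for immune-cell signatures / TME
infiltration); ``gsva`` is the kernel-CDF, rank-statistic KS-walk score
(used for pathway activity). Both operate on a log2-scale expression
matrix and are purely rank-based within each sample/gene, so they are
invariant to monotone transforms of the relevant margin.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .diffexpr import moderated_ttest
from .io_formats import ExpressionMatrix, GeneSetCollection


@dataclass
class EnrichmentScores:
    scores: pd.DataFrame  # sets x samples
    method: str  # 'ssgsea' | 'gsva'
    normalized: bool

    def __post_init__(self) -> None:
        if self.method not in ("ssgsea", "gsva"):
            raise ValueError(f"unknown enrichment method {self.method!r}")
        arr = self.scores.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        if self.method == "gsva" and finite.size and (np.abs(finite) > 1 + 1e-9).any():
            raise ValueError("GSVA scores must lie in [-1, 1]")

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)


def ssgsea(
    m: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> EnrichmentScores:
    """Single-sample GSEA enrichment scores.

    Per sample, genes are ranked by expression (average ranks for ties) and
    walked in descending order; the score is the summed difference between
    the rank^alpha-weighted in-set ECDF and the uniform out-of-set ECDF.
    With ``normalize`` the whole score matrix is divided by its range.
    Sets with no member present score NaN with a warning."""
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    values = m.values.to_numpy()
    genes = np.array(m.gene_ids)
    n_genes, n_samples = values.shape
    memberships = []
    for s in sets:
        present = np.isin(genes, list(s.members))
        if not present.any():
            warnings.warn(f"gene set {s.name!r} has no member in the matrix",
                          stacklevel=2)
        memberships.append(present)
    out = np.full((len(sets.sets), n_samples), np.nan)
    for j in range(n_samples):
        col = values[:, j]
        ranks = rankdata(col, method="average")
        order = np.argsort(-col, kind="stable")
        r_ord = ranks[order]
        w = r_ord**alpha
        for si, present in enumerate(memberships):
            m_size = int(present.sum())
            if m_size == 0:
                continue
            in_ord = present[order]
            w_in = np.where(in_ord, w, 0.0)
            denom_in = w_in.sum()
            p_in = np.cumsum(w_in) / denom_in
            n_out = n_genes - m_size
            if n_out == 0:
                out[si, j] = 0.0
                continue
            p_out = np.cumsum(~in_ord) / n_out
            out[si, j] = float((p_in - p_out).sum())
    if normalize:
        finite = out[np.isfinite(out)]
        rng_ = finite.max() - finite.min() if finite.size else 0.0
        if rng_ > 0:
            out = out / rng_
    return EnrichmentScores(
        pd.DataFrame(out, index=sets.names, columns=m.sample_ids),
        method="ssgsea",
        normalized=normalize,
    )


def _kernel_cdf(values: np.ndarray) -> np.ndarray:
    """Gaussian-kernel ECDF of each gene across samples, evaluated at the
    observed points (bandwidth = gene sd / 4, floored at 1e-8)."""
    n_genes, n_samples = values.shape
    out = np.empty_like(values, dtype=float)
    sds = values.std(axis=1, ddof=1)
    if (sds == 0).any():
        warnings.warn("constant gene(s): kernel bandwidth floored", stacklevel=2)
    h = np.maximum(sds / 4.0, 1e-8)
    for i in range(n_genes):
        diff = (values[i][:, None] - values[i][None, :]) / h[i]
        out[i] = norm.cdf(diff).mean(axis=1)
    return out


def gsva(
    m: ExpressionMatrix,
    sets: GeneSetCollection,
    tau: float = 1.0,
    mx_diff: bool = True,
) -> EnrichmentScores:
    """GSVA-style pathway scores.

    Gene-wise kernel CDFs across samples are converted per sample to the
    symmetric rank statistic |rank - p/2|; a KS-like walk down the ranking
    with in-set weight |r|^tau yields the score: max positive plus max
    negative deviation when ``mx_diff``, else the maximal absolute
    deviation. Scores are bounded in [-1, 1]."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if len(m.sample_ids) < 3:
        raise ValueError("GSVA needs at least 3 samples for the kernel density")
    values = m.values.to_numpy()
    genes = np.array(m.gene_ids)
    n_genes, n_samples = values.shape
    z = _kernel_cdf(values)
    out = np.full((len(sets.sets), n_samples), np.nan)
    memberships = []
    for s in sets:
        present = np.isin(genes, list(s.members))
        if not present.any():
            warnings.warn(f"gene set {s.name!r} has no member in the matrix",
                          stacklevel=2)
        memberships.append(present)
    for j in range(n_samples):
        col = z[:, j]
        rank_asc = rankdata(col, method="average")
        r_stat = np.abs(rank_asc - n_genes / 2.0)
        order = np.argsort(-col, kind="stable")  # walk from largest statistic down
        w_ord = r_stat[order] ** tau
        for si, present in enumerate(memberships):
            m_size = int(present.sum())
            if m_size == 0:
                continue
            if m_size == n_genes:
                warnings.warn(
                    f"gene set {sets.names[si]!r} equals the whole gene universe; "
                    "score degenerate, returned as 0",
                    stacklevel=2,
                )
                out[si, j] = 0.0
                continue
            in_ord = present[order]
            w_in = np.where(in_ord, w_ord, 0.0)
            p_in = np.cumsum(w_in) / w_in.sum()
            p_out = np.cumsum(~in_ord) / (n_genes - m_size)
            v = p_in - p_out
            if mx_diff:
                out[si, j] = float(v.max() + v.min())
            else:
                out[si, j] = float(v[np.argmax(np.abs(v))])
    return EnrichmentScores(
        pd.DataFrame(out, index=sets.names, columns=m.sample_ids),
        method="gsva",
        normalized=False,
    )


def score_group_contrast(
    s: EnrichmentScores, groups: Sequence, pair: tuple
) -> pd.DataFrame:
    """Per-set moderated-t contrast between two groups of samples; columns
    logFC, AveExpr, t, p, adj_p, sorted by adj_p."""
    groups = np.asarray(groups)
    for g in pair:
        if g not in groups:
            raise ValueError(f"unknown group label {g!r}")
    tab = moderated_ttest(s.scores, groups, pair)
    return tab.sort_values("adj_p")
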