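"""Group-comparison statistics: empirical-Bayes moderated t-tests,
phenotype DEG calling across cluster pairs, rank tests, BH adjustment, and
Spearman / distance correlation.

The moderated t shrinks per-gene variances toward a common prior whose
degrees of freedom and scale are estimated by moment-matching of log
residual variances to a scaled F distribution (trigamma inversion), the
standard variance-shrinkage approach for expression microarray/RNA data.
"""
from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .io_formats import ExpressionMatrix

log = logging.getLogger(__name__)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/trigamma)."""
    if x <= 0:
        raise ValueError("trigamma inverse requires positive input")
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Estimate prior df d0 and scale s0^2 from per-gene variances, return
    (d0, s0^2, posterior variances). d0=inf (no finite prior) falls back to
    the unshrunk variances with a warning."""
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 0.0, s2.copy()
    z = np.log(positive)
    e_z = z - digamma(df / 2.0) + np.log(df / 2.0)
    mean_e = float(np.mean(e_z))
    var_e = float(np.var(z, ddof=1)) - float(polygamma(1, df / 2.0))
    if var_e <= 0:
        warnings.warn(
            "log-variance underdispersed; falling back to unmoderated variances",
            stacklevel=2,
        )
        return np.inf, float(np.exp(mean_e)), s2.copy()
    d0 = 2.0 * _trigamma_inverse(var_e)
    s0_2 = float(np.exp(mean_e + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    post = (d0 * s0_2 + df * s2) / (d0 + df)
    return d0, s0_2, post


def moderated_ttest(
    m: ExpressionMatrix | pd.DataFrame,
    groups: Sequence,
    pair: tuple | None = None,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Per-gene moderated two-sample t-test between the two labels of
    ``pair`` (default: the two unique labels present).

    Returns a DataFrame indexed by gene with columns logFC (difference of
    group means, group1 - group2), AveExpr, t, p, adj_p. ``d0_override``
    forces the prior df (np.inf recovers the ordinary pooled t)."""
    values = m.values if isinstance(m, ExpressionMatrix) else m
    groups = np.asarray(groups)
    if groups.size != values.shape[1]:
        raise ValueError("groups length must equal sample count")
    if pair is None:
        uniq = pd.unique(groups)
        if uniq.size != 2:
            raise ValueError("pair must be given when more than two labels present")
        pair = (uniq[0], uniq[1])
    g1, g2 = pair
    i1, i2 = np.flatnonzero(groups == g1), np.flatnonzero(groups == g2)
    if len(i1) < 2 or len(i2) < 2:
        raise ValueError(f"each group of pair {pair} needs at least 2 samples")
    X1, X2 = values.iloc[:, i1].to_numpy(), values.iloc[:, i2].to_numpy()
    n1, n2 = X1.shape[1], X2.shape[1]
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    logfc = m1 - m2
    ave = values.iloc[:, np.concatenate([i1, i2])].to_numpy().mean(axis=1)
    ss = ((X1 - m1[:, None]) ** 2).sum(axis=1) + ((X2 - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    s2 = ss / df
    if d0_override is not None:
        d0 = float(d0_override)
        if np.isinf(d0):
            post = s2.copy()
        else:
            _, s0_2, _ = squeeze_variances(s2, df)
            post = (d0 * s0_2 + df * s2) / (d0 + df)
    else:
        d0, _, post = squeeze_variances(s2, df)
    se = np.sqrt(post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    df_total = df + d0 if np.isfinite(d0) else df
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(se > 0, p, 1.0)
    return pd.DataFrame(
        {
            "logFC": logfc,
            "AveExpr": ave,
            "t": t,
            "p": p,
            "adj_p": bh_adjust(p),
        },
        index=values.index,
    )


def phenotype_degs(
    m: ExpressionMatrix,
    cluster_labels: Sequence,
    p_threshold: float = 0.05,
    mode: str = "union",
    use_adjusted: bool = True,
) -> tuple[set[str], dict[tuple, pd.DataFrame]]:
    """Phenotype-related DEGs across all cluster pairs.

    mode='union' keeps genes significant in >= 1 pair (permissive default);
    'intersect' requires all pairs. Returns (gene set, per-pair tables)."""
    labels = np.asarray(cluster_labels)
    uniq = sorted(pd.unique(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    if mode not in ("union", "intersect"):
        raise ValueError("mode must be 'union' or 'intersect'")
    col = "adj_p" if use_adjusted else "p"
    tables: dict[tuple, pd.DataFrame] = {}
    sig_sets: list[set[str]] = []
    for i, a in enumerate(uniq):
        for b in uniq[i + 1 :]:
            tab = moderated_ttest(m, labels, (a, b))
            tables[(a, b)] = tab
            sig_sets.append(set(tab.index[tab[col] < p_threshold]))
    if mode == "union":
        genes = set().union(*sig_sets)
    else:
        genes = set.intersection(*sig_sets)
    if not genes:
        warnings.warn("no phenotype DEGs at the requested threshold", stacklevel=2)
    return genes, tables


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction (chi-square reference)."""
    arrays = _split_groups(values, groups)
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def one_way_anova(values: Sequence[float], groups: Sequence) -> tuple[float, float]:
    arrays = _split_groups(values, groups)
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def wilcoxon_ranksum(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U with normal
    approximation and tie correction)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _split_groups(values: Sequence[float], groups: Sequence) -> list[np.ndarray]:
    values, groups = np.asarray(values, dtype=float), np.asarray(groups)
    uniq = pd.unique(groups)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    return [values[groups == g] for g in uniq]


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Sample distance correlation via double-centered pairwise distances."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    a = np.abs(x[:, None] - x[None, :])
    b = np.abs(y[:, None] - y[None, :])
    A = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    B = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
    dcov2 = (A * B).mean()
    dvar_x, dvar_y = (A * A).mean(), (B * B).mean()
    denom = np.sqrt(dvar_x * dvar_y)
    return float(np.sqrt(max(dcov2, 0.0) / denom)) if denom > 0 else 0.0


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "spearman",
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Correlation between two vectors.

    'spearman': rho with the t-approximation p-value. 'distance': distance
    correlation with a seeded permutation p-value. Constant input yields
    (nan, nan)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    method = method.lower()
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
        return float(rho), float(p)
    if method == "distance":
        stat = distance_correlation(x, y)
        rng = np.random.default_rng(seed)
        count = 1
        for _ in range(n_permutations):
            if distance_correlation(x, rng.permutation(y)) >= stat:
                count += 1
        return stat, count / (n_permutations + 1)
    raise ValueError(f"unknown correlation method {method!r}")
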