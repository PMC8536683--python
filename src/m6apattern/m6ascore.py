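"""The m6Ascore: a PCA-based per-sample summary of the m6A phenotype-gene
signature.

Signature genes (phenotype-related DEGs passing a univariate-Cox prognostic
filter) are z-scored; the score is the sum of each sample's first two
principal-component coordinates, with principal-axis signs anchored so that
protective genes (negative Cox beta) load positively — "high score = good
prognosis". The score is then dichotomized at the maximally selected
log-rank cutpoint.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .diffexpr import bh_adjust
from .io_formats import ClinicalTable, ExpressionMatrix
from .enrichment import EnrichmentScores
from .survival import CutpointResult, cox_fit, surv_cutpoint


@dataclass
class ScoreTable:
    """Per-sample PC coordinates and m6Ascore; ``group`` (HIGH/LOW) and
    ``cutpoint`` are filled in by :func:`dichotomize_score`."""

    table: pd.DataFrame  # index sample_id; columns pc1, pc2, m6ascore [, group]
    signature_genes: list[str]
    orientation_sign: tuple[int, int]
    cutpoint: float | None = None

    def __post_init__(self) -> None:
        t = self.table
        if not np.allclose(t["m6ascore"], t["pc1"] + t["pc2"]):
            raise ValueError("m6ascore must equal pc1 + pc2")
        if abs(float(t["pc1"].sum())) > 1e-8 * max(1.0, float(np.abs(t["pc1"]).max())):
            raise ValueError("pc1 coordinates must be centered")
        if abs(float(t["pc2"].sum())) > 1e-8 * max(1.0, float(np.abs(t["pc2"]).max())):
            raise ValueError("pc2 coordinates must be centered")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def m6ascore(self) -> pd.Series:
        return self.table["m6ascore"]

    @property
    def groups(self) -> pd.Series:
        if "group" not in self.table:
            raise ValueError("score table has not been dichotomized yet")
        return self.table["group"]


def prognostic_filter(
    m: ExpressionMatrix,
    genes: Sequence[str],
    clinical: ClinicalTable,
    p_threshold: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Univariate-Cox screen of candidate genes.

    Each gene's standardized expression is fit against overall survival;
    genes with Wald p < ``p_threshold`` are kept. Returns (kept genes,
    full table with beta, hr, p and risk/protective direction)."""
    missing = [g for g in genes if g not in m.values.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    clin = clinical.aligned_to(m.sample_ids)
    times = clin.table["os_time"].to_numpy()
    events = clin.table["os_event"].to_numpy()
    rows = []
    for g in genes:
        x = m.values.loc[g].to_numpy()
        sd = x.std()
        if sd == 0:
            rows.append((g, np.nan, np.nan, np.nan, "constant"))
            continue
        fit = cox_fit(times, events, (x - x.mean()) / sd, names=[g])
        term = fit.terms[0]
        rows.append(
            (g, term.beta, term.hr, term.p, "risk" if term.beta > 0 else "protective")
        )
    tab = pd.DataFrame(
        rows, columns=["gene", "beta", "hr", "p", "direction"]
    ).set_index("gene")
    kept = [g for g in genes if np.isfinite(tab.loc[g, "p"]) and tab.loc[g, "p"] < p_threshold]
    if not kept:
        raise ValueError(
            f"no gene passes the prognostic filter at p < {p_threshold}; "
            "consider raising the threshold"
        )
    return kept, tab


def compute_m6ascore(
    m: ExpressionMatrix,
    signature_genes: Sequence[str],
    protective_genes: Sequence[str] | None = None,
) -> ScoreTable:
    """PCA of the z-scored signature-gene matrix (samples as observations);
    m6ascore_j = PC1_j + PC2_j.

    Sign convention: each PC's loading vector is flipped, if needed, so the
    summed loading over ``protective_genes`` is positive; with no (or
    perfectly balanced) protective genes, so the largest-|loading| gene
    loads positively. This makes the score fully deterministic and oriented
    'high = protective'."""
    signature_genes = list(signature_genes)
    if len(signature_genes) < 2:
        raise ValueError("need at least 2 signature genes")
    missing = [g for g in signature_genes if g not in m.values.index]
    if missing:
        raise KeyError(f"signature genes absent from matrix: {missing}")
    if len(m.sample_ids) < 3:
        raise ValueError("need at least 3 samples")
    sub = m.values.loc[signature_genes]
    sds = sub.std(axis=1, ddof=0)
    constant = list(sub.index[sds == 0])
    if constant:
        warnings.warn(f"dropping constant signature genes: {constant}", stacklevel=2)
        signature_genes = [g for g in signature_genes if g not in constant]
        sub = sub.loc[signature_genes]
        sds = sds.loc[signature_genes]
    if len(signature_genes) < 2:
        raise ValueError("fewer than 2 nonconstant signature genes")
    Z = ((sub.sub(sub.mean(axis=1), axis=0)).div(sds, axis=0)).to_numpy().T
    # samples x genes, column-centered by construction
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    coords = U * S  # sample coordinates on the principal axes
    prot = set(protective_genes or [])
    signs = []
    for c in range(2):
        loadings = Vt[c]
        anchor = sum(loadings[i] for i, g in enumerate(signature_genes) if g in prot)
        if anchor == 0.0:
            anchor = loadings[np.argmax(np.abs(loadings))]
        sign = 1 if anchor >= 0 else -1
        signs.append(sign)
    pc1 = coords[:, 0] * signs[0]
    pc2 = (coords[:, 1] * signs[1]) if coords.shape[1] > 1 else np.zeros(len(pc1))
    if coords.shape[1] < 2:
        signs = [signs[0], 1]
    table = pd.DataFrame(
        {"pc1": pc1, "pc2": pc2, "m6ascore": pc1 + pc2},
        index=pd.Index(m.sample_ids, name="sample_id"),
    )
    return ScoreTable(
        table=table,
        signature_genes=signature_genes,
        orientation_sign=(signs[0], signs[1]),
    )


def dichotomize_score(
    st: ScoreTable, clinical: ClinicalTable, minprop: float = 0.1
) -> ScoreTable:
    """Split samples into HIGH/LOW m6Ascore groups at the maximally selected
    log-rank cutpoint (HIGH iff score > cutpoint)."""
    clin = clinical.aligned_to(st.sample_ids)
    cp: CutpointResult = surv_cutpoint(
        st.m6ascore.to_numpy(),
        clin.table["os_time"].to_numpy(),
        clin.table["os_event"].to_numpy(),
        minprop=minprop,
    )
    table = st.table.copy()
    table["group"] = np.where(table["m6ascore"] > cp.cutpoint, "HIGH", "LOW")
    return ScoreTable(
        table=table,
        signature_genes=list(st.signature_genes),
        orientation_sign=st.orientation_sign,
        cutpoint=cp.cutpoint,
    )


def score_immune_correlation(st: ScoreTable, es: EnrichmentScores) -> pd.DataFrame:
    """Spearman correlation of the m6Ascore with each enrichment signature
    across shared samples; BH-adjusted. Columns rho, p, adj_p."""
    from scipy.stats import spearmanr

    shared = [s for s in st.sample_ids if s in es.scores.columns]
    if len(shared) < 4:
        raise ValueError("need at least 4 shared samples")
    score = st.table.loc[shared, "m6ascore"].to_numpy()
    rows = []
    for name in es.set_names:
        vals = es.scores.loc[name, shared].to_numpy(dtype=float)
        if np.isnan(vals).all():
            rows.append((name, np.nan, np.nan))
            continue
        rho, p = spearmanr(score, vals)
        rows.append((name, float(rho), float(p)))
    tab = pd.DataFrame(rows, columns=["set", "rho", "p"]).set_index("set")
    finite = tab["p"].notna()
    adj = np.full(len(tab), np.nan)
    adj[finite.to_numpy()] = bh_adjust(tab.loc[finite, "p"].to_numpy())
    tab["adj_p"] = adj
    return tab
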