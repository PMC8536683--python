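"""Immunotherapy-response comparisons between m6Ascore groups.

Response scores (e.g. immunophenoscores) are consumed as-is on an
arbitrary ordinal scale, stratified by the four checkpoint-blockade
treatment flags; checkpoint-ligand expression (B7-1/CD80, B7-2/CD86) is
contrasted between score groups with rank tests.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diffexpr import wilcoxon_ranksum
from .io_formats import ExpressionMatrix
from .m6ascore import ScoreTable

STRATA = (
    "CTLA4neg_PD1pos",
    "CTLA4pos_PD1neg",
    "CTLA4pos_PD1pos",
    "CTLA4neg_PD1neg",
)


@dataclass
class ResponseTable:
    table: pd.DataFrame  # columns sample_id, stratum, response_score

    def __post_init__(self) -> None:
        req = ["sample_id", "stratum", "response_score"]
        missing = [c for c in req if c not in self.table.columns]
        if missing:
            raise ValueError(f"response table missing columns: {missing}")
        bad = set(self.table["stratum"]) - set(STRATA)
        if bad:
            raise ValueError(f"unknown treatment strata: {sorted(bad)}")
        if self.table.duplicated(["sample_id", "stratum"]).any():
            raise ValueError("duplicate sample within a stratum")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ResponseTable":
        if df.index.name == "sample_id":
            df = df.reset_index()
        return cls(df[["sample_id", "stratum", "response_score"]].copy())

    @classmethod
    def read_tsv(cls, path: Path | str) -> "ResponseTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def compare_response(
    rt: ResponseTable, st: ScoreTable, stratum: str = "CTLA4pos_PD1neg"
) -> dict[str, float]:
    """Wilcoxon rank-sum of the response score between HIGH and LOW m6Ascore
    groups within one treatment stratum; medians reported."""
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}")
    sub = rt.table[rt.table["stratum"] == stratum].set_index("sample_id")
    if sub.empty:
        raise ValueError(f"stratum {stratum!r} has no samples")
    groups = st.groups
    shared = [s for s in sub.index if s in groups.index]
    g = groups.loc[shared]
    hi = sub.loc[[s for s in shared if g[s] == "HIGH"], "response_score"]
    lo = sub.loc[[s for s in shared if g[s] == "LOW"], "response_score"]
    if hi.empty or lo.empty:
        raise ValueError("both score groups must be represented in the stratum")
    w, p = wilcoxon_ranksum(hi, lo)
    return {
        "median_high": float(hi.median()),
        "median_low": float(lo.median()),
        "W": w,
        "p": p,
        "n_high": int(hi.size),
        "n_low": int(lo.size),
    }


def ligand_contrast(
    m: ExpressionMatrix,
    st: ScoreTable,
    genes: Sequence[str] = ("CD80", "CD86"),
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum of checkpoint-ligand expression between
    HIGH and LOW score groups. Columns W, p, direction."""
    missing = [g for g in genes if g not in m.values.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    groups = st.groups
    shared = [s for s in m.sample_ids if s in groups.index]
    g = groups.loc[shared]
    hi_ids = [s for s in shared if g[s] == "HIGH"]
    lo_ids = [s for s in shared if g[s] == "LOW"]
    rows = []
    for gene in genes:
        hi = m.values.loc[gene, hi_ids].to_numpy(dtype=float)
        lo = m.values.loc[gene, lo_ids].to_numpy(dtype=float)
        if np.ptp(np.concatenate([hi, lo])) == 0:
            warnings.warn(f"gene {gene!r} constant across samples", stacklevel=2)
            rows.append((gene, float("nan"), 1.0, "none"))
            continue
        w, p = wilcoxon_ranksum(hi, lo)
        direction = "HIGH-up" if np.median(hi) > np.median(lo) else "LOW-up"
        rows.append((gene, w, p, direction))
    return pd.DataFrame(rows, columns=["gene", "W", "p", "direction"]).set_index("gene")
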