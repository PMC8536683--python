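"""Mutation-landscape summaries: per-gene mutation frequency, per-sample
tumor mutation burden (TMB), CNV gain/loss frequencies, and comparisons of
mutation burden between m6Ascore groups."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .diffexpr import wilcoxon_ranksum
from .io_formats import CnvMatrix, ExpressionMatrix, MutationTable

#: Conventional MAF nonsynonymous variant classes.
DEFAULT_NONSYN_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "Splice_Site",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Translation_Start_Site",
        "Nonstop_Mutation",
    }
)

#: Common whole-exome capture size estimate, in megabases.
DEFAULT_EXOME_MB = 38.0


@dataclass
class GeneMutationFrequency:
    per_gene: pd.DataFrame  # index gene; columns n_mutated, fraction
    panel_n_mutated: int  # samples with >= 1 mutation in ANY listed gene
    panel_fraction: float
    n_cohort: int


@dataclass
class TmbTable:
    table: pd.DataFrame  # index sample_id; columns n_mutations, tmb
    exome_mb: float

    def __post_init__(self) -> None:
        if (self.table["n_mutations"] < 0).any():
            raise ValueError("negative mutation count")
        expected = self.table["n_mutations"] / self.exome_mb
        if not np.allclose(self.table["tmb"], expected):
            raise ValueError("tmb must equal n_mutations / exome_mb")


def gene_mutation_frequency(
    mt: MutationTable, cohort_samples: Sequence[str], genes: Sequence[str]
) -> GeneMutationFrequency:
    """Fraction of cohort samples carrying >= 1 mutation per gene, plus the
    panel-level fraction (>= 1 mutation in any listed gene). Multiple
    records of one sample in one gene count once."""
    cohort = list(cohort_samples)
    if not cohort:
        raise ValueError("cohort_samples must be nonempty")
    n = len(cohort)
    rec = mt.records
    rec = rec[rec["sample_id"].isin(cohort) & rec["gene_symbol"].isin(list(genes))]
    pairs = rec[["sample_id", "gene_symbol"]].drop_duplicates()
    counts = pairs["gene_symbol"].value_counts()
    per_gene = pd.DataFrame(
        {
            "n_mutated": [int(counts.get(g, 0)) for g in genes],
            "fraction": [counts.get(g, 0) / n for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    panel_n = int(pairs["sample_id"].nunique())
    return GeneMutationFrequency(
        per_gene=per_gene,
        panel_n_mutated=panel_n,
        panel_fraction=panel_n / n,
        n_cohort=n,
    )


def tmb(
    mt: MutationTable,
    cohort_samples: Sequence[str],
    nonsyn_classes: frozenset[str] | set[str] = DEFAULT_NONSYN_CLASSES,
    exome_mb: float = DEFAULT_EXOME_MB,
) -> TmbTable:
    """Per-sample nonsynonymous mutation counts divided by the exome size in
    Mb; cohort samples absent from the mutation table get 0."""
    if exome_mb <= 0:
        raise ValueError("exome_mb must be positive")
    cohort = list(cohort_samples)
    rec = mt.records
    rec = rec[rec["sample_id"].isin(cohort) & rec["variant_class"].isin(list(nonsyn_classes))]
    counts = rec["sample_id"].value_counts()
    n_mut = np.array([int(counts.get(s, 0)) for s in cohort])
    table = pd.DataFrame(
        {"n_mutations": n_mut, "tmb": n_mut / exome_mb},
        index=pd.Index(cohort, name="sample_id"),
    )
    return TmbTable(table=table, exome_mb=exome_mb)


def cnv_frequency(c: CnvMatrix) -> pd.DataFrame:
    """Per-gene amplification (call > 0) and deletion (call < 0) fractions."""
    arr = c.calls.to_numpy()
    n = arr.shape[1]
    return pd.DataFrame(
        {
            "gain_fraction": (arr > 0).sum(axis=1) / n,
            "loss_fraction": (arr < 0).sum(axis=1) / n,
        },
        index=pd.Index(c.gene_ids, name="gene"),
    )


def mutated_vs_wildtype_expression(
    mt: MutationTable,
    m: ExpressionMatrix,
    mut_gene: str,
    expr_gene: str,
) -> tuple[float, float, str]:
    """Wilcoxon rank-sum of ``expr_gene`` expression between samples mutated
    vs wild-type for ``mut_gene``; direction is 'mutant-up'/'wildtype-up'."""
    if expr_gene not in m.values.index:
        raise KeyError(f"gene {expr_gene!r} absent from expression matrix")
    mutated = set(
        mt.records.loc[mt.records["gene_symbol"] == mut_gene, "sample_id"]
    )
    samples = m.sample_ids
    is_mut = np.array([s in mutated for s in samples])
    if not is_mut.any():
        raise ValueError(f"no sample mutated for {mut_gene!r}")
    if is_mut.all():
        raise ValueError(f"no wild-type sample for {mut_gene!r}")
    expr = m.values.loc[expr_gene].to_numpy()
    w, p = wilcoxon_ranksum(expr[is_mut], expr[~is_mut])
    direction = (
        "mutant-up" if expr[is_mut].mean() > expr[~is_mut].mean() else "wildtype-up"
    )
    return w, p, direction


def score_group_tmb_comparison(
    tmb_table: TmbTable, groups: pd.Series
) -> dict[str, float]:
    """Compare TMB between HIGH and LOW score groups: Wilcoxon rank-sum on
    per-sample TMB plus the any-nonsynonymous-mutation fraction per group."""
    shared = [s for s in tmb_table.table.index if s in groups.index]
    t = tmb_table.table.loc[shared]
    g = groups.loc[shared]
    hi, lo = t.loc[g == "HIGH"], t.loc[g == "LOW"]
    if hi.empty or lo.empty:
        raise ValueError("both HIGH and LOW groups must be nonempty")
    w, p = wilcoxon_ranksum(hi["tmb"], lo["tmb"])
    return {
        "W": w,
        "p": p,
        "median_tmb_high": float(hi["tmb"].median()),
        "median_tmb_low": float(lo["tmb"].median()),
        "mutated_fraction_high": float((hi["n_mutations"] > 0).mean()),
        "mutated_fraction_low": float((lo["n_mutations"] > 0).mean()),
    }
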