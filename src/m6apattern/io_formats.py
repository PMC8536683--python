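"""Containers and TSV/GMT readers for expression, clinical, mutation, CNV
and gene-set data, plus the packaged m6A regulator catalog.

All tabular formats are plain tab-delimited UTF-8 text with '.' decimals.
Gene identity is by symbol string, case-sensitive; no alias resolution.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TPM_TOTAL = 1e6


class ExpressionUnit(enum.Enum):
    """Scale of an expression matrix: raw FPKM, raw TPM, or log2(x+1)."""

    FPKM = "FPKM"
    TPM = "TPM"
    LOG2 = "LOG2"


@dataclass
class ExpressionMatrix:
    """Dense genes x samples abundance matrix with a unit tag.

    Invariants checked on construction: unique gene and sample ids, all
    values finite, and (for TPM) each sample column summing to 1e6 within
    relative tolerance 1e-6.
    """

    values: pd.DataFrame
    unit: ExpressionUnit = ExpressionUnit.LOG2

    def __post_init__(self) -> None:
        if isinstance(self.unit, str):
            self.unit = ExpressionUnit(self.unit.upper())
        idx, cols = self.values.index, self.values.columns
        if idx.duplicated().any():
            raise ValueError(
                f"duplicate gene ids: {sorted(idx[idx.duplicated()].unique())}"
            )
        if cols.duplicated().any():
            raise ValueError(
                f"duplicate sample ids: {sorted(cols[cols.duplicated()].unique())}"
            )
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at gene {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )
        self.values = self.values.astype(float)
        if self.unit is ExpressionUnit.TPM:
            sums = arr.sum(axis=0)
            if not np.allclose(sums, TPM_TOTAL, rtol=1e-6):
                off = cols[np.argmax(np.abs(sums - TPM_TOTAL))]
                raise ValueError(f"TPM column {off!r} does not sum to 1e6")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(genes)].copy(), self.unit)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing}")
        return ExpressionMatrix(self.values[list(samples)].copy(), self.unit)


class RegulatorCategory(enum.Enum):
    WRITER = "Writer"
    READER = "Reader"
    ERASER = "Eraser"


@dataclass(frozen=True)
class RegulatorEntry:
    symbol: str
    category: RegulatorCategory
    full_name: str


@dataclass
class RegulatorCatalog:
    """Catalog of m6A regulators: writers (methyltransferases), readers
    (m6A-binding proteins) and erasers (demethylases)."""

    entries: list[RegulatorEntry]

    def __post_init__(self) -> None:
        symbols = [e.symbol for e in self.entries]
        if len(set(symbols)) != len(symbols):
            raise ValueError("duplicate regulator symbols")
        present = {e.category for e in self.entries}
        if present != set(RegulatorCategory):
            raise ValueError("every regulator category must be nonempty")

    @property
    def symbols(self) -> list[str]:
        return [e.symbol for e in self.entries]

    def category_of(self, symbol: str) -> RegulatorCategory:
        for e in self.entries:
            if e.symbol == symbol:
                return e.category
        raise KeyError(symbol)

    def by_category(self, category: RegulatorCategory) -> list[str]:
        return [e.symbol for e in self.entries if e.category is category]


_W = RegulatorCategory.WRITER
_R = RegulatorCategory.READER
_E = RegulatorCategory.ERASER

#: The 23 m6A regulators: 8 writers, 13 readers, 2 erasers.
_REGULATORS: list[tuple[str, RegulatorCategory, str]] = [
    ("METTL3", _W, "Methyltransferase-like protein 3"),
    ("METTL14", _W, "Methyltransferase-like protein 14"),
    ("METTL16", _W, "Methyltransferase-like protein 16"),
    ("WTAP", _W, "Wilms tumor 1-associated protein"),
    ("VIRMA", _W, "Vir-like m6A methyltransferase associated protein"),
    ("ZC3H13", _W, "Zinc finger CCCH domain-containing protein 13"),
    ("RBM15", _W, "RNA-binding motif protein 15"),
    ("RBM15B", _W, "RNA binding motif protein 15B"),
    ("YTHDC1", _R, "YTH domain-containing 1"),
    ("YTHDC2", _R, "YTH domain-containing 2"),
    ("YTHDF1", _R, "YTH m6A RNA-binding protein 1"),
    ("YTHDF2", _R, "YTH m6A RNA-binding protein 2"),
    ("YTHDF3", _R, "YTH m6A RNA-binding protein 3"),
    ("HNRNPC", _R, "Heterogeneous nuclear ribonucleoprotein C"),
    ("FMR1", _R, "Fragile X mental retardation protein"),
    ("LRPPRC", _R, "Leucine-rich PPR-motif-containing protein"),
    ("HNRNPA2B1", _R, "Heterogeneous nuclear ribonucleoprotein A2B1"),
    ("IGFBP1", _R, "Insulin-like growth factor binding protein 1"),
    ("IGFBP2", _R, "Insulin-like growth factor binding protein 2"),
    ("IGFBP3", _R, "Insulin-like growth factor binding protein 3"),
    ("RBMX", _R, "X-linked RNA-binding motif protein"),
    ("FTO", _E, "Fat mass and obesity-associated protein"),
    ("ALKBH5", _E, "Alk B homologue 5"),
]


def default_regulator_catalog() -> RegulatorCatalog:
    """Return the packaged catalog of the 23 m6A regulators."""
    return RegulatorCatalog(
        [RegulatorEntry(sym, cat, name) for sym, cat, name in _REGULATORS]
    )


@dataclass
class ClinicalTable:
    """Per-sample overall-survival data plus optional covariates.

    ``table`` is indexed by sample id with columns ``os_time`` (nonnegative,
    in ``time_unit``), ``os_event`` (0 censored / 1 event), and optional
    ``age`` (years), ``gender`` and ``stage`` (ordinal 1-4). Missing
    covariates propagate as NaN; samples without survival information are
    dropped by the reader.
    """

    table: pd.DataFrame
    time_unit: str = "days"

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        t = self.table["os_time"].to_numpy(dtype=float)
        e = self.table["os_event"].to_numpy(dtype=float)
        if (t < 0).any():
            bad = self.table.index[t < 0][0]
            raise ValueError(f"negative os_time for sample {bad!r}")
        if not np.isin(e, (0.0, 1.0)).all():
            bad = self.table.index[~np.isin(e, (0.0, 1.0))][0]
            raise ValueError(f"os_event outside {{0,1}} for sample {bad!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def aligned_to(self, samples: Sequence[str]) -> "ClinicalTable":
        missing = [s for s in samples if s not in self.table.index]
        if missing:
            raise KeyError(f"samples absent from clinical table: {missing}")
        return ClinicalTable(self.table.loc[list(samples)].copy(), self.time_unit)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class GeneSetCollection:
    """Named gene sets, e.g. immune-cell signatures or pathway collections."""

    sets: list[GeneSet]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene-set names")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class MutationTable:
    """Long-format somatic mutation records (sample, gene, variant class)."""

    records: pd.DataFrame  # columns: sample_id, gene_symbol, variant_class

    def __post_init__(self) -> None:
        req = ["sample_id", "gene_symbol", "variant_class"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise ValueError(f"mutation table missing columns: {missing}")
        self.records = self.records[req].astype(str).reset_index(drop=True)
        if (self.records["sample_id"].str.len() == 0).any():
            raise ValueError("mutation record with empty sample id")
        if (self.records["gene_symbol"].str.len() == 0).any():
            raise ValueError("mutation record with empty gene symbol")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class CnvMatrix:
    """Gene x sample integer copy-number calls in {-2,-1,0,1,2} (GISTIC-like)."""

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.calls.to_numpy()
        if not np.isin(arr, (-2, -1, 0, 1, 2)).all():
            gi, sj = np.argwhere(~np.isin(arr, (-2, -1, 0, 1, 2)))[0]
            raise ValueError(
                f"CNV call out of code set at gene {self.calls.index[gi]!r}, "
                f"sample {self.calls.columns[sj]!r}"
            )
        self.calls = self.calls.astype(int)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.columns)


# ---------------------------------------------------------------------------
# readers / writers


def _read_header(path: Path | str) -> list[str]:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                return line.rstrip("\n").split("\t")
    raise ValueError(f"{path}: empty file")


def read_expression(
    path: Path | str, unit_hint: ExpressionUnit | str = ExpressionUnit.LOG2
) -> ExpressionMatrix:
    """Read a genes x samples TSV (header row of sample ids, first column
    gene ids). Duplicate gene rows are collapsed by arithmetic mean (logged);
    duplicate sample columns are a hard error."""
    header = _read_header(path)
    if len(header) < 2:
        raise ValueError(f"{path}: malformed header (need gene column + samples)")
    samples = header[1:]
    dup = {s for s in samples if samples.count(s) > 1}
    if dup:
        raise ValueError(f"{path}: duplicate sample columns: {sorted(dup)}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.columns = samples
    try:
        df = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError):
        for col in df.columns:
            conv = pd.to_numeric(df[col], errors="coerce")
            bad = conv.isna() & df[col].notna()
            if bad.any():
                raise ValueError(
                    f"{path}: non-numeric cell at gene {df.index[bad][0]!r}, "
                    f"sample {col!r}"
                ) from None
        raise
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        log.info("collapsing %d duplicate gene rows by mean", n_dup)
        df = df.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(df, ExpressionUnit(unit_hint) if isinstance(unit_hint, str) else unit_hint)


def write_expression(m: ExpressionMatrix, path: Path | str) -> None:
    out = m.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def fpkm_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Convert FPKM to TPM: TPM_ij = FPKM_ij / sum_i FPKM_ij * 1e6.

    Each sample column is rescaled to sum to one million, making abundances
    comparable across samples."""
    if m.unit is not ExpressionUnit.FPKM:
        raise ValueError(f"expected FPKM input, got {m.unit.value}")
    arr = m.values.to_numpy()
    if (arr < 0).any():
        raise ValueError("negative FPKM values")
    sums = arr.sum(axis=0)
    if (sums <= 0).any():
        bad = m.values.columns[np.argmax(sums <= 0)]
        raise ValueError(f"zero-sum expression column for sample {bad!r}")
    out = pd.DataFrame(
        arr / sums * TPM_TOTAL, index=m.values.index, columns=m.values.columns
    )
    return ExpressionMatrix(out, ExpressionUnit.TPM)


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x+1)-transform unless already on the log2 scale (applied exactly
    once, at pipeline entry)."""
    if m.unit is ExpressionUnit.LOG2:
        return m
    return ExpressionMatrix(np.log2(m.values + 1.0), ExpressionUnit.LOG2)


def read_gmt(path: Path | str) -> GeneSetCollection:
    """Read a GMT file: one set per line, 'name TAB description TAB members...'.
    Duplicate members within a line are de-duplicated (first occurrence)."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: GMT line has fewer than 3 fields")
            name, desc = fields[0], fields[1]
            if name in seen:
                raise ValueError(f"{path}:{ln}: duplicate gene-set name {name!r}")
            seen.add(name)
            members = frozenset(g for g in fields[2:] if g)
            sets.append(GeneSet(name, desc, members))
    return GeneSetCollection(sets)


def write_gmt(gsc: GeneSetCollection, path: Path | str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in gsc.sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


_MAF_COLUMNS = {
    "Tumor_Sample_Barcode": "sample_id",
    "Hugo_Symbol": "gene_symbol",
    "Variant_Classification": "variant_class",
}


def read_maf(path: Path | str) -> MutationTable:
    """Read a MAF-subset TSV (Tumor_Sample_Barcode, Hugo_Symbol,
    Variant_Classification); extra columns are ignored."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required MAF columns: {missing}")
    return MutationTable(df[list(_MAF_COLUMNS)].rename(columns=_MAF_COLUMNS))


def write_maf(mt: MutationTable, path: Path | str) -> None:
    inv = {v: k for k, v in _MAF_COLUMNS.items()}
    mt.records.rename(columns=inv).to_csv(path, sep="\t", index=False)


_STAGE_MAP = {"I": 1, "II": 2, "III": 3, "IV": 4, "1": 1, "2": 2, "3": 3, "4": 4}


def read_clinical(path: Path | str, time_unit: str = "days") -> ClinicalTable:
    """Read a clinical TSV with columns sample_id, os_time, os_event and
    optional age, gender, stage. Samples lacking os_time or os_event are
    dropped (count logged); invalid values are hard errors."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "os_time", "os_event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required clinical columns: {missing}")
    df = df.set_index("sample_id")
    os_time = pd.to_numeric(df["os_time"], errors="coerce")
    os_event = pd.to_numeric(df["os_event"], errors="coerce")
    keep = os_time.notna() & os_event.notna() & df["os_time"].notna() & df["os_event"].notna()
    # distinguish missing (blank) from malformed: blanks are dropped, other
    # unparsable strings raise
    raw_t, raw_e = df["os_time"].fillna(""), df["os_event"].fillna("")
    malformed = (os_time.isna() & (raw_t.str.strip() != "")) | (
        os_event.isna() & (raw_e.str.strip() != "")
    )
    if malformed.any():
        raise ValueError(
            f"{path}: non-numeric survival field for sample "
            f"{df.index[malformed][0]!r}"
        )
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("dropping %d samples without survival information", n_drop)
    df = df[keep]
    out = pd.DataFrame(index=df.index)
    out["os_time"] = os_time[keep]
    out["os_event"] = os_event[keep].astype(int)
    out["age"] = pd.to_numeric(df["age"], errors="coerce") if "age" in df else np.nan
    out["gender"] = df["gender"] if "gender" in df else None
    if "stage" in df:
        out["stage"] = df["stage"].map(lambda s: _STAGE_MAP.get(str(s).strip(), np.nan))
    else:
        out["stage"] = np.nan
    return ClinicalTable(out, time_unit)


def write_clinical(ct: ClinicalTable, path: Path | str) -> None:
    out = ct.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_cnv(path: Path | str) -> CnvMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CnvMatrix(df)


def write_cnv(c: CnvMatrix, path: Path | str) -> None:
    out = c.calls.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
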