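"""Synthetic LUAD-like cohort generator.

Emits a single pre-integrated expression matrix (log2 scale) carrying three
planted expression subtypes over the 23-regulator panel plus phenotype,
immune-signature and background genes; subtype-linked exponential survival
with uniform censoring; overdispersed per-sample mutation counts inversely
coupled to a latent prognosis score; GISTIC-like CNV calls; and per-sample
immunotherapy-response scores positively coupled to that latent score.

The generator is a pure function of its config: the same seed yields a
byte-identical cohort. Its defaults define the study conditions every
downstream twin test runs under.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_formats import (
    ClinicalTable,
    CnvMatrix,
    ExpressionMatrix,
    ExpressionUnit,
    GeneSet,
    GeneSetCollection,
    MutationTable,
    default_regulator_catalog,
    write_clinical,
    write_cnv,
    write_expression,
    write_gmt,
    write_maf,
)

SUBTYPES = ("A", "B", "C")

#: Regulator blocks up-shifted in each planted subtype.
SUBTYPE_REGULATOR_BLOCKS: dict[str, tuple[str, ...]] = {
    "A": ("METTL14", "RBM15", "YTHDC1", "YTHDC2", "FMR1", "HNRNPA2B1"),
    "B": ("IGFBP1", "IGFBP3"),
    "C": ("RBM15B", "YTHDF2", "IGFBP2", "FTO", "ALKBH5"),
}

#: Regulators with an amplification- vs deletion-dominant CNV profile.
_CNV_GAIN_TREND = (
    "YTHDF1", "VIRMA", "FMR1", "METTL3", "HNRNPC", "RBMX", "YTHDF3",
    "HNRNPA2B1", "LRPPRC", "IGFBP1", "IGFBP3", "FTO", "YTHDC1",
)

RESPONSE_STRATA = (
    "CTLA4neg_PD1pos",
    "CTLA4pos_PD1neg",
    "CTLA4pos_PD1pos",
    "CTLA4neg_PD1neg",
)

_IMMUNE_SET_NAMES = (
    "Immune_Activated_CD8_T_cell",
    "Immune_Activated_B_cell",
    "Immune_Natural_killer_cell",
    "Immune_Macrophage",
    "Immune_Activated_dendritic_cell",
    "Immune_T_follicular_helper_cell",
)

_VARIANT_CLASSES = (
    ("Missense_Mutation", 0.60),
    ("Nonsense_Mutation", 0.10),
    ("Frame_Shift_Del", 0.08),
    ("Frame_Shift_Ins", 0.06),
    ("Splice_Site", 0.06),
    ("In_Frame_Del", 0.04),
    ("In_Frame_Ins", 0.03),
    ("Nonstop_Mutation", 0.02),
    ("Translation_Start_Site", 0.01),
)

#: NB dispersion (size) for mutation counts; overdispersion typical of TMB.
NB_SIZE = 2.0
#: Within-subtype coupling of mutation burden to the protective frailty.
TMB_LATENT_COUPLING = 0.35
#: Baseline exponential hazard: median survival 36 months at log-hazard 0.
BASELINE_HAZARD = np.log(2) / 36.0
#: SD of the continuous protective frailty g.
FRAILTY_SD = 0.5


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the planted cohort structure.

    Shifts are mean log2-expression offsets; hazards are log hazard ratios
    relative to the cohort baseline; TMB means are expected nonsynonymous
    mutation counts per sample.
    """

    n_samples: int = 600
    subtype_proportions: tuple[float, float, float] = (0.45, 0.18, 0.37)
    n_background_genes: int = 200
    n_phenotype_genes: int = 90
    regulator_shift: float = 1.2
    phenotype_shift: float = 1.0
    #: log2-expression loading of phenotype genes on the standardized latent
    #: prognosis score (positive for the A/C blocks, negative for the B
    #: block); gives the continuous score analyses genuine signal beyond the
    #: cluster-level means.
    phenotype_latent_coupling: float = 0.4
    immune_shift: float = 1.0
    noise_sd: float = 1.0
    hazard_log_hr: tuple[float, float, float] = (-0.5, 0.8, -0.3)
    censor_rate: float = 0.5
    tmb_mean_by_subtype: tuple[float, float, float] = (40.0, 120.0, 60.0)
    response_shift: float = 0.8
    seed: int = 42

    def __post_init__(self) -> None:
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ValueError("subtype proportions must sum to 1")
        if min(self.subtype_proportions) < 0:
            raise ValueError("subtype proportions must be nonnegative")
        if self.n_samples < 30:
            raise ValueError("n_samples must be at least 30")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0.0 < self.censor_rate < 1.0):
            raise ValueError("censor_rate must lie in (0,1)")
        if min(self.tmb_mean_by_subtype) <= 0:
            raise ValueError("TMB means must be positive")

    def to_json(self, path: Path | str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: Path | str) -> "CohortConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown cohort-config keys: {sorted(unknown)}")
        for key in ("subtype_proportions", "hazard_log_hr", "tmb_mean_by_subtype"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    truth: pd.DataFrame  # index sample_id; columns subtype, latent_score
    mutations: MutationTable
    cnv: CnvMatrix
    response: pd.DataFrame  # index sample_id; columns stratum, response_score
    gene_sets: GeneSetCollection
    config: CohortConfig

    def __post_init__(self) -> None:
        ids = set(self.expression.sample_ids)
        for name, other in (
            ("clinical", set(self.clinical.sample_ids)),
            ("truth", set(self.truth.index)),
            ("cnv", set(self.cnv.sample_ids)),
            ("response", set(self.response.index)),
        ):
            if other != ids:
                raise ValueError(f"sample ids of {name} do not match expression")
        if not set(self.truth["subtype"]).issubset(set(SUBTYPES)):
            raise ValueError("truth subtype labels must be in {A,B,C}")

    @property
    def immune_sets(self) -> GeneSetCollection:
        return GeneSetCollection(
            [s for s in self.gene_sets if s.name.startswith("Immune_")]
        )

    @property
    def pathway_sets(self) -> GeneSetCollection:
        return GeneSetCollection(
            [s for s in self.gene_sets if s.name.startswith("Pathway_")]
        )


def default_config() -> CohortConfig:
    """The documented default study conditions (n=600, proportions
    0.45/0.18/0.37 emulating the 646/262/522 pattern sizes)."""
    return CohortConfig()


def _subtype_counts(cfg: CohortConfig) -> list[int]:
    # largest-remainder apportionment -> exact, deterministic sizes
    raw = [p * cfg.n_samples for p in cfg.subtype_proportions]
    counts = [int(np.floor(r)) for r in raw]
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in range(cfg.n_samples - sum(counts)):
        counts[order[i]] += 1
    shifts = (cfg.regulator_shift, cfg.regulator_shift, cfg.regulator_shift)
    for c, s in zip(counts, shifts):
        if c == 0 and s != 0:
            raise ValueError("a subtype with a planted shift has 0 samples")
    return counts


def _solve_censor_scale(rates: np.ndarray, censor_rate: float) -> float:
    """Upper bound c of Uniform(0,c) censoring s.t. the expected censored
    fraction equals censor_rate (events: T ~ Exp(rate), censored iff C < T)."""

    def expected_event_rate(c: float) -> float:
        lc = rates * c
        return float(np.mean(1.0 - (1.0 - np.exp(-lc)) / lc))

    target = 1.0 - censor_rate
    lo, hi = 1e-9, 1e9
    return float(brentq(lambda c: expected_event_rate(c) - target, lo, hi, xtol=1e-10))


def generate(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a cohort with the planted structure described in the module
    docstring. All randomness flows from ``config.seed``."""
    cfg = config or default_config()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]

    counts = _subtype_counts(cfg)
    subtype = np.repeat(np.array(SUBTYPES), counts)
    subtype = subtype[rng.permutation(n)]
    sub_idx = {s: np.flatnonzero(subtype == s) for s in SUBTYPES}

    # latent prognosis score: subtype hazard component + continuous frailty
    hz = dict(zip(SUBTYPES, cfg.hazard_log_hr))
    g_frailty = rng.normal(0.0, FRAILTY_SD, size=n)
    log_hazard = np.array([hz[s] for s in subtype]) - g_frailty
    latent = -log_hazard  # high = good prognosis
    z_lat = (latent - latent.mean()) / latent.std()

    catalog = default_regulator_catalog()
    regulators = catalog.symbols
    immune_genes = [f"IMM{i:03d}" for i in range(1, 47)] + ["CD80", "CD86"]
    n_ph = cfg.n_phenotype_genes
    phenotype_genes = [f"PHG{i:03d}" for i in range(1, n_ph + 1)]
    background_genes = [f"BG{i:04d}" for i in range(1, cfg.n_background_genes + 1)]
    genes = regulators + immune_genes + phenotype_genes + background_genes

    base = rng.uniform(2.0, 8.0, size=len(genes))
    mean = np.tile(base[:, None], (1, n))
    gpos = {g: i for i, g in enumerate(genes)}

    for s, block in SUBTYPE_REGULATOR_BLOCKS.items():
        rows = [gpos[g] for g in block]
        mean[np.ix_(rows, sub_idx[s])] += cfg.regulator_shift
    # immune-signature genes elevated in subtype A
    imm_rows = [gpos[g] for g in immune_genes]
    mean[np.ix_(imm_rows, sub_idx["A"])] += cfg.immune_shift
    # phenotype genes: three blocks, each up in one subtype -> recoverable
    # DEGs; on top, every block loads on the standardized latent prognosis
    # score (A/C blocks positively, B block negatively) so the continuous
    # PCA score carries prognostic signal, not just cluster-level contrast
    blocks = np.array_split(np.arange(n_ph), 3)
    phenotype_blocks: dict[str, list[str]] = {}
    for s, blk in zip(SUBTYPES, blocks):
        rows = [gpos[phenotype_genes[i]] for i in blk]
        phenotype_blocks[s] = [phenotype_genes[i] for i in blk]
        mean[np.ix_(rows, sub_idx[s])] += cfg.phenotype_shift
        load = cfg.phenotype_latent_coupling * (-1.0 if s == "B" else 1.0)
        mean[rows, :] += load * z_lat[None, :]

    values = mean + rng.normal(0.0, cfg.noise_sd, size=mean.shape)
    expression = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=sample_ids), ExpressionUnit.LOG2
    )

    # survival: exponential event times, frailty-protective log-hazard
    rates = BASELINE_HAZARD * np.exp(log_hazard)
    event_t = rng.exponential(1.0 / rates)
    c_scale = _solve_censor_scale(rates, cfg.censor_rate)
    censor_t = rng.uniform(0.0, c_scale, size=n)
    os_time = np.minimum(event_t, censor_t)
    os_event = (event_t <= censor_t).astype(int)

    age = np.clip(np.round(rng.normal(65.0, 10.0, size=n)), 30, 90)
    gender = rng.choice(["F", "M"], size=n)
    stage_probs = {
        "A": (0.55, 0.25, 0.15, 0.05),
        "B": (0.25, 0.25, 0.35, 0.15),
        "C": (0.55, 0.25, 0.15, 0.05),
    }
    stage = np.empty(n, dtype=int)
    for s in SUBTYPES:
        idx = sub_idx[s]
        stage[idx] = rng.choice([1, 2, 3, 4], size=len(idx), p=stage_probs[s])
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "os_time": os_time,
                "os_event": os_event,
                "age": age,
                "gender": gender,
                "stage": stage,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        ),
        time_unit="months",
    )

    # mutations: NB counts, mean by subtype scaled down with the frailty
    tmb_mean = dict(zip(SUBTYPES, cfg.tmb_mean_by_subtype))
    mu = np.array([tmb_mean[s] for s in subtype]) * np.exp(
        -TMB_LATENT_COUPLING * g_frailty
    )
    n_mut = rng.negative_binomial(NB_SIZE, NB_SIZE / (NB_SIZE + mu))
    # gene draw: regulator panel carries 25% of mutations, ZC3H13 heaviest
    reg_w = np.array([4.0 if g == "ZC3H13" else 1.0 for g in regulators])
    pool = regulators + background_genes
    weights = np.concatenate(
        [0.25 * reg_w / reg_w.sum(),
         np.full(len(background_genes), 0.75 / len(background_genes))]
    )
    vc_names = [v for v, _ in _VARIANT_CLASSES]
    vc_probs = np.array([p for _, p in _VARIANT_CLASSES])
    recs: list[tuple[str, str, str]] = []
    for sid, k in zip(sample_ids, n_mut):
        if k == 0:
            continue
        muts = rng.choice(len(pool), size=k, p=weights)
        classes = rng.choice(len(vc_names), size=k, p=vc_probs)
        recs.extend((sid, pool[g], vc_names[c]) for g, c in zip(muts, classes))
        n_silent = rng.poisson(0.15 * k)
        if n_silent:
            sil = rng.choice(len(pool), size=n_silent, p=weights)
            recs.extend((sid, pool[g], "Silent") for g in sil)
    mutations = MutationTable(
        pd.DataFrame(recs, columns=["sample_id", "gene_symbol", "variant_class"])
    )

    # CNV: regulators get trend-specific gain/loss probabilities
    calls = np.zeros((len(regulators), n), dtype=int)
    for i, g in enumerate(regulators):
        p_gain, p_loss = (0.25, 0.05) if g in _CNV_GAIN_TREND else (0.05, 0.25)
        u = rng.uniform(size=n)
        amp = rng.choice([1, 2], size=n, p=[0.7, 0.3])
        dele = rng.choice([-1, -2], size=n, p=[0.7, 0.3])
        calls[i] = np.where(u < p_gain, amp, np.where(u < p_gain + p_loss, dele, 0))
    cnv = CnvMatrix(pd.DataFrame(calls, index=regulators, columns=sample_ids))

    # immunotherapy response: positively coupled to the latent score
    stratum = rng.choice(RESPONSE_STRATA, size=n)
    response_score = cfg.response_shift * z_lat + rng.normal(0.0, 1.0, size=n)
    response = pd.DataFrame(
        {"stratum": stratum, "response_score": response_score},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # toy gene sets: 6 immune signatures (8 genes each) + 4 pathway sets
    sets: list[GeneSet] = []
    for i, name in enumerate(_IMMUNE_SET_NAMES):
        members = frozenset(immune_genes[8 * i : 8 * (i + 1)])
        sets.append(GeneSet(name, "synthetic immune-cell signature", members))
    sets.append(
        GeneSet(
            "Pathway_immune_activation",
            "synthetic pathway up in subtype A",
            frozenset(immune_genes[:12]),
        )
    )
    sets.append(
        GeneSet(
            "Pathway_oncogenic_activation",
            "synthetic pathway up in subtype B",
            frozenset(phenotype_blocks["B"][:12]),
        )
    )
    sets.append(
        GeneSet(
            "Pathway_substance_metabolism",
            "synthetic pathway up in subtype C",
            frozenset(phenotype_blocks["C"][:12]),
        )
    )
    sets.append(
        GeneSet(
            "Pathway_background",
            "synthetic null pathway",
            frozenset(background_genes[:12]),
        )
    )
    gene_sets = GeneSetCollection(sets)

    truth = pd.DataFrame(
        {"subtype": subtype, "latent_score": latent},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    return SyntheticCohort(
        expression=expression,
        clinical=clinical,
        truth=truth,
        mutations=mutations,
        cnv=cnv,
        response=response,
        gene_sets=gene_sets,
        config=cfg,
    )


def phenotype_gene_blocks(cohort: SyntheticCohort) -> dict[str, list[str]]:
    """Planted phenotype-gene blocks keyed by the subtype they are up in."""
    n_ph = cohort.config.n_phenotype_genes
    names = [f"PHG{i:03d}" for i in range(1, n_ph + 1)]
    blocks = np.array_split(np.arange(n_ph), 3)
    return {s: [names[i] for i in blk] for s, blk in zip(SUBTYPES, blocks)}


def write_cohort(cohort: SyntheticCohort, outdir: Path | str) -> dict[str, Path]:
    """Write the cohort as the standard file bundle; returns written paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "clinical": out / "clinical.tsv",
        "mutations": out / "mutations.maf.tsv",
        "cnv": out / "cnv.tsv",
        "response": out / "response.tsv",
        "gene_sets": out / "sets.gmt",
        "truth": out / "truth.tsv",
        "config": out / "config.json",
    }
    write_expression(cohort.expression, paths["expression"])
    write_clinical(cohort.clinical, paths["clinical"])
    write_maf(cohort.mutations, paths["mutations"])
    write_cnv(cohort.cnv, paths["cnv"])
    cohort.response.to_csv(paths["response"], sep="\t")
    write_gmt(cohort.gene_sets, paths["gene_sets"])
    cohort.truth.to_csv(paths["truth"], sep="\t")
    cohort.config.to_json(paths["config"])
    return paths
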