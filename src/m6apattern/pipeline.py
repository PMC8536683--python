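"""End-to-end orchestration: simulate-or-load -> regulator consensus
clustering -> immune ssGSEA -> pathway GSVA contrasts -> phenotype DEGs ->
DEG-panel gene clustering -> prognostic filter + m6Ascore -> survival
models -> mutation summaries -> immunotherapy comparisons.

A single global seed makes the full run reproducible; every stage writes
its outputs under the configured directory and the machine-readable
``report.json`` records provenance (config hash, seed, version).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .consensus_cluster import adjusted_rand_index, consensus_cluster
from .diffexpr import kruskal_wallis, phenotype_degs
from .enrichment import gsva, score_group_contrast, ssgsea
from .immunotherapy import STRATA, ResponseTable, compare_response, ligand_contrast
from .io_formats import (
    ClinicalTable,
    ExpressionMatrix,
    default_regulator_catalog,
    log2_transform,
    read_clinical,
    read_cnv,
    read_expression,
    read_gmt,
    read_maf,
)
from .m6ascore import (
    compute_m6ascore,
    dichotomize_score,
    prognostic_filter,
    score_immune_correlation,
)
from .mutation import (
    DEFAULT_EXOME_MB,
    cnv_frequency,
    gene_mutation_frequency,
    score_group_tmb_comparison,
    tmb,
)
from .survival import cox_fit, km_estimate, logrank_test, median_survival
from .synthetic_cohort import CohortConfig, generate, write_cohort

log = logging.getLogger(__name__)

STAGES = (
    "cluster",
    "immune",
    "pathway",
    "deg",
    "genecluster",
    "score",
    "survival",
    "mutation",
    "immuno",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Serializable configuration of every pipeline stage.

    Either ``simulate`` (a :class:`CohortConfig`) or ``inputs`` (paths to
    expression/clinical/... files) must be given. Unknown JSON keys are
    rejected before any compute."""

    outdir: str = "m6apattern_out"
    seed: int = 42
    simulate: CohortConfig | None = field(default_factory=CohortConfig)
    inputs: dict | None = None
    expression_unit: str = "LOG2"
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    n_resamples: int = 1000
    item_fraction: float = 0.8
    ssgsea_alpha: float = 0.25
    gsva_tau: float = 1.0
    deg_p_threshold: float = 0.05
    deg_mode: str = "union"
    prognostic_p: float = 0.05
    minprop: float = 0.1
    exome_mb: float = DEFAULT_EXOME_MB
    skip_stages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs either 'simulate' or 'inputs'")
        unknown = set(self.skip_stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown skip stages: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_json(cls, path: Path | str) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline-config keys: {sorted(unknown)}")
        if raw.get("simulate") is not None:
            sim = raw["simulate"]
            sim_known = {f.name for f in dataclasses.fields(CohortConfig)}
            sim_unknown = set(sim) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown cohort-config keys: {sorted(sim_unknown)}")
            for key in ("subtype_proportions", "hazard_log_hr", "tmb_mean_by_subtype"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            raw["simulate"] = CohortConfig(**sim)
        for key in ("k_range", "skip_stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        # hash of the scientific parameters only: where outputs land (and
        # which cached stages are skipped) does not change the analysis
        d = self.to_dict()
        d.pop("outdir", None)
        d.pop("skip_stages", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    outdir: Path
    report: dict
    files: dict[str, Path]

    def validate(self) -> None:
        for name, path in self.files.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"missing stage output {name}: {path}")
        for key in ("config_hash", "seed", "version"):
            if key not in self.report.get("provenance", {}):
                raise ValueError(f"provenance incomplete: missing {key}")


def _load_inputs(cfg: PipelineConfig):
    paths = cfg.inputs
    expr = read_expression(paths["expression"], cfg.expression_unit)
    expr = log2_transform(expr)
    clinical = read_clinical(paths["clinical"])
    sets = read_gmt(paths["gene_sets"]) if "gene_sets" in paths else None
    mutations = read_maf(paths["mutations"]) if "mutations" in paths else None
    cnv = read_cnv(paths["cnv"]) if "cnv" in paths else None
    response = (
        ResponseTable.read_tsv(paths["response"]) if "response" in paths else None
    )
    truth = (
        pd.read_csv(paths["truth"], sep="\t", index_col=0) if "truth" in paths else None
    )
    return expr, clinical, sets, mutations, cnv, response, truth


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute all stages in order and return the report bundle. Stage
    failures abort with the stage name; outputs written so far remain."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "version": __version__,
        }
    }
    files: dict[str, Path] = {}

    if cfg.simulate is not None:
        sim_cfg = dataclasses.replace(cfg.simulate, seed=cfg.seed)
        cohort = generate(sim_cfg)
        write_cohort(cohort, out / "cohort")
        expr, clinical = cohort.expression, cohort.clinical
        immune_sets, pathway_sets = cohort.immune_sets, cohort.pathway_sets
        mutations, cnv, truth = cohort.mutations, cohort.cnv, cohort.truth
        response = ResponseTable.from_frame(cohort.response)
    else:
        expr, clinical, sets, mutations, cnv, response, truth = _load_inputs(cfg)
        immune_sets = pathway_sets = sets
    clinical = clinical.aligned_to(expr.sample_ids)
    times = clinical.table["os_time"].to_numpy()
    events = clinical.table["os_event"].to_numpy()

    def stage(name):
        def deco(fn):
            if name in cfg.skip_stages:
                log.info("skipping stage %s", name)
                return None
            log.info("running stage %s", name)
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - annotate stage name
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return deco

    # (1) regulator-panel consensus clustering
    catalog = default_regulator_catalog()
    panel = [g for g in catalog.symbols if g in expr.values.index]
    clusters = None

    @stage("cluster")
    def _cluster():
        nonlocal clusters
        res = consensus_cluster(
            expr,
            panel,
            k_range=cfg.k_range,
            n_resamples=cfg.n_resamples,
            item_fraction=cfg.item_fraction,
            seed=cfg.seed,
        )
        clusters = pd.Series(
            res.assignments[res.chosen_k], index=expr.sample_ids, name="m6Acluster"
        )
        path = out / "m6acluster_assignments.tsv"
        clusters.rename_axis("sample_id").to_csv(path, sep="\t")
        files["cluster_assignments"] = path
        stability = {
            "chosen_k": res.chosen_k,
            "cdf_area": {str(k): v for k, v in res.cdf_area.items()},
            "delta_area": {str(k): v for k, v in res.delta_area.items()},
        }
        with open(out / "m6acluster_stability.json", "w", encoding="utf-8") as fh:
            json.dump(stability, fh, indent=2)
        files["cluster_stability"] = out / "m6acluster_stability.json"
        report["cluster"] = {"chosen_k": res.chosen_k}
        if truth is not None and "subtype" in truth:
            report["cluster"]["ari_vs_truth"] = adjusted_rand_index(
                clusters.to_numpy(), truth.loc[expr.sample_ids, "subtype"].to_numpy()
            )
        return res

    if clusters is None:
        cached = out / "m6acluster_assignments.tsv"
        if cached.exists():
            clusters = pd.read_csv(cached, sep="\t", index_col=0).iloc[:, 0]
        else:
            raise RuntimeError("stage 'cluster' skipped but no cached assignments")

    # (2) immune ssGSEA + per-cluster Kruskal-Wallis
    immune_scores = None

    @stage("immune")
    def _immune():
        nonlocal immune_scores
        immune_scores = ssgsea(expr, immune_sets, alpha=cfg.ssgsea_alpha)
        path = out / "immune_ssgsea.tsv"
        immune_scores.scores.rename_axis("set").to_csv(path, sep="\t")
        files["immune_ssgsea"] = path
        kw = {}
        for name in immune_scores.set_names:
            vals = immune_scores.scores.loc[name].to_numpy(dtype=float)
            if np.isnan(vals).all():
                continue
            h, p = kruskal_wallis(vals, clusters.to_numpy())
            kw[name] = {"H": h, "p": p}
        report["immune"] = {"kruskal_wallis": kw}

    # (3) pathway GSVA + pairwise contrasts
    @stage("pathway")
    def _pathway():
        scores = gsva(expr, pathway_sets, tau=cfg.gsva_tau)
        path = out / "pathway_gsva.tsv"
        scores.scores.rename_axis("set").to_csv(path, sep="\t")
        files["pathway_gsva"] = path
        labels = clusters.to_numpy()
        uniq = sorted(pd.unique(labels))
        contrasts = {}
        for i, a in enumerate(uniq):
            for b in uniq[i + 1 :]:
                tab = score_group_contrast(scores, labels, (a, b))
                key = f"{a}_vs_{b}"
                cpath = out / f"gsva_contrast_{key}.tsv"
                tab.rename_axis("set").to_csv(cpath, sep="\t")
                files[f"gsva_contrast_{key}"] = cpath
                contrasts[key] = {
                    "top_set": tab.index[0],
                    "top_adj_p": float(tab["adj_p"].iloc[0]),
                }
        report["pathway"] = contrasts

    # (4) phenotype DEGs
    degs: set[str] = set()

    @stage("deg")
    def _deg():
        nonlocal degs
        degs, _tables = phenotype_degs(
            expr, clusters.to_numpy(), cfg.deg_p_threshold, cfg.deg_mode
        )
        path = out / "phenotype_degs.txt"
        path.write_text("\n".join(sorted(degs)) + "\n", encoding="utf-8")
        files["phenotype_degs"] = path
        report["deg"] = {"n_degs": len(degs)}

    if not degs:
        cached = out / "phenotype_degs.txt"
        if cached.exists():
            degs = set(cached.read_text(encoding="utf-8").split())
        else:
            raise RuntimeError("stage 'deg' skipped but no cached DEG list")

    # (5) DEG-panel consensus clustering (geneclusters); k re-selected by the
    # same delta-area rule, not forced to 3
    geneclusters = None

    @stage("genecluster")
    def _genecluster():
        nonlocal geneclusters
        res = consensus_cluster(
            expr,
            sorted(degs),
            k_range=cfg.k_range,
            n_resamples=cfg.n_resamples,
            item_fraction=cfg.item_fraction,
            seed=cfg.seed + 1,
        )
        geneclusters = pd.Series(
            res.assignments[res.chosen_k], index=expr.sample_ids, name="genecluster"
        )
        path = out / "genecluster_assignments.tsv"
        geneclusters.rename_axis("sample_id").to_csv(path, sep="\t")
        files["genecluster_assignments"] = path
        report["genecluster"] = {"chosen_k": res.chosen_k}
        return res

    # (6) prognostic filter + m6Ascore + dichotomization
    score_table = None

    @stage("score")
    def _score():
        nonlocal score_table
        kept, prog_tab = prognostic_filter(
            expr, sorted(degs), clinical, cfg.prognostic_p
        )
        protective = list(prog_tab.index[prog_tab["direction"] == "protective"])
        st = compute_m6ascore(expr, kept, protective_genes=protective)
        score_table = dichotomize_score(st, clinical, cfg.minprop)
        path = out / "m6ascore.tsv"
        score_table.table.to_csv(path, sep="\t")
        files["m6ascore"] = path
        prog_path = out / "prognostic_genes.tsv"
        prog_tab.to_csv(prog_path, sep="\t")
        files["prognostic_genes"] = prog_path
        report["score"] = {
            "n_signature_genes": len(score_table.signature_genes),
            "cutpoint": score_table.cutpoint,
            "n_high": int((score_table.groups == "HIGH").sum()),
            "n_low": int((score_table.groups == "LOW").sum()),
        }

    # (7) survival models
    @stage("survival")
    def _survival():
        surv_report = {}
        for name, labels in (
            ("m6Acluster", clusters),
            ("genecluster", geneclusters),
            ("score_group", score_table.groups if score_table is not None else None),
        ):
            if labels is None:
                continue
            chi2, df, p = logrank_test(times, events, labels.to_numpy())
            medians = {}
            for lab in sorted(pd.unique(labels)):
                mask = (labels == lab).to_numpy()
                medians[str(lab)] = median_survival(
                    km_estimate(times[mask], events[mask])
                )
            surv_report[name] = {"chi2": chi2, "df": df, "p": p, "median_survival": medians}
        if score_table is not None:
            score = score_table.m6ascore.to_numpy()
            uni = cox_fit(times, events, (score - score.mean()) / score.std(),
                          names=["m6ascore"])
            surv_report["cox_univariate"] = _cox_report(uni)
            covars = pd.DataFrame(
                {
                    "m6ascore": (score - score.mean()) / score.std(),
                    "age": clinical.table["age"].to_numpy(dtype=float),
                    "gender": (clinical.table["gender"].astype(str) == "M").astype(float),
                    "stage": clinical.table["stage"].to_numpy(dtype=float),
                },
                index=clinical.table.index,
            ).dropna()
            multi = cox_fit(
                times[[s in covars.index for s in clinical.table.index]],
                events[[s in covars.index for s in clinical.table.index]],
                covars.to_numpy(),
                names=list(covars.columns),
            )
            surv_report["cox_multivariate"] = _cox_report(multi)
            forest = pd.DataFrame(
                [
                    (t.name, t.beta, t.hr, t.ci_low, t.ci_high, t.p)
                    for t in multi.terms
                ],
                columns=["term", "beta", "hr", "ci_low", "ci_high", "p"],
            )
            fpath = out / "cox_multivariate.tsv"
            forest.to_csv(fpath, sep="\t", index=False)
            files["cox_multivariate"] = fpath
        report["survival"] = surv_report

    # (8) mutation summaries
    @stage("mutation")
    def _mutation():
        if mutations is None:
            report["mutation"] = {"skipped": "no mutation data"}
            return
        mut_report = {}
        freq = gene_mutation_frequency(mutations, expr.sample_ids, panel)
        fpath = out / "regulator_mutation_frequency.tsv"
        freq.per_gene.to_csv(fpath, sep="\t")
        files["mutation_frequency"] = fpath
        mut_report["panel_fraction"] = freq.panel_fraction
        tmb_table = tmb(mutations, expr.sample_ids, exome_mb=cfg.exome_mb)
        tpath = out / "tmb.tsv"
        tmb_table.table.to_csv(tpath, sep="\t")
        files["tmb"] = tpath
        if score_table is not None:
            from scipy.stats import spearmanr

            rho, p = spearmanr(
                score_table.m6ascore.to_numpy(),
                tmb_table.table.loc[score_table.sample_ids, "tmb"].to_numpy(),
            )
            mut_report["score_tmb_spearman"] = {"rho": float(rho), "p": float(p)}
            mut_report["group_comparison"] = score_group_tmb_comparison(
                tmb_table, score_table.groups
            )
        if cnv is not None:
            cfreq = cnv_frequency(cnv)
            cpath = out / "cnv_frequency.tsv"
            cfreq.to_csv(cpath, sep="\t")
            files["cnv_frequency"] = cpath
        report["mutation"] = mut_report

    # (9) immunotherapy comparisons
    @stage("immuno")
    def _immuno():
        if response is None or score_table is None:
            report["immuno"] = {"skipped": "no response data or score"}
            return
        imm_report = {}
        for stratum in STRATA:
            try:
                imm_report[stratum] = compare_response(response, score_table, stratum)
            except ValueError as exc:
                imm_report[stratum] = {"error": str(exc)}
        try:
            lig = ligand_contrast(expr, score_table)
            imm_report["ligand_contrast"] = {
                g: {"p": float(lig.loc[g, "p"]), "direction": lig.loc[g, "direction"]}
                for g in lig.index
            }
        except KeyError:
            imm_report["ligand_contrast"] = {"skipped": "CD80/CD86 absent"}
        report["immuno"] = imm_report

    # (10) score-immune correlation (uses both score and immune stages)
    if score_table is not None and immune_scores is not None:
        corr = score_immune_correlation(score_table, immune_scores)
        cpath = out / "score_immune_correlation.tsv"
        corr.to_csv(cpath, sep="\t")
        files["score_immune_correlation"] = cpath

    rpath = out / "report.json"
    with open(rpath, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    files["report"] = rpath
    bundle = ReportBundle(outdir=out, report=report, files=files)
    bundle.validate()
    return bundle


def _cox_report(fit) -> dict:
    return {
        t.name: {
            "beta": t.beta,
            "hr": t.hr,
            "ci_low": t.ci_low,
            "ci_high": t.ci_high,
            "p": t.p,
        }
        for t in fit.terms
    } | {"converged": fit.converged, "n": fit.n, "n_events": fit.n_events}


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
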