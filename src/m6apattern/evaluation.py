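"""Convenience evaluation of the full score chain on a synthetic cohort.

Runs phenotype-DEG calling (against the generator's known subtype labels),
the univariate-Cox prognostic filter, the PCA m6Ascore with protective
orientation, cutpoint dichotomization, and the downstream survival / TMB /
immunotherapy contrasts, returning a flat summary dict. Used to verify that
every planted direction in the generator is recovered end to end.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import spearmanr

from .diffexpr import phenotype_degs
from .immunotherapy import ResponseTable, compare_response
from .m6ascore import compute_m6ascore, dichotomize_score, prognostic_filter
from .mutation import tmb
from .survival import cox_fit, km_estimate, logrank_test, median_survival
from .synthetic_cohort import SUBTYPES, SyntheticCohort


def score_chain_summary(cohort: SyntheticCohort) -> dict:
    """Summary metrics of the score chain run on ``cohort``.

    Keys: subtype_logrank_p, median_survival (per subtype), b_worst (bool),
    score_mean (per subtype), b_lowest_score (bool), high_vs_low_hr,
    score_logrank_p, tmb_rho, tmb_p, ctla4_median_high/low, ctla4_p."""
    truth = cohort.truth["subtype"].to_numpy()
    expr, clin = cohort.expression, cohort.clinical
    times = clin.table["os_time"].to_numpy()
    events = clin.table["os_event"].to_numpy()

    _, _, subtype_p = logrank_test(times, events, truth)
    medians = {
        s: median_survival(km_estimate(times[truth == s], events[truth == s]))
        for s in SUBTYPES
    }

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        degs, _ = phenotype_degs(expr, truth)
        kept, prog = prognostic_filter(expr, sorted(degs), clin)
        protective = list(prog.index[prog["direction"] == "protective"])
        st = dichotomize_score(compute_m6ascore(expr, kept, protective), clin)

    score = st.m6ascore
    score_mean = {s: float(score[truth == s].mean()) for s in SUBTYPES}
    high = (st.groups == "HIGH").to_numpy(float)
    fit = cox_fit(times, events, high, names=["high"])
    _, _, score_p = logrank_test(times, events, st.groups.to_numpy())

    tmb_table = tmb(cohort.mutations, expr.sample_ids)
    rho, tmb_p = spearmanr(
        score.to_numpy(), tmb_table.table.loc[st.sample_ids, "tmb"].to_numpy()
    )

    imm = compare_response(
        ResponseTable.from_frame(cohort.response), st, "CTLA4pos_PD1neg"
    )

    return {
        "subtype_logrank_p": float(subtype_p),
        "median_survival": medians,
        "b_worst": bool(
            medians["B"] < medians["A"] and medians["B"] < medians["C"]
        ),
        "n_degs": len(degs),
        "n_signature_genes": len(kept),
        "score_mean": score_mean,
        "b_lowest_score": bool(
            score_mean["B"] < score_mean["A"] and score_mean["B"] < score_mean["C"]
        ),
        "high_vs_low_hr": float(fit.terms[0].hr),
        "score_logrank_p": float(score_p),
        "tmb_rho": float(rho),
        "tmb_p": float(tmb_p),
        "ctla4_median_high": imm["median_high"],
        "ctla4_median_low": imm["median_low"],
        "ctla4_p": imm["p"],
    }
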