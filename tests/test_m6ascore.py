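import numpy as np
import pandas as pd
import pytest

from m6apattern.enrichment import EnrichmentScores
from m6apattern.io_formats import ClinicalTable, ExpressionMatrix
from m6apattern.m6ascore import (
    compute_m6ascore,
    dichotomize_score,
    prognostic_filter,
    score_immune_correlation,
)


def _matrix(arr):
    arr = np.asarray(arr, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            arr,
            index=[f"g{i}" for i in range(arr.shape[0])],
            columns=[f"s{j}" for j in range(arr.shape[1])],
        ),
        "LOG2",
    )


class TestComputeScore:
    def test_scores_sum_to_zero(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.normal(size=(8, 20)))
        st = compute_m6ascore(m, m.gene_ids)
        assert st.table["m6ascore"].sum() == pytest.approx(0.0, abs=1e-8)
        assert st.table["pc1"].sum() == pytest.approx(0.0, abs=1e-8)

    def test_duplicated_samples_get_equal_scores(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(6, 10))
        dup = np.hstack([base, base])
        m = ExpressionMatrix(
            pd.DataFrame(
                dup,
                index=[f"g{i}" for i in range(6)],
                columns=[f"s{j}" for j in range(20)],
            ),
            "LOG2",
        )
        st = compute_m6ascore(m, m.gene_ids)
        np.testing.assert_allclose(
            st.table["m6ascore"].iloc[:10], st.table["m6ascore"].iloc[10:], atol=1e-8
        )

    def test_rank_one_matrix_recovers_latent_factor(self):
        factor = np.array([3.0, -1.0, 0.5, 2.0, -2.5, -2.0])
        loadings = np.array([1.0, 0.8, -0.5, 1.2, 0.3])
        vals = np.outer(loadings, factor)
        m = _matrix(vals)
        st = compute_m6ascore(m, m.gene_ids)
        np.testing.assert_allclose(st.table["pc2"], 0.0, atol=1e-8)
        # score proportional to the (centered, z-scaled) factor
        z = factor - factor.mean()
        corr = np.corrcoef(st.table["m6ascore"], z)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-8)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            n_genes, n_samples = rng.integers(4, 21), rng.integers(5, 21)
            m = _matrix(rng.normal(size=(n_genes, n_samples)))
            st = compute_m6ascore(m, m.gene_ids)
            # oracle: eigendecomposition of the sample covariance of the
            # z-scored gene matrix (samples as observations)
            Z = m.values.to_numpy()
            Z = (Z - Z.mean(axis=1, keepdims=True)) / Z.std(axis=1, keepdims=True)
            C = Z @ Z.T / 1.0  # gene-gene scatter; eigvecs = loadings
            w, v = np.linalg.eigh(C)
            order = np.argsort(w)[::-1]
            for c, col in enumerate(["pc1", "pc2"]):
                if min(n_genes, n_samples) <= c:
                    continue
                coords = Z.T @ v[:, order[c]]
                ours = st.table[col].to_numpy()
                # compare up to the declared sign convention
                assert min(
                    np.abs(ours - coords).max(), np.abs(ours + coords).max()
                ) < 1e-8

    def test_fully_deterministic(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.normal(size=(10, 15)))
        s1 = compute_m6ascore(m, m.gene_ids, protective_genes=["g1", "g2"])
        s2 = compute_m6ascore(m, m.gene_ids, protective_genes=["g1", "g2"])
        pd.testing.assert_frame_equal(s1.table, s2.table)
        assert s1.orientation_sign == s2.orientation_sign

    def test_invariant_to_gene_and_sample_order(self):
        rng = np.random.default_rng(4)
        m = _matrix(rng.normal(size=(7, 12)))
        st = compute_m6ascore(m, m.gene_ids, protective_genes=["g0"])
        gperm = rng.permutation(7)
        sperm = rng.permutation(12)
        m2 = ExpressionMatrix(m.values.iloc[gperm, sperm], "LOG2")
        st2 = compute_m6ascore(
            m2, [f"g{i}" for i in gperm], protective_genes=["g0"]
        )
        np.testing.assert_allclose(
            st.table["m6ascore"].to_numpy()[sperm],
            st2.table["m6ascore"].to_numpy(),
            atol=1e-8,
        )

    def test_missing_gene_listed(self):
        m = _matrix(np.zeros((3, 5)) + np.arange(5))
        with pytest.raises(KeyError, match="nope"):
            compute_m6ascore(m, ["g0", "nope"])

    def test_constant_genes_dropped_then_error(self):
        m = _matrix(np.ones((3, 5)))
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                compute_m6ascore(m, m.gene_ids)


def _clinical(times, events):
    n = len(times)
    return ClinicalTable(
        pd.DataFrame(
            {"os_time": times, "os_event": events},
            index=pd.Index([f"s{j}" for j in range(n)], name="sample_id"),
        )
    )


class TestPrognosticFilter:
    def test_threshold_one_keeps_all(self):
        rng = np.random.default_rng(5)
        m = _matrix(rng.normal(size=(6, 40)))
        clin = _clinical(rng.exponential(10, 40), np.ones(40))
        kept, tab = prognostic_filter(m, m.gene_ids, clin, p_threshold=1.0)
        assert kept == m.gene_ids
        assert set(tab["direction"]) <= {"risk", "protective"}

    def test_planted_prognostic_genes_recovered(self, default_cohort):
        genes = [g for g in default_cohort.expression.gene_ids if g.startswith("PHG")]
        kept, tab = prognostic_filter(
            default_cohort.expression, genes, default_cohort.clinical
        )
        # every phenotype block loads on the latent prognosis score
        assert len(kept) / len(genes) >= 0.8

    def test_no_survivor_raises_helpful_error(self):
        rng = np.random.default_rng(6)
        m = _matrix(rng.normal(size=(3, 30)))
        clin = _clinical(rng.exponential(10, 30), np.ones(30))
        with pytest.raises(ValueError, match="threshold"):
            prognostic_filter(m, m.gene_ids, clin, p_threshold=1e-12)


class TestDichotomize:
    def test_default_cohort_high_group_protective(self, default_cohort):
        from m6apattern import cox_fit, phenotype_degs

        truth = default_cohort.truth["subtype"].to_numpy()
        degs, _ = phenotype_degs(default_cohort.expression, truth)
        kept, tab = prognostic_filter(
            default_cohort.expression, sorted(degs), default_cohort.clinical
        )
        protective = list(tab.index[tab["direction"] == "protective"])
        st = compute_m6ascore(default_cohort.expression, kept, protective)
        std = dichotomize_score(st, default_cohort.clinical)
        clin = default_cohort.clinical.table
        fit = cox_fit(
            clin["os_time"].to_numpy(),
            clin["os_event"].to_numpy(),
            (std.groups == "HIGH").to_numpy(float),
            ["high"],
        )
        assert fit.terms[0].hr < 1.0
        assert fit.terms[0].p < 0.05
        # subtype B (poor prognosis) has the lowest mean score
        means = {s: float(std.m6ascore[truth == s].mean()) for s in "ABC"}
        assert means["B"] < means["A"] and means["B"] < means["C"]
        # group sizes respect minprop
        assert min((std.groups == "HIGH").sum(), (std.groups == "LOW").sum()) >= 60

    def test_constant_score_rejected(self):
        rng = np.random.default_rng(7)
        m = _matrix(np.vstack([np.ones(10), np.ones(10) * 2, rng.normal(size=10)]))
        clin = _clinical(rng.exponential(5, 10), np.ones(10))
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                st = compute_m6ascore(m, m.gene_ids)
                # only one nonconstant gene -> error before dichotomization
                dichotomize_score(st, clin)


class TestScoreImmuneCorrelation:
    def test_score_against_itself_is_one(self):
        rng = np.random.default_rng(8)
        m = _matrix(rng.normal(size=(6, 25)))
        st = compute_m6ascore(m, m.gene_ids)
        fake = EnrichmentScores(
            pd.DataFrame(
                [st.table["m6ascore"].to_numpy()], index=["self"],
                columns=st.sample_ids,
            ),
            "ssgsea",
            True,
        )
        tab = score_immune_correlation(st, fake)
        assert tab.loc["self", "rho"] == pytest.approx(1.0)

    def test_consistent_under_shared_sample_shuffle(self):
        rng = np.random.default_rng(9)
        m = _matrix(rng.normal(size=(6, 25)))
        st = compute_m6ascore(m, m.gene_ids)
        scores = pd.DataFrame(
            rng.normal(size=(3, 25)), index=list("abc"), columns=st.sample_ids
        )
        es1 = EnrichmentScores(scores, "ssgsea", True)
        perm = rng.permutation(25)
        es2 = EnrichmentScores(scores.iloc[:, perm], "ssgsea", True)
        t1 = score_immune_correlation(st, es1)
        t2 = score_immune_correlation(st, es2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_immune_signal_positive(self, default_cohort):
        from m6apattern import phenotype_degs, ssgsea

        truth = default_cohort.truth["subtype"].to_numpy()
        degs, _ = phenotype_degs(default_cohort.expression, truth)
        kept, tab = prognostic_filter(
            default_cohort.expression, sorted(degs), default_cohort.clinical
        )
        protective = list(tab.index[tab["direction"] == "protective"])
        st = compute_m6ascore(default_cohort.expression, kept, protective)
        es = ssgsea(default_cohort.expression, default_cohort.immune_sets)
        corr = score_immune_correlation(st, es)
        # signatures planted high in the good-prognosis subtype A correlate
        # positively with the protective-oriented score
        assert (corr["rho"] > 0).mean() >= 0.8
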