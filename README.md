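# m6apattern

Tools for classifying bulk tumor expression cohorts by the activity of the
23 N6-methyladenosine (m6A) RNA-modification regulators, and for scoring
each patient's m6A modification pattern against survival, tumor mutation
burden and immunotherapy response. The workflow targets lung
adenocarcinoma-style cohorts (expression + clinical + somatic mutation +
CNV tables) but is generic over any gene panel.

m6A methylation is written by methyltransferases (METTL3, METTL14, WTAP,
...), erased by demethylases (FTO, ALKBH5) and read by binding proteins
(YTHDF1-3, YTHDC1/2, HNRNPC, ...). Tumors with different regulator
expression patterns differ in immune infiltration and prognosis; this
package quantifies those patterns per patient.

## What it computes

1. **Consensus clustering** of samples on the regulator panel: repeated
   subsampling (default 1000 resamples at 80%) with an inner k-means, a
   sample-by-sample co-clustering matrix per k, and automatic selection of
   the cluster number from the consensus CDF (delta-area curve recorded;
   the chosen k is the largest k whose proportion of ambiguous consensus
   entries, PAC, stays below 0.2).
2. **Single-sample enrichment**: ssGSEA (rank-weighted running sums, used
   for immune-cell signatures / TME infiltration) and GSVA-style
   kernel-CDF KS-walk scores (pathway activity), plus moderated-t group
   contrasts with BH correction.
3. **The m6Ascore** — the package's core statistic. Phenotype-related DEGs
   between the m6A clusters are filtered by univariate Cox regression;
   the surviving genes are z-scored and decomposed by PCA, and each
   sample's score is

   ```
   m6Ascore_j = PC1_j + PC2_j
   ```

   with principal-axis signs anchored so protective genes (Cox beta < 0)
   load positively — high score means good prognosis by construction.
4. **Survival machinery from first principles**: Kaplan-Meier curves,
   k-group log-rank tests, Cox proportional hazards (Newton-Raphson on the
   Breslow/Efron partial likelihood), and the maximally selected log-rank
   cutpoint that dichotomizes the score into HIGH/LOW groups.
5. **Mutation and immunotherapy summaries**: per-gene mutation frequency,
   per-sample TMB (nonsynonymous mutations / exome Mb), CNV gain/loss
   frequencies, score-vs-TMB correlation, and response-score / checkpoint
   ligand (CD80, CD86) comparisons between score groups across the four
   anti-CTLA4 / anti-PD-1 treatment strata.

A synthetic-cohort generator (`m6apattern.synthetic_cohort`) plants three
expression subtypes over the regulator panel, subtype-linked hazards,
immune-signature elevation, TMB inversely coupled to a latent prognosis
score, and response scores positively coupled to it — so the entire
pipeline is testable without any cohort download.

## Worked example

```python
from m6apattern import (generate, default_config, consensus_cluster,
                        default_regulator_catalog, adjusted_rand_index,
                        phenotype_degs, prognostic_filter, compute_m6ascore,
                        dichotomize_score, cox_fit, logrank_test)

cohort = generate(default_config())          # 600 samples, 3 planted subtypes
panel = default_regulator_catalog().symbols  # the 23-regulator panel

res = consensus_cluster(cohort.expression, panel, k_range=range(2, 7),
                        n_resamples=200, seed=1)
print("chosen k:", res.chosen_k)
print("ARI vs planted subtypes:",
      round(adjusted_rand_index(res.assignments[res.chosen_k],
                                cohort.truth["subtype"]), 3))

degs, _ = phenotype_degs(cohort.expression, res.assignments[res.chosen_k])
kept, prog = prognostic_filter(cohort.expression, sorted(degs), cohort.clinical)
protective = list(prog.index[prog["direction"] == "protective"])
score = dichotomize_score(
    compute_m6ascore(cohort.expression, kept, protective), cohort.clinical)
print("signature genes:", len(kept), "| cutpoint:", round(score.cutpoint, 3))

clin = cohort.clinical.table
fit = cox_fit(clin["os_time"], clin["os_event"],
              (score.groups == "HIGH").to_numpy(float), names=["HIGH"])
chi2, df, p = logrank_test(clin["os_time"], clin["os_event"], score.groups)
print(f"HIGH vs LOW: HR={fit['HIGH'].hr:.2f} "
      f"(95% CI {fit['HIGH'].ci_low:.2f}-{fit['HIGH'].ci_high:.2f}), "
      f"log-rank p={p:.2e}")
```

Output:

```
chosen k: 3
ARI vs planted subtypes: 0.791
signature genes: 123 | cutpoint: -5.942
HIGH vs LOW: HR=0.29 (95% CI 0.22-0.37), log-rank p=3.26e-25
```

Three stable regulator patterns emerge; the PCA score built from the
prognostically filtered phenotype genes splits the cohort into a HIGH
group with roughly a third of the LOW group's hazard — the planted
"high score = survival advantage" structure, recovered end to end.

The same stages are available from the shell:

```
m6apattern simulate --outdir cohort --seed 42
m6apattern cluster --expression cohort/expression.tsv --panel regulators \
    --k-min 2 --k-max 6 --outdir clusters
m6apattern run --outdir full_run --seed 42     # whole pipeline + report.json
```

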