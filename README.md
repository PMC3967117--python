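# riskpipe

Integrated genomic + clinical wellness risk assessment: from GWAS
case-control association records and individual genotypes to post-test
disease probabilities, five-level clinical risk categories, clinically
conditioned "risk-o-grams", eight-domain "gridiron" integration, and
genetic/clinical concordance classification.

`riskpipe` is aimed at researchers prototyping multivariate genotypic risk
assessment in wellness cohorts: people with a curated table of per-study
case/control genotype frequencies, a VCF of subject genotypes, baseline
disease priors, and longitudinal clinical measurements, who want
reproducible per-subject risk reports. A synthetic-cohort generator with
known ground truth makes every stage testable without access to any real
cohort.

## The model

**Genotypic risk.** For a SNP *x* observed in *s* case-control studies of
size *S(i)*, the per-genotype likelihood ratio is the sample-size-weighted
log-mean of the frequency ratios:

```
logLR(x, g) = Σᵢ log[ F(g | cases, i) / F(g | controls, i) ] · S(i) / Σᵢ S(i)
```

Only SNPs reaching *P* < 10⁻⁶ in at least one ancestry-matched study are
used, keeping a single most-significant representative per haplotype block
(SNPs linked at *r*² ≥ 0.8). A subject's post-test odds for a disease are

```
post-test odds = pre-test odds · Πᵢ LR(gᵢ),    p = odds / (1 + odds)
```

with the pre-test odds taken from sex-specific baseline lifetime risk.

**Clinical risk.** Continuous traits are averaged over the first three
visits, standardised against the cohort (z = (x − mean)/sd), and binned at
±1 and ±2 SD into five categories (very low … very high); protective traits
(HDL-C-like) are sign-inverted first. Domain risk is the unweighted mean of
the direction-adjusted z-scores in each of eight domains (immunological,
metabolic, cardiovascular, musculoskeletal, respiratory, cognitive,
psychiatric, oncological).

**Integration.** The baseline can be conditioned on clinical status before
the genotypic update, either by the proper Bayes update
`p' = p·LR / (1 + p·(LR − 1))` (Framingham-ratio route) or by
heritability-weighted scaling `p' = p · 2h² · LR` — with h² = 0.50 the
multiplier is exactly the clinical LR, with h² = 0.30 it is 60 % of it.
Genetic scores are percentile-ranked into the same five categories
(cutoffs 2.5/16/84/97.5), and concordance compares the direction of the
genotypic LR (vs 1) with the clinical category (vs intermediate).

## Worked example

```python
from riskpipe.synthetic_data import SimulationConfig, simulate_study
from riskpipe.reporting import run_pipeline

cfg = SimulationConfig(seed=7, n_subjects=50)
simulate_study(cfg, "demo")                 # catalog, VCF, clinical, priors
reports = run_pipeline("demo/dataset.json")
```

The first subject's risk-o-gram (seed 7, a 50-subject cohort, default five
diseases with 10 simulated SNPs each):

```
 rank                 disease  pre_test_probability  combined_lr  post_test_probability  n_snps
    1            hypertension                 0.830        1.285                  0.862       6
    2 coronary_artery_disease                 0.490        0.891                  0.461       4
    3                 obesity                 0.350        1.548                  0.455       3
    4    hypertriglyceridemia                 0.300        1.145                  0.329       4
    5         type_2_diabetes                 0.330        0.426                  0.173       6
```

Reading: this man's genotypes at the 3 obesity SNPs that survived curation
multiply his baseline lifetime risk of 0.35 by a combined LR of 1.55,
lifting the post-test probability to 0.455; his type 2 diabetes risk is
roughly halved (LR 0.43). `n_snps` counts the catalog SNPs that passed the
significance filter and LD pruning and had a called genotype.

Conditioning the baselines on observed clinical status
(heritability-scaled route, h² = 0.50 for obesity, 0.30 for
hypertriglyceridemia) re-ranks without touching the genotypic LRs:

```
                disease  clinical_lr  adjusted_prior  post_test_probability  rank_before  rank_after
           hypertension        1.000           0.830                  0.862            1           1
                obesity        1.175           0.411                  0.520            3           2
coronary_artery_disease        1.000           0.490                  0.461            2           3
        type_2_diabetes        1.000           0.330                  0.173            5           4
   hypertriglyceridemia        0.669           0.120                  0.135            4           5
```

His below-average triglycerides (clinical LR 0.67, scaled by 2h² = 0.6)
pull hypertriglyceridemia from rank 4 to rank 5, while his elevated BMI
nudges obesity up to rank 2.

The same pipeline is available from the shell:

```sh
riskpipe simulate --out demo --seed 7
riskpipe run --config demo/dataset.json --out demo/reports --formats json,png
```

which writes per-subject JSON reports plus risk-o-gram, gridiron and radar
plots.

## Layout

- `riskpipe.synthetic_data` — cohort/catalog generator (logistic disease
  model on HWE genotypes, liability-coupled clinical traits)
- `riskpipe.association_catalog` — catalog I/O, validation, significance
  filter, LD pruning
- `riskpipe.genetic_risk` — weighted genotype LRs, Bayesian updating,
  VCF dosage matching, risk-o-gram
- `riskpipe.clinical_risk` — z-scores, five-level bins, domain scores,
  clinical LR models
- `riskpipe.integration` — conditioning, genetic percentile categories,
  gridiron, concordance
- `riskpipe.reporting` / `riskpipe.cli` — subject reports, plots, the
  `riskpipe` command

`riskpipe` is a research prototype for methods exploration on synthetic
data; it is not a medical device and produces no clinical advice.
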