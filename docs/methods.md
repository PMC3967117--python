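# Methods

This note records the statistical model behind `riskpipe`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical and design decisions that were genuinely open.

## Genotypic likelihood ratios

Each catalog record carries the genotype frequency triple F(g | cases) and
F(g | controls), g ∈ {0, 1, 2} copies of the effect allele, for one study of
one SNP for one disease. The per-genotype LR pools studies on the log scale,
weighted by total study size S(i) = n_cases + n_controls:

    logLR(g) = Σᵢ log[F(g|cases,i) / F(g|controls,i)] · S(i) / Σᵢ S(i).

The weighting is applied to the log-ratio, not to the ratio; with a single
study LR(g) is exactly the frequency ratio, which yields the algebraic
identity Σ_g F(g|controls)·LR(g) = 1 (asserted to 1e-12 in the tests).
S(i) is the total sample size; no effective-N correction is attempted
because none is defined for the input format.

Zero frequencies would make the log-ratio infinite. Rather than dropping
such studies, a Haldane-style continuity correction adds 0.5 to the implied
genotype count of every class in both groups and renormalises; a warning is
logged because the correction slightly shrinks extreme ratios.

Curation keeps a SNP×disease when at least one study with exact
string-matching ancestry (default "European") has P < 1e-6. The stricter
reading — the significant study must itself be ancestry-matched, not merely
exist — was adopted; the alternative would retain SNPs whose only
significant evidence is from another ancestry. Haplotype blocks are the
connected components (transitive closure) of the pairwise r² ≥ 0.8 graph,
or a precomputed `block_id` column; LD is never computed from genotypes
here. Within a block the SNP with the smallest best P survives, ties broken
by (chrom, pos, snp_id). Strand-ambiguous (A/T, C/G) SNPs are excluded from
genotype matching by default because silent strand flips would corrupt LRs
undetectably.

## Bayesian updating

Sex-specific baseline lifetime risks are converted to odds, multiplied by
the product of the subject's per-SNP LRs, and converted back:
post-p = odds/(1+odds). The product is accumulated as a sum of logs so that
many small LRs cannot underflow. Missing genotypes contribute the neutral
element LR = 1 and are reported in a skipped list; dropping the disease
instead would conflate "no information" with "no risk". Diseases with no
prior for the subject's sex are omitted from the risk-o-gram.

For k independent SNPs whose catalog frequencies are exact, this product
update is algebraically identical to the full Bayes posterior obtained by
enumerating all 3^k genotype vectors; the acceptance suite checks the
identity at k = 5 to 1e-10. Over a population in Hardy–Weinberg
equilibrium the mean posterior is close to, but not exactly, the
prevalence, because per-SNP frequencies calibrated marginally do not
compose into the exact joint model; at the default effect sizes (OR ≈
1.1–1.5) the deviation is ~2e-4, an order below the Monte-Carlo
standard error at n = 20,000, which is why the calibration check is stated
as "within 3 MC SE".

## Clinical risk

Per-subject trait summaries are the mean of the first min(3, available)
visits. Cohort reference statistics are the mean and n−1 SD over those
per-subject means (the SD convention was a free choice; n−1 is the field
default and is pinned by a frozen two-point example in the tests). The
five-level bins on the direction-adjusted z are frozen as

    z < −2 → very_low, [−2, −1) → low, [−1, 1] → intermediate,
    (1, 2] → high, > 2 → very_high,

which puts ≈2.3/13.6/68.3/13.6/2.3 % of a normal cohort in the five bins.
Boundary membership (which bin owns ±1, ±2 exactly) is arbitrary and
frozen. Traits whose high values are protective carry the
`risk-increasing-low` direction and are sign-inverted before binning and
before domain averaging, so "very high" always reads as high risk. Domain
scores are unweighted means of the direction-adjusted z-scores of the
domain's measured traits — covariance-aware weighting is a known
improvement explicitly left out of scope.

Two clinical-LR models are provided because the mapping from a z-score to
an LR is underdetermined:

* **Gaussian shift (default)**: cases N(δ, 1) vs controls N(0, 1) on the
  z scale gives LR(z) = exp(δz − δ²/2). It integrates to 1 over controls
  (checked numerically) and is the minimal two-parameter-free choice. δ is
  config-required; there is no defensible universal default for the
  case/control separation of an arbitrary biomarker. The simulated-study
  manifests use δ = 0.5 — a modest half-SD separation typical of a single
  biomarker.
* **Empirical bins**: P(bin|case)/P(bin|control) from a labelled cohort,
  with 0.5 pseudo-counts, for when labels exist.

Framingham risk scores are consumed as input columns; the equations are
deliberately not implemented (`compute_frs` raises), since the published
calculators are the source of record. The FRS clinical LR is the subject's
three-visit mean divided by the cohort mean, so cohort-mean LR is exactly 1.

## Conditioning and integration

The FRS route applies the proper Bayes update
p' = p·LR/(1 + p·(LR − 1)), which is odds-multiplication in disguise; it
maps (0,1)→(0,1) and never needs clipping. The heritability route
multiplies the pre-test *probability* by 2·h²·LR (h² = 0.50 for obesity
makes the multiplier exactly the clinical LR; h² = 0.30 for
hypertriglyceridemia makes it 60 % of the LR). Multiplying a probability is
statistically non-standard — the product can exceed 1 — but it is the
operation this route defines; values ≥ 1 are clipped to 1 − 1e-9 with a
warning. Both routes leave the genotypic combined LR bitwise untouched and
re-rank diseases by the adjusted post-test probability.

Genetic five-level categories use empirical percentile cutoffs
2.5/16/84/97.5 within the cohort, chosen to mirror the ±1/±2 SD clinical
bins (the alternative, equal 20 % quintiles, would make the two axes of the
gridiron incommensurable). The per-domain genetic score is the mean log
combined LR over the domain's diseases.

Concordance is a direction-only comparison. Neutral zones — combined LR in
[0.95, 1.05], clinical category intermediate — are repo-defined: some
dead-band is needed to avoid calling LR = 1.001 "increased risk", and
±5 % on the LR is commensurate with the catalog-sampling noise of a typical
single-SNP LR. Either side neutral ⇒ indeterminate; otherwise agreement in
sign ⇒ concordant.

## The synthetic-data generator

The generator emulates the four pipeline inputs with known ground truth.

* **Genotypes**: independent SNPs at HWE with configured risk-allele
  frequencies; no LD beyond block labels (each simulated SNP is its own
  block). Default frequencies U(0.10, 0.90) and per-allele ORs log-normal
  around 1.25 (σ_log = 0.15), the effect-size range of replicated
  common-variant hits.
* **Disease status**: logistic in allele dosages,
  P(case|g) = σ(b₀ + Σ log(OR)·g), with b₀ calibrated per disease and sex
  by Brent root-finding on the exact distribution of the linear predictor
  (a value-merged convolution), so the configured marginal prevalence is
  matched exactly and the per-allele OR is the exact conditional effect —
  the alternative liability-threshold draw would make configured ORs only
  approximate.
* **Catalog frequencies**: Bayes inversion of the single-SNP calibrated
  model at the sex-averaged prevalence; finite studies draw multinomial
  genotype counts and attach a chi-square 2×3 p-value, so the significance
  filter acts on real sampling variation. `exact_frequencies=True` emits
  the infinite-sample expectations instead (used by the oracle tests).
* **Clinical traits**: a latent liability (cohort-standardised sum of the
  per-disease genetic scores) drives each trait's subject mean as
  r·L + √(1−r²)·ε, then affine mapping into trait units and independent
  Gaussian visit noise (default 0.30 latent-SD units, 3 visits, no time
  trend — longitudinal drift is presentation, not model, at this scale).

Default study conditions: five prevalent conditions (CAD, T2D,
hypertension, obesity, hypertriglyceridemia) with sex-specific lifetime
risks in the 0.25–0.85 range; 13 traits across all eight domains with
liability correlations 0.15–0.50 (negative for protective traits); three
studies per SNP of sizes 4000/2000/1000 split evenly cases/controls.

What the generator does **not** emulate: LD between SNPs, assortative or
stratified populations, trait–trait covariance beyond the shared liability
factor, non-Gaussian trait distributions, missing visits, measurement
batch effects, or real cohort trait ranges. Passing tests therefore
demonstrate the correctness of the arithmetic and the internal consistency
of the pipeline under its own assumptions — not predictive validity on real
cohorts, where catalog ORs are noisy, winner's-cursed, and
ancestry-confounded.

## Numerical choices and problem sizes

All randomness descends from one integer seed through named substreams;
identical configuration ⇒ byte-identical output files and reports. Output
floats are written with shortest-round-trip repr (catalog reading uses
pandas' `float_precision="round_trip"` so write→read→write is
byte-stable). Intercept calibration brackets b₀ in [−80, 80] with xtol
1e-12. The convolution pmf rounds support values to 1e-6 (coarsening to
1e-3 only if the support exceeds 250k points).

Statistical tests in the suite run at sizes chosen to make their
Monte-Carlo error small relative to the asserted effect: calibration at
n = 20,000 subjects × 10 SNPs; parameter recovery at 20 replicates of
n = 5,000 × 20 SNPs (OR 1.5); HWE goodness-of-fit and prevalence recovery
over 50 replicate generations at n = 5,000; bin occupancy at n = 50,000.
The trait-correlation recovery band (±0.027 at r = 0.6, n = 5,000) is 3×
the seed-to-seed SD measured over 50 replicate generations.

## Known limitations

The multiplicative LR model assumes SNP independence given disease status
and ignores epistasis and gene–environment interaction. The
heritability-scaled conditioning is a literal probability scaling with no
calibration guarantee; it is provided as specified, clipped when it
overflows, and should be read as an exploratory re-ranking device. The
percentile cutoffs for genetic categories are cohort-relative, so a
subject's category can change when the reference cohort changes. Clinical
LR-from-z requires an externally chosen δ or a labelled cohort; the package
never guesses it.
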