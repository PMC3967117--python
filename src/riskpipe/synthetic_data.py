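"""Synthetic cohorts with the statistical structure the risk pipeline assumes.

The generator produces the four inputs the analysis consumes — a per-study
case/control association catalog, a multi-sample VCF of genotypes, sex-specific
baseline disease priors, and a longitudinal clinical table plus trait
configuration — together with the ground truth (liability, case status,
dosages) needed for parameter-recovery tests.

Generative model
----------------
Genotype dosages are drawn per SNP from Hardy-Weinberg proportions at the
configured risk-allele frequency, with SNPs in independent blocks.  Disease
status follows a logistic model on the allele dosages,

    P(case | g) = sigmoid(b0 + sum_j log(OR_j) * g_j),

with the intercept ``b0`` calibrated per disease and sex by root-finding so
that the marginal prevalence matches the configuration exactly; this makes the
configured per-allele odds ratio the exact conditional effect rather than an
approximation.  Catalog genotype frequencies in cases and controls are the
Bayes inversion of the single-SNP version of the same model at the configured
prevalence; finite studies draw multinomial genotype counts from those
frequencies and attach a chi-square p-value computed from the simulated 2x3
table, so the significance filter downstream has something real to act on.

A latent liability per subject (the cohort-standardised sum of per-disease
genetic scores) drives the clinical traits: each trait's subject-level mean is
``r * L + sqrt(1 - r^2) * eps`` on a standard scale, then shifted/scaled into
trait units, with independent Gaussian visit noise per visit and no time
trend.  All randomness flows from the single configuration seed through named
substreams, so a fixed seed reproduces byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from collections import defaultdict
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import chi2_contingency

logger = logging.getLogger(__name__)

# substream tags: keep randomness sources disjoint and seed-derived
_STREAM_SNPS = 11
_STREAM_CATALOG = 12
_STREAM_GENOTYPES = 13
_STREAM_SEX = 14
_STREAM_CASE = 15
_STREAM_CLINICAL = 16

#: non-strand-ambiguous allele pairs cycled over simulated SNPs
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C"), ("G", "T")]

DEFAULT_DISEASES = [
    "coronary_artery_disease",
    "type_2_diabetes",
    "hypertension",
    "obesity",
    "hypertriglyceridemia",
]

#: sex-specific baseline lifetime risks used as pre-test probabilities
DEFAULT_PREVALENCE = {
    "coronary_artery_disease": {"M": 0.49, "F": 0.32},
    "type_2_diabetes": {"M": 0.33, "F": 0.39},
    "hypertension": {"M": 0.83, "F": 0.85},
    "obesity": {"M": 0.35, "F": 0.40},
    "hypertriglyceridemia": {"M": 0.30, "F": 0.25},
}


class TraitSim(BaseModel):
    """One simulated clinical trait: where it lives and how it couples to liability."""

    name: str
    domain: str
    direction: Literal["risk-increasing-high", "risk-increasing-low"] = "risk-increasing-high"
    liability_corr: float = Field(0.3, ge=-1.0, le=1.0)
    loc: float = 0.0
    scale: float = Field(1.0, gt=0.0)
    linked_disease: Optional[str] = None
    heritability: Optional[float] = Field(None, gt=0.0, le=1.0)


def default_traits() -> list[TraitSim]:
    """Thirteen traits spanning the eight clinical risk domains.

    Correlations with liability, units and dispersions are plausible values
    for a middle-aged wellness cohort; protective traits (HDL-C, lung
    function, bone density, cognition) carry negative liability correlation
    and the ``risk-increasing-low`` direction.
    """
    rows = [
        # name, domain, direction, corr, loc, scale, linked disease, h2
        ("bmi", "metabolic", "risk-increasing-high", 0.50, 27.6, 5.9, "obesity", 0.50),
        ("triglycerides", "metabolic", "risk-increasing-high", 0.45, 130.0, 85.0, "hypertriglyceridemia", 0.30),
        ("fasting_glucose", "metabolic", "risk-increasing-high", 0.35, 92.0, 12.0, "type_2_diabetes", None),
        ("systolic_bp", "cardiovascular", "risk-increasing-high", 0.40, 121.0, 14.0, "hypertension", None),
        ("hdl_cholesterol", "cardiovascular", "risk-increasing-low", -0.40, 55.0, 14.0, "coronary_artery_disease", None),
        ("augmentation_index", "cardiovascular", "risk-increasing-high", 0.30, 20.0, 10.0, "coronary_artery_disease", None),
        ("crp", "immunological", "risk-increasing-high", 0.30, 2.0, 1.5, None, None),
        ("neutrophil_lymphocyte_ratio", "immunological", "risk-increasing-high", 0.25, 1.8, 0.6, None, None),
        ("fev1_fvc_ratio", "respiratory", "risk-increasing-low", -0.25, 0.78, 0.06, None, None),
        ("bone_mineral_density", "musculoskeletal", "risk-increasing-low", -0.20, 0.0, 1.0, None, None),
        ("beck_depression_index", "psychiatric", "risk-increasing-high", 0.20, 8.0, 6.0, None, None),
        ("cognitive_summary_score", "cognitive", "risk-increasing-low", -0.20, 100.0, 15.0, None, None),
        ("oxidative_stress_index", "oncological", "risk-increasing-high", 0.15, 1.0, 0.4, None, None),
    ]
    return [
        TraitSim(
            name=n, domain=d, direction=dirn, liability_corr=r, loc=loc, scale=sc,
            linked_disease=ld, heritability=h2,
        )
        for n, d, dirn, r, loc, sc, ld, h2 in rows
    ]


class SimulationConfig(BaseModel):
    """Full description of a simulated study; the seed determines everything."""

    seed: int = 0
    n_subjects: int = Field(500, gt=0)
    diseases: list[str] = Field(default_factory=lambda: list(DEFAULT_DISEASES))
    n_snps_per_disease: int = Field(10, gt=0)
    prevalence_by_disease_and_sex: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {d: dict(v) for d, v in DEFAULT_PREVALENCE.items()}
    )
    allele_freqs: Optional[dict[str, list[float]]] = None
    per_allele_or: Optional[dict[str, list[float]]] = None
    n_studies_per_snp: int = Field(3, gt=0)
    study_sizes: list[int] = Field(default_factory=lambda: [4000, 2000, 1000])
    n_visits: int = Field(3, gt=0)
    traits: list[TraitSim] = Field(default_factory=default_traits)
    visit_noise_sd: float = Field(0.30, ge=0.0)
    #: emit expected (infinite-sample) genotype frequencies instead of drawing counts
    exact_frequencies: bool = False
    ancestry: str = "European"

    @field_validator("prevalence_by_disease_and_sex")
    @classmethod
    def _prevalence_open_unit(cls, v):
        for disease, by_sex in v.items():
            for sex, p in by_sex.items():
                if not (0.0 < p < 1.0):
                    raise ValueError(f"prevalence for {disease}/{sex} must be in (0, 1), got {p}")
        return v

    @field_validator("allele_freqs")
    @classmethod
    def _freqs_open_unit(cls, v):
        if v is not None:
            for disease, freqs in v.items():
                for f in freqs:
                    if not (0.0 < f < 1.0):
                        raise ValueError(f"allele frequency for {disease} outside (0, 1): {f}")
        return v

    @field_validator("per_allele_or")
    @classmethod
    def _or_positive(cls, v):
        if v is not None:
            for disease, ors in v.items():
                for o in ors:
                    if o <= 0:
                        raise ValueError(f"per-allele OR for {disease} must be > 0, got {o}")
        return v

    @field_validator("study_sizes")
    @classmethod
    def _sizes_positive(cls, v):
        if not v or any(s < 4 for s in v):
            raise ValueError("study_sizes must be non-empty with sizes >= 4")
        return v

    @model_validator(mode="after")
    def _diseases_have_prevalence(self):
        missing = [d for d in self.diseases if d not in self.prevalence_by_disease_and_sex]
        if missing:
            raise ValueError(f"no prevalence configured for disease(s): {missing}")
        return self


# ---------------------------------------------------------------------------
# logistic-model calibration
# ---------------------------------------------------------------------------

def hwe_genotype_probs(p: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities for risk-allele frequency ``p``."""
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])


def _linear_predictor_pmf(ors, freqs, ndigits: int = 6) -> tuple[np.ndarray, np.ndarray]:
    """Exact pmf of sum_j log(OR_j)*g_j under independent HWE genotypes.

    Sequential convolution with value-rounding keeps the support bounded even
    for many SNPs with irrational effect sizes.
    """
    pmf: dict[float, float] = {0.0: 1.0}
    for or_, p in zip(ors, freqs):
        beta = math.log(or_)
        probs = hwe_genotype_probs(p)
        nxt: dict[float, float] = defaultdict(float)
        for v, q in pmf.items():
            for g in range(3):
                nxt[round(v + beta * g, ndigits)] += q * probs[g]
        if len(nxt) > 250_000:  # coarsen rather than blow up
            coarse: dict[float, float] = defaultdict(float)
            for v, q in nxt.items():
                coarse[round(v, 3)] += q
            nxt = coarse
        pmf = nxt
    vals = np.fromiter(pmf.keys(), dtype=float)
    probs = np.fromiter(pmf.values(), dtype=float)
    return vals, probs


def calibrate_logistic_intercept(ors, freqs, prevalence: float) -> float:
    """Intercept b0 such that E_g[sigmoid(b0 + sum log(OR)*g)] = prevalence."""
    if not (0.0 < prevalence < 1.0):
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    vals, probs = _linear_predictor_pmf(ors, freqs)

    def marginal(b0: float) -> float:
        return float(probs @ expit(b0 + vals)) - prevalence

    return brentq(marginal, -80.0, 80.0, xtol=1e-12)


def expected_case_control_freqs(p: float, odds_ratio: float, prevalence: float
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Expected genotype frequencies in cases and controls for one SNP.

    Bayes inversion of the calibrated single-SNP logistic model: with
    penetrances f_g = P(case | g), the case frequencies are
    f_g * HWE(g) / prevalence and the control frequencies
    (1 - f_g) * HWE(g) / (1 - prevalence).
    """
    if odds_ratio <= 0:
        raise ValueError(f"odds ratio must be > 0, got {odds_ratio}")
    if not (0.0 < p < 1.0):
        raise ValueError(f"allele frequency must be in (0, 1), got {p}")
    hwe = hwe_genotype_probs(p)
    b0 = calibrate_logistic_intercept([odds_ratio], [p], prevalence)
    penetrance = expit(b0 + math.log(odds_ratio) * np.arange(3))
    f_cases = penetrance * hwe / prevalence
    f_controls = (1.0 - penetrance) * hwe / (1.0 - prevalence)
    # renormalise away the root-finder's last-digit slack
    return f_cases / f_cases.sum(), f_controls / f_controls.sum()


# ---------------------------------------------------------------------------
# SNP panel resolution
# ---------------------------------------------------------------------------

def resolve_snps(config: SimulationConfig) -> pd.DataFrame:
    """Materialise the per-SNP panel (ids, positions, alleles, freq, OR).

    Frequencies/ORs not pinned in the config are drawn deterministically from
    the config seed: frequencies uniform on (0.10, 0.90), odds ratios
    log-normal around 1.25 — the effect-size range typical of replicated
    common-variant associations.
    """
    rng = np.random.default_rng([config.seed, _STREAM_SNPS])
    rows = []
    idx = 0
    for disease in config.diseases:
        k = config.n_snps_per_disease
        if config.allele_freqs is not None and disease in config.allele_freqs:
            freqs = list(config.allele_freqs[disease])
            if len(freqs) != k:
                raise ValueError(f"allele_freqs[{disease}] must have length {k}")
        else:
            freqs = rng.uniform(0.10, 0.90, size=k).tolist()
        if config.per_allele_or is not None and disease in config.per_allele_or:
            ors = list(config.per_allele_or[disease])
            if len(ors) != k:
                raise ValueError(f"per_allele_or[{disease}] must have length {k}")
        else:
            ors = np.exp(rng.normal(math.log(1.25), 0.15, size=k)).tolist()
        for j in range(k):
            effect, other = _ALLELE_PAIRS[idx % len(_ALLELE_PAIRS)]
            effect_is_alt = bool(rng.integers(0, 2))
            rows.append({
                "disease": disease,
                "snp_id": f"rs{100000 + idx}",
                "chrom": "chrS",
                "pos": 10_000 * (idx + 1),
                "effect_allele": effect,
                "other_allele": other,
                "ref": other if effect_is_alt else effect,
                "alt": effect if effect_is_alt else other,
                "allele_freq": freqs[j],
                "odds_ratio": ors[j],
                "block_id": f"blk_{disease}_{j}",
            })
            idx += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# association catalog
# ---------------------------------------------------------------------------

def _chi2_pvalue(case_counts: np.ndarray, control_counts: np.ndarray) -> float:
    """P-value of the 2x3 genotype-by-status table; degenerate tables give 1."""
    table = np.vstack([case_counts, control_counts])
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        return 1.0
    stat, p, dof, _ = chi2_contingency(table, correction=False)
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def simulate_association_catalog(config: SimulationConfig,
                                 snps: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-study case/control genotype-frequency records for every SNP.

    Each SNP contributes ``n_studies_per_snp`` studies whose sizes cycle
    through ``study_sizes`` (split evenly cases/controls).  Frequencies are
    the Bayes-inverted expectations at the sex-averaged prevalence, sampled
    multinomially unless ``exact_frequencies`` is set.
    """
    if snps is None:
        snps = resolve_snps(config)
    rng = np.random.default_rng([config.seed, _STREAM_CATALOG])
    rows = []
    for snp in snps.itertuples(index=False):
        by_sex = config.prevalence_by_disease_and_sex[snp.disease]
        prevalence = float(np.mean(list(by_sex.values())))
        f_cases, f_controls = expected_case_control_freqs(
            snp.allele_freq, snp.odds_ratio, prevalence)
        for s in range(config.n_studies_per_snp):
            size = config.study_sizes[s % len(config.study_sizes)]
            n_cases = size // 2
            n_controls = size - n_cases
            if config.exact_frequencies:
                fc, fu = f_cases, f_controls
                cc = fc * n_cases
                cu = fu * n_controls
            else:
                cc = rng.multinomial(n_cases, f_cases).astype(float)
                cu = rng.multinomial(n_controls, f_controls).astype(float)
                fc = cc / n_cases
                fu = cu / n_controls
            rows.append({
                "disease": snp.disease,
                "snp_id": snp.snp_id,
                "chrom": snp.chrom,
                "pos": snp.pos,
                "effect_allele": snp.effect_allele,
                "other_allele": snp.other_allele,
                "study_id": f"{snp.disease}_s{s}",
                "n_cases": n_cases,
                "n_controls": n_controls,
                "sample_size": size,
                "p_value": _chi2_pvalue(cc, cu),
                "ancestry": config.ancestry,
                "block_id": snp.block_id,
                "freq0_cases": fc[0], "freq1_cases": fc[1], "freq2_cases": fc[2],
                "freq0_controls": fu[0], "freq1_controls": fu[1], "freq2_controls": fu[2],
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SimTruth:
    """Ground truth for parameter-recovery tests."""

    liability: pd.Series                 # subject -> standardised latent liability
    case_status: pd.DataFrame            # subject x disease booleans
    dosages: pd.DataFrame                # subject x snp_id effect-allele counts
    intercepts: dict[str, dict[str, float]]  # disease -> sex -> calibrated b0


@dataclasses.dataclass
class SimulatedCohort:
    config: SimulationConfig
    snps: pd.DataFrame
    sex: pd.Series                       # subject -> "M"/"F"
    clinical: pd.DataFrame               # long: subject_id, sex, visit, trait, value
    truth: SimTruth

    @property
    def subjects(self) -> list[str]:
        return list(self.sex.index)


def simulate_cohort(config: SimulationConfig,
                    snps: pd.DataFrame | None = None) -> SimulatedCohort:
    """Draw a cohort: genotypes (HWE), disease status (logistic), clinical visits."""
    if snps is None:
        snps = resolve_snps(config)
    n = config.n_subjects
    subjects = [f"S{i + 1:04d}" for i in range(n)]

    rng_sex = np.random.default_rng([config.seed, _STREAM_SEX])
    sex = pd.Series(np.where(rng_sex.random(n) < 0.5, "F", "M"), index=subjects, name="sex")

    rng_g = np.random.default_rng([config.seed, _STREAM_GENOTYPES])
    dosages = pd.DataFrame(
        {snp.snp_id: rng_g.binomial(2, snp.allele_freq, size=n)
         for snp in snps.itertuples(index=False)},
        index=subjects,
    )

    rng_case = np.random.default_rng([config.seed, _STREAM_CASE])
    case_cols = {}
    intercepts: dict[str, dict[str, float]] = {}
    eta_by_disease = {}
    for disease in config.diseases:
        sub = snps[snps["disease"] == disease]
        betas = np.log(sub["odds_ratio"].to_numpy())
        eta = dosages[sub["snp_id"]].to_numpy() @ betas
        eta_by_disease[disease] = eta
        intercepts[disease] = {}
        p_case = np.empty(n)
        for s, prev in config.prevalence_by_disease_and_sex[disease].items():
            b0 = calibrate_logistic_intercept(
                sub["odds_ratio"].to_numpy(), sub["allele_freq"].to_numpy(), prev)
            intercepts[disease][s] = b0
            mask = (sex == s).to_numpy()
            p_case[mask] = expit(b0 + eta[mask])
        case_cols[disease] = rng_case.random(n) < p_case
    case_status = pd.DataFrame(case_cols, index=subjects)

    # latent liability: cohort-standardised sum of per-disease genetic scores;
    # degenerates to pure environmental noise when no SNP carries an effect
    rng_c = np.random.default_rng([config.seed, _STREAM_CLINICAL])
    parts = []
    for disease, eta in eta_by_disease.items():
        sd = eta.std()
        if sd > 0:
            parts.append((eta - eta.mean()) / sd)
    if parts:
        raw = np.sum(parts, axis=0)
        liability = (raw - raw.mean()) / raw.std() if raw.std() > 0 else rng_c.standard_normal(n)
    else:
        liability = rng_c.standard_normal(n)

    rows = []
    for trait in config.traits:
        r = trait.liability_corr
        latent_mean = r * liability + math.sqrt(max(0.0, 1.0 - r * r)) * rng_c.standard_normal(n)
        noise = rng_c.normal(0.0, config.visit_noise_sd, size=(n, config.n_visits)) \
            if config.visit_noise_sd > 0 else np.zeros((n, config.n_visits))
        values = trait.loc + trait.scale * (latent_mean[:, None] + noise)
        for v in range(config.n_visits):
            rows.append(pd.DataFrame({
                "subject_id": subjects,
                "sex": sex.to_numpy(),
                "visit": v + 1,
                "trait": trait.name,
                "value": values[:, v],
            }))
    clinical = pd.concat(rows, ignore_index=True)
    clinical = clinical.sort_values(["subject_id", "trait", "visit"], kind="stable").reset_index(drop=True)

    truth = SimTruth(liability=pd.Series(liability, index=subjects, name="liability"),
                     case_status=case_status, dosages=dosages, intercepts=intercepts)
    return SimulatedCohort(config=config, snps=snps, sex=sex, clinical=clinical, truth=truth)


# ---------------------------------------------------------------------------
# writers (all deterministic text)
# ---------------------------------------------------------------------------

def write_vcf(cohort: SimulatedCohort, path: str | Path) -> Path:
    """Write cohort genotypes as a minimal multi-sample VCFv4.2 (GT only).

    One synthetic contig ``chrS``; ALT dosage is translated from the effect
    allele dosage according to which strand-unambiguous allele was placed on
    REF for each site.
    """
    path = Path(path)
    snps = cohort.snps.sort_values("pos")
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=riskpipe-simulate\n")
        fh.write(f"##contig=<ID=chrS,length={int(snps['pos'].max()) + 10_000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(cohort.subjects) + "\n")
        for snp in snps.itertuples(index=False):
            dos = cohort.truth.dosages[snp.snp_id].to_numpy()
            alt_dos = dos if snp.alt == snp.effect_allele else 2 - dos
            gts = "\t".join(gt_strings[int(g)] for g in alt_dos)
            fh.write(f"{snp.chrom}\t{snp.pos}\t{snp.snp_id}\t{snp.ref}\t{snp.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")
    return path


def write_clinical(cohort: SimulatedCohort, path: str | Path) -> Path:
    path = Path(path)
    df = cohort.clinical.copy()
    df["value"] = df["value"].map(lambda x: f"{x:.6f}")
    df.to_csv(path, sep="\t", index=False)
    return path


def write_priors(config: SimulationConfig, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"disease": d, "sex": s, "pre_test_probability": p}
        for d in config.diseases
        for s, p in sorted(config.prevalence_by_disease_and_sex[d].items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def write_traits_json(config: SimulationConfig, path: str | Path) -> Path:
    """Trait/domain configuration consumed by the clinical-risk module."""
    path = Path(path)
    payload = [
        {"name": t.name, "domain": t.domain, "direction": t.direction,
         "linked_disease": t.linked_disease, "heritability": t.heritability}
        for t in config.traits
    ]
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return path


def write_truth(cohort: SimulatedCohort, path: str | Path) -> Path:
    path = Path(path)
    truth = cohort.truth
    payload = {
        "liability": {s: round(float(v), 10) for s, v in truth.liability.items()},
        "case_status": {d: {s: bool(v) for s, v in truth.case_status[d].items()}
                        for d in truth.case_status.columns},
        "dosages": {c: {s: int(v) for s, v in truth.dosages[c].items()}
                    for c in truth.dosages.columns},
        "intercepts": truth.intercepts,
    }
    path.write_text(json.dumps(payload, indent=0, sort_keys=True) + "\n")
    return path


def simulate_study(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate every pipeline input into ``out_dir`` and a dataset manifest.

    Returns the path of each artifact; ``dataset.json`` references them all
    and is directly consumable by :func:`riskpipe.reporting.run_pipeline`.
    """
    from .association_catalog import write_catalog  # local import, avoids cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snps = resolve_snps(config)
    catalog = simulate_association_catalog(config, snps=snps)
    cohort = simulate_cohort(config, snps=snps)

    paths = {
        "catalog": write_catalog(catalog, out / "catalog.tsv"),
        "vcf": write_vcf(cohort, out / "cohort.vcf"),
        "clinical": write_clinical(cohort, out / "clinical.tsv"),
        "priors": write_priors(config, out / "priors.tsv"),
        "traits": write_traits_json(config, out / "traits.json"),
        "truth": write_truth(cohort, out / "truth.json"),
    }
    disease_domains = {t.linked_disease: t.domain for t in config.traits if t.linked_disease}
    manifest = {
        "catalog": "catalog.tsv",
        "vcf": "cohort.vcf",
        "clinical": "clinical.tsv",
        "priors": "priors.tsv",
        "traits": "traits.json",
        "disease_domains": disease_domains,
        # equal-variance Gaussian-shift clinical LR model: a case/control mean
        # separation of half an SD, a modest single-biomarker signal
        "conditioning": {"method": "heritability_scaled", "delta": 0.5},
        "ancestry": config.ancestry,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            config.model_dump_json().encode()).hexdigest(),
    }
    mpath = out / "dataset.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    paths["manifest"] = mpath
    logger.info("simulated study written to %s (%d subjects, %d SNPs)",
                out, config.n_subjects, len(snps))
    return paths
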