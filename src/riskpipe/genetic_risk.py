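"""Genotype likelihood ratios, Bayesian risk updating and risk-o-gram assembly.

For a SNP observed in ``s`` case-control studies of size S(i), the per-genotype
likelihood ratio is computed on the log scale as the sample-size-weighted mean
of the per-study log frequency ratios,

    logLR(g) = sum_i log( F(g in cases, i) / F(g in controls, i) ) * S(i)
               / sum_i S(i),

and a subject's post-test odds for a disease are the pre-test odds (from the
sex-specific baseline lifetime risk) multiplied by the product of the LRs of
their genotypes at every retained SNP:

    post-test odds = pre-test odds * prod_i LR(g_i),
    post-test probability = odds / (1 + odds).

Missing genotypes contribute the multiplicative neutral element LR = 1 and are
reported in a skipped list rather than silently dropped.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .association_catalog import (FREQ_CASE_COLS, FREQ_CONTROL_COLS,
                                  is_strand_ambiguous)

logger = logging.getLogger(__name__)

GENOTYPES = (0, 1, 2)


@dataclasses.dataclass
class SnpGenotypeLR:
    """Per-SNP, per-genotype likelihood ratios after multi-study weighting."""

    snp_id: str
    disease: str
    lr_by_genotype: dict[int, float]
    n_studies: int
    total_weight: float
    chrom: str = ""
    pos: int = 0
    effect_allele: str = ""
    other_allele: str = ""

    def __post_init__(self):
        for g, lr in self.lr_by_genotype.items():
            if not lr > 0:
                raise ValueError(f"{self.snp_id}: LR({g}) must be > 0, got {lr}")


@dataclasses.dataclass(frozen=True)
class DiseasePrior:
    disease: str
    sex: str
    pre_test_probability: float

    def __post_init__(self):
        if not (0.0 < self.pre_test_probability < 1.0):
            raise ValueError(
                f"pre-test probability for {self.disease}/{self.sex} must be in (0, 1)")


@dataclasses.dataclass
class PostTestAssessment:
    """One risk-o-gram row: a disease's risk after the genotypic update."""

    disease: str
    sex: str
    pre_test_probability: float
    combined_lr: float
    post_test_odds: float
    post_test_probability: float
    n_snps: int
    fold_change: float
    skipped_snps: list[str] = dataclasses.field(default_factory=list)


def _haldane_correct(freqs_cases: np.ndarray, freqs_controls: np.ndarray,
                     n_cases: float, n_controls: float) -> tuple[np.ndarray, np.ndarray]:
    """Haldane-style continuity correction for zero genotype frequencies.

    Adds 0.5 to the implied genotype count of every genotype class in both
    groups and renormalises, keeping the log-ratio finite without discarding
    the study.
    """
    cc = freqs_cases * n_cases + 0.5
    cu = freqs_controls * n_controls + 0.5
    return cc / cc.sum(), cu / cu.sum()


def compute_snp_lr(records: pd.DataFrame) -> SnpGenotypeLR:
    """Sample-size-weighted genotype LRs for one SNP x disease across its studies.

    With a single study the result is exactly F(g|cases)/F(g|controls); with
    several, the weighted mean is taken in log space.  Studies containing a
    zero frequency in either group are continuity-corrected (with a warning).
    """
    if records.empty:
        raise ValueError("compute_snp_lr needs at least one study record")
    snp_ids = records["snp_id"].unique()
    diseases = records["disease"].unique()
    if len(snp_ids) != 1 or len(diseases) != 1:
        raise ValueError("compute_snp_lr expects records for a single SNP x disease")

    weights = records["sample_size"].to_numpy(dtype=float)
    if weights.sum() <= 0:
        raise ValueError(f"{snp_ids[0]}: total study weight is zero")

    log_ratios = np.empty((len(records), 3))
    for i, row in enumerate(records.itertuples(index=False)):
        fc = np.array([getattr(row, c) for c in FREQ_CASE_COLS], dtype=float)
        fu = np.array([getattr(row, c) for c in FREQ_CONTROL_COLS], dtype=float)
        if (fc == 0).any() or (fu == 0).any():
            logger.warning("SNP %s study %s: zero genotype frequency, applying "
                           "continuity correction", row.snp_id, row.study_id)
            fc, fu = _haldane_correct(fc, fu, row.n_cases, row.n_controls)
        log_ratios[i] = np.log(fc) - np.log(fu)

    weighted = (log_ratios * weights[:, None]).sum(axis=0) / weights.sum()
    first = records.iloc[0]
    return SnpGenotypeLR(
        snp_id=str(first["snp_id"]),
        disease=str(first["disease"]),
        lr_by_genotype={g: float(math.exp(weighted[g])) for g in GENOTYPES},
        n_studies=len(records),
        total_weight=float(weights.sum()),
        chrom=str(first["chrom"]),
        pos=int(first["pos"]),
        effect_allele=str(first["effect_allele"]),
        other_allele=str(first["other_allele"]),
    )


def compute_catalog_lrs(records: pd.DataFrame) -> dict[str, dict[str, SnpGenotypeLR]]:
    """LR tables for every SNP of every disease in a curated catalog."""
    out: dict[str, dict[str, SnpGenotypeLR]] = {}
    for (disease, snp_id), sub in records.groupby(["disease", "snp_id"], sort=True):
        out.setdefault(disease, {})[snp_id] = compute_snp_lr(sub)
    return out


# ---------------------------------------------------------------------------
# genotype lookup
# ---------------------------------------------------------------------------

def read_vcf_dosages(vcf_path: str | Path, catalog: pd.DataFrame,
                     exclude_ambiguous: bool = True) -> pd.DataFrame:
    """Effect-allele dosages (subject x snp_id) for the catalog's SNPs.

    Sites are matched on (chrom, pos); the catalog's effect/other alleles are
    matched to REF/ALT in either orientation (dosage is flipped when the
    effect allele sits on REF).  Strand-ambiguous SNPs and allele mismatches
    yield missing dosage (NaN), with a log record of why.
    """
    from cyvcf2 import VCF

    keys = (catalog[["snp_id", "chrom", "pos", "effect_allele", "other_allele"]]
            .drop_duplicates("snp_id"))
    by_site: dict[tuple[str, int], list] = {}
    for row in keys.itertuples(index=False):
        by_site.setdefault((str(row.chrom), int(row.pos)), []).append(row)

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    data: dict[str, np.ndarray] = {}
    for variant in vcf:
        matches = by_site.get((variant.CHROM, variant.POS))
        if not matches:
            continue
        alt = variant.ALT[0] if variant.ALT else None
        for row in matches:
            if exclude_ambiguous and is_strand_ambiguous(row.effect_allele, row.other_allele):
                logger.warning("genotype lookup: %s is strand-ambiguous (%s/%s), skipped",
                               row.snp_id, row.effect_allele, row.other_allele)
                continue
            # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
            gt = np.asarray(variant.gt_types)
            alt_dosage = np.select([gt == 0, gt == 1, gt == 3],
                                   [0.0, 1.0, 2.0], default=np.nan)
            if variant.REF == row.other_allele and alt == row.effect_allele:
                data[row.snp_id] = alt_dosage
            elif variant.REF == row.effect_allele and alt == row.other_allele:
                data[row.snp_id] = 2.0 - alt_dosage
            else:
                logger.warning("genotype lookup: %s alleles %s/%s do not match "
                               "VCF %s/%s in either orientation; missing",
                               row.snp_id, row.effect_allele, row.other_allele,
                               variant.REF, alt)
    frame = pd.DataFrame(index=samples)
    for snp_id in keys["snp_id"]:
        frame[snp_id] = data.get(snp_id, np.full(len(samples), np.nan))
    return frame


def genotype_lookup(vcf_path: str | Path, catalog: pd.DataFrame, sample: str,
                    exclude_ambiguous: bool = True) -> dict[str, Optional[int]]:
    """Per-SNP effect-allele dosage for one sample (None where missing)."""
    dosages = read_vcf_dosages(vcf_path, catalog, exclude_ambiguous=exclude_ambiguous)
    if sample not in dosages.index:
        raise KeyError(f"sample {sample!r} not present in {vcf_path}")
    row = dosages.loc[sample]
    return {snp: (None if pd.isna(v) else int(v)) for snp, v in row.items()}


# ---------------------------------------------------------------------------
# Bayesian updating
# ---------------------------------------------------------------------------

def combine_post_test(prior: DiseasePrior,
                      snp_lrs: Mapping[str, SnpGenotypeLR],
                      genotypes: Mapping[str, Optional[int]]) -> PostTestAssessment:
    """Update the baseline risk with the product of the subject's genotype LRs.

    ``genotypes`` maps snp_id to effect-allele dosage; SNPs with a missing
    dosage contribute LR = 1 and are listed in ``skipped_snps``.
    """
    log_lr = 0.0
    n_called = 0
    skipped: list[str] = []
    for snp_id, entry in snp_lrs.items():
        g = genotypes.get(snp_id)
        if g is None:
            skipped.append(snp_id)
            continue
        lr = entry.lr_by_genotype[int(g)]
        log_lr += math.log(lr)
        n_called += 1

    p = prior.pre_test_probability
    pre_odds = p / (1.0 - p)
    combined = math.exp(log_lr)
    post_odds = pre_odds * combined
    post_p = post_odds / (1.0 + post_odds)
    return PostTestAssessment(
        disease=prior.disease, sex=prior.sex, pre_test_probability=p,
        combined_lr=combined, post_test_odds=post_odds,
        post_test_probability=post_p, n_snps=n_called,
        fold_change=post_p / p, skipped_snps=skipped,
    )


def posterior_matrix(lr_tables: Sequence[SnpGenotypeLR],
                     dosages: np.ndarray, prior: float) -> np.ndarray:
    """Vectorised post-test probabilities for a dosage matrix (n x k).

    NaN dosages are treated as missing (LR = 1).  Used for cohort-level
    calibration and for percentile ranking of genetic scores.
    """
    if not (0.0 < prior < 1.0):
        raise ValueError("prior must be in (0, 1)")
    log_tables = np.array([[math.log(t.lr_by_genotype[g]) for g in GENOTYPES]
                           for t in lr_tables])  # k x 3
    dosages = np.asarray(dosages, dtype=float)
    log_lr = np.zeros(dosages.shape[0])
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        called = ~np.isnan(col)
        log_lr[called] += log_tables[j, col[called].astype(int)]
    odds = prior / (1.0 - prior) * np.exp(log_lr)
    return odds / (1.0 + odds)


# ---------------------------------------------------------------------------
# priors and riskogram
# ---------------------------------------------------------------------------

def read_priors(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"disease", "sex", "pre_test_probability"}
    if not required.issubset(df.columns):
        raise ValueError(f"priors file must have columns {sorted(required)}")
    bad = ~df["pre_test_probability"].between(0, 1, inclusive="neither")
    if bad.any():
        raise ValueError(f"priors outside (0, 1) for rows {list(df.index[bad])}")
    return df


def get_prior(priors: pd.DataFrame, disease: str, sex: str) -> Optional[DiseasePrior]:
    sub = priors[(priors["disease"] == disease) & (priors["sex"] == sex)]
    if sub.empty:
        return None
    return DiseasePrior(disease=disease, sex=sex,
                        pre_test_probability=float(sub.iloc[0]["pre_test_probability"]))


def assess_subject(catalog_lrs: Mapping[str, Mapping[str, SnpGenotypeLR]],
                   priors: pd.DataFrame, genotypes: Mapping[str, Optional[int]],
                   sex: str) -> list[PostTestAssessment]:
    """Post-test assessment per disease for one subject.

    Diseases with no prior for the subject's sex (for example prostate cancer
    for a woman) are omitted.
    """
    out = []
    for disease in sorted(catalog_lrs):
        prior = get_prior(priors, disease, sex)
        if prior is None:
            logger.info("no %s prior for sex=%s; disease omitted", disease, sex)
            continue
        out.append(combine_post_test(prior, catalog_lrs[disease], genotypes))
    return out


def build_riskogram(assessments: Sequence[PostTestAssessment]) -> pd.DataFrame:
    """Rank-ordered risk table: post-test probability descending, ties by name."""
    if not assessments:
        raise ValueError("build_riskogram needs at least one assessment")
    rows = []
    for a in assessments:
        direction = ("increased" if a.combined_lr > 1.0
                     else "decreased" if a.combined_lr < 1.0 else "neutral")
        rows.append({
            "disease": a.disease,
            "sex": a.sex,
            "pre_test_probability": a.pre_test_probability,
            "combined_lr": a.combined_lr,
            "post_test_probability": a.post_test_probability,
            "fold_change": a.fold_change,
            "direction": direction,
            "n_snps": a.n_snps,
        })
    df = pd.DataFrame(rows).sort_values(
        ["post_test_probability", "disease"], ascending=[False, True],
        kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
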