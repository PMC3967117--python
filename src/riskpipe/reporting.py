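"""Per-subject reports and the end-to-end pipeline.

A :class:`SubjectReport` bundles the rank-ordered risk-o-gram, the clinically
conditioned risk-o-gram, the eight-domain gridiron and a concordance summary,
plus a provenance block (input hashes, seed, tool version) so every number is
traceable to an upstream artifact.  Reports render to JSON (canonical,
round-trippable), TSV tables, or PNG figures (risk-o-gram bars, gridiron
grid, radar summary) on headless systems.

By default reports carry z-scores rather than raw trait values; pass
``include_raw=True`` to embed the measured values as well.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .association_catalog import curate, read_catalog
from .clinical_risk import (ClinicalProfile, RiskCategory, build_profiles,
                            clinical_lr_from_z, frs_lr, load_trait_config,
                            read_clinical)
from .genetic_risk import (assess_subject, build_riskogram, compute_catalog_lrs,
                           read_priors, read_vcf_dosages)
from .integration import (GridironCell, build_gridiron, concordance_summary,
                          condition_assessments, genetic_category)

logger = logging.getLogger(__name__)

SUPPORTED_FORMATS = ("json", "tsv", "png")


@dataclasses.dataclass
class SubjectReport:
    subject_id: str
    sex: str
    riskogram: list[dict]
    conditioned: list[dict]
    gridiron: list[dict]
    concordance: dict
    clinical_z: dict[str, float]
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "SubjectReport":
        return cls(**payload)


def _cell_to_dict(cell: GridironCell) -> dict:
    return {
        "domain": cell.domain,
        "clinical_category": cell.clinical_category.name if cell.clinical_category is not None else None,
        "genetic_category": cell.genetic_category.name if cell.genetic_category is not None else None,
        "concordance": cell.concordance,
    }


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_report(report: SubjectReport, out_dir: str | Path,
                  formats: Sequence[str] = ("json",)) -> list[Path]:
    """Write a report in the requested formats; returns the files written."""
    unknown = [f for f in formats if f not in SUPPORTED_FORMATS]
    if unknown:
        raise ValueError(f"unknown format(s) {unknown}; supported: {SUPPORTED_FORMATS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stem = report.subject_id
    if "json" in formats:
        path = out / f"{stem}.json"
        path.write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True) + "\n")
        written.append(path)
    if "tsv" in formats:
        rg = out / f"{stem}_riskogram.tsv"
        pd.DataFrame(report.riskogram).to_csv(rg, sep="\t", index=False)
        written.append(rg)
        gi = out / f"{stem}_gridiron.tsv"
        pd.DataFrame(report.gridiron).to_csv(gi, sep="\t", index=False)
        written.append(gi)
    if "png" in formats:
        written.extend(_render_plots(report, out))
    return written


def _render_plots(report: SubjectReport, out: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    written = []
    if report.riskogram:
        rg = pd.DataFrame(report.riskogram).sort_values("post_test_probability")
        fig, ax = plt.subplots(figsize=(7, 0.45 * len(rg) + 1.5))
        colors = np.where(rg["combined_lr"] > 1, "tab:orange", "tab:purple")
        ax.barh(rg["disease"], rg["post_test_probability"], color=colors)
        ax.scatter(rg["pre_test_probability"], np.arange(len(rg)), marker="v",
                   color="black", zorder=3, label="baseline")
        for i, n in enumerate(rg["n_snps"]):
            ax.annotate(f"{n} SNPs", (ax.get_xlim()[1], i), fontsize=7,
                        ha="right", va="center")
        ax.set_xlabel("post-test probability")
        ax.set_title(f"Risk-o-gram: {report.subject_id}")
        ax.legend(loc="lower right", fontsize=7)
        fig.tight_layout()
        path = out / f"{report.subject_id}_riskogram.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    cells = [c for c in report.gridiron
             if c["clinical_category"] is not None and c["genetic_category"] is not None]
    if cells:
        order = [c.name for c in RiskCategory]
        fig, ax = plt.subplots(figsize=(1.0 * len(cells) + 2, 4))
        for i, cell in enumerate(cells):
            ax.scatter(i, order.index(cell["clinical_category"]), marker="s",
                       s=180, color="tab:blue", label="clinical" if i == 0 else None)
            ax.scatter(i, order.index(cell["genetic_category"]), marker="D",
                       s=120, color="tab:red", label="genetic" if i == 0 else None)
        ax.set_xticks(range(len(cells)), [c["domain"] for c in cells],
                      rotation=45, ha="right")
        ax.set_yticks(range(5), order)
        ax.set_title(f"Gridiron: {report.subject_id}")
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = out / f"{report.subject_id}_gridiron.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

        # radar summary of domain-level genetic risk, sized by clinical category
        angles = np.linspace(0, 2 * np.pi, len(cells), endpoint=False)
        fig = plt.figure(figsize=(5, 5))
        ax = fig.add_subplot(projection="polar")
        gvals = [order.index(c["genetic_category"]) for c in cells]
        ax.plot(np.append(angles, angles[0]), gvals + [gvals[0]], color="tab:red")
        for a, cell in zip(angles, cells):
            ax.scatter(a, order.index(cell["genetic_category"]),
                       s=60 + 60 * order.index(cell["clinical_category"]),
                       color="tab:blue", alpha=0.6)
        ax.set_xticks(angles, [c["domain"] for c in cells], fontsize=7)
        ax.set_yticks(range(5), order, fontsize=6)
        ax.set_title(f"Domain risk radar: {report.subject_id}", fontsize=9)
        path = out / f"{report.subject_id}_radar.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def _load_manifest(config: Mapping | str | Path) -> tuple[dict, Path]:
    if isinstance(config, (str, Path)):
        path = Path(config)
        return json.loads(path.read_text()), path.parent
    return dict(config), Path(".")


def run_pipeline(config: Mapping | str | Path,
                 out_dir: str | Path | None = None,
                 formats: Sequence[str] = ("json",),
                 include_raw: bool = False) -> list[SubjectReport]:
    """Run curation, genetic and clinical risk, conditioning and reporting.

    ``config`` is a dataset manifest (dict or JSON path) with keys: catalog,
    vcf, clinical, priors, traits (paths, relative to the manifest), optional
    ld (pairwise r^2 TSV), ancestry, p_threshold, r2_threshold,
    disease_domains (disease -> domain), conditioning
    ({method, delta}), seed.  Reports are returned and, when ``out_dir`` is
    given, rendered there.
    """
    manifest, base = _load_manifest(config)
    for key in ("catalog", "vcf", "clinical", "priors", "traits"):
        if key not in manifest:
            raise ValueError(f"pipeline manifest is missing {key!r}")
        if not (base / manifest[key]).exists():
            raise FileNotFoundError(f"stage=input: {key} file not found: "
                                    f"{base / manifest[key]}")

    ancestry = manifest.get("ancestry", "European")
    p_threshold = float(manifest.get("p_threshold", 1e-6))
    r2_threshold = float(manifest.get("r2_threshold", 0.8))
    conditioning = dict(manifest.get("conditioning",
                                     {"method": "heritability_scaled"}))
    disease_domains = dict(manifest.get("disease_domains", {}))

    # stage: curation
    catalog_path = base / manifest["catalog"]
    raw = read_catalog(catalog_path)
    ld = None
    if manifest.get("ld"):
        ld = pd.read_csv(base / manifest["ld"], sep="\t")
    curated = curate(raw, ancestry=ancestry, p_threshold=p_threshold,
                     ld=ld, r2_threshold=r2_threshold)
    logger.info("stage=curate: %d records read, %d retained after filter+prune",
                len(raw), len(curated))
    if curated.empty:
        raise RuntimeError("stage=curate: no SNP passed curation")
    catalog_lrs = compute_catalog_lrs(curated)

    # stage: genotypes
    dosages = read_vcf_dosages(base / manifest["vcf"], curated)
    n_missing = int(dosages.isna().sum().sum())
    logger.info("stage=genotypes: %d samples x %d SNPs, %d missing calls",
                dosages.shape[0], dosages.shape[1], n_missing)

    # stage: clinical
    priors = read_priors(base / manifest["priors"])
    clinical = read_clinical(base / manifest["clinical"])
    trait_configs = load_trait_config(base / manifest["traits"])
    profiles = build_profiles(clinical, trait_configs)

    provenance = {
        "catalog_sha256": _sha256(catalog_path),
        "config_sha256": manifest.get("config_sha256",
                                      hashlib.sha256(json.dumps(
                                          manifest, sort_keys=True).encode()).hexdigest()),
        "seed": manifest.get("seed"),
        "tool_version": __version__,
    }

    # genetic domain scores across the cohort (log combined LR averaged over
    # the domain's diseases) for percentile categorisation
    subjects = [s for s in dosages.index if s in profiles]
    if not subjects:
        raise RuntimeError("stage=report: no subject present in both VCF and "
                           "clinical table")
    assessments_by_subject = {
        s: assess_subject(catalog_lrs, priors, {k: (None if pd.isna(v) else int(v))
                                                for k, v in dosages.loc[s].items()},
                          profiles[s].sex)
        for s in subjects
    }
    domain_scores = _genetic_domain_scores(assessments_by_subject, disease_domains)

    h2_by_disease = {cfg.linked_disease: cfg.heritability
                     for cfg in trait_configs.values()
                     if cfg.linked_disease and cfg.heritability}

    reports = []
    for s in subjects:
        reports.append(_build_subject_report(
            s, profiles[s], assessments_by_subject[s], domain_scores,
            trait_configs, h2_by_disease, conditioning, provenance,
            include_raw=include_raw))
    if out_dir is not None:
        for r in reports:
            render_report(r, out_dir, formats=formats)
    return reports


def _genetic_domain_scores(assessments_by_subject: Mapping[str, list],
                           disease_domains: Mapping[str, str]) -> dict:
    """Per-subject mean log combined LR per domain, plus cohort distributions."""
    per_subject: dict[str, dict[str, float]] = {}
    for s, assessments in assessments_by_subject.items():
        by_domain: dict[str, list[float]] = {}
        for a in assessments:
            domain = disease_domains.get(a.disease)
            if domain is not None:
                by_domain.setdefault(domain, []).append(np.log(a.combined_lr))
        per_subject[s] = {d: float(np.mean(v)) for d, v in by_domain.items()}
    cohort: dict[str, list[float]] = {}
    for scores in per_subject.values():
        for d, v in scores.items():
            cohort.setdefault(d, []).append(v)
    return {"per_subject": per_subject, "cohort": cohort}


def _clinical_lrs_for_subject(profile: ClinicalProfile,
                              trait_configs, conditioning: dict) -> dict[str, float]:
    """Clinical LR per linked disease for one subject.

    FRS-like traits (named ``frs_<disease>``) are not generated by the
    simulator but, when present, take precedence via the FRS-ratio; other
    linked traits use the configured z-score LR model.
    """
    delta = conditioning.get("delta")
    lrs: dict[str, float] = {}
    for name, cfg in trait_configs.items():
        if not cfg.linked_disease or name not in profile.z:
            continue
        if delta is None:
            raise ValueError("conditioning model unconfigured: set "
                             "conditioning.delta in the manifest")
        z = profile.z[name]
        if cfg.direction == "risk-increasing-low":
            z = -z
        lrs[cfg.linked_disease] = clinical_lr_from_z(z, delta=float(delta))
    return lrs


def _build_subject_report(subject: str, profile: ClinicalProfile,
                          assessments, domain_scores, trait_configs,
                          h2_by_disease, conditioning, provenance,
                          include_raw: bool = False) -> SubjectReport:
    riskogram = build_riskogram(assessments).to_dict(orient="records")

    clinical_lrs = _clinical_lrs_for_subject(profile, trait_configs, conditioning)
    method = conditioning.get("method", "heritability_scaled")
    if method == "heritability_scaled":
        clinical_lrs = {d: lr for d, lr in clinical_lrs.items() if d in h2_by_disease}
    conditioned = condition_assessments(assessments, clinical_lrs, method,
                                        h2_by_disease=h2_by_disease)
    conditioned_rows = sorted((dataclasses.asdict(c) for c in conditioned),
                              key=lambda r: r["rank_after"])

    gen_cats = {}
    for domain, score in domain_scores["per_subject"][subject].items():
        cohort = domain_scores["cohort"][domain]
        if len(cohort) >= 20:
            gen_cats[domain] = genetic_category(score, cohort)
    cells = build_gridiron(profile.domain_categories, gen_cats)

    report = SubjectReport(
        subject_id=subject,
        sex=profile.sex,
        riskogram=riskogram,
        conditioned=conditioned_rows,
        gridiron=[_cell_to_dict(c) for c in cells],
        concordance=concordance_summary(cells),
        clinical_z={t: round(v, 10) for t, v in profile.z.items()},
        provenance=dict(provenance),
    )
    if include_raw:
        report.provenance["raw_trait_means"] = {
            t: v for t, v in profile.trait_means.items()}
    return report
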