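"""Cohort-referenced clinical risk: z-scores, five-level bins, domain scores.

Continuous clinical variables are summarised per subject as the mean of the
first (up to) three visits and standardised against the whole cohort,
z = (x - mean) / sd with the n-1 SD.  Each trait then lands in one of five
risk categories defined by one and two standard-deviation bins around the
cohort mean; for traits whose *high* values are protective (HDL-C, lung
function, bone density) the additive inverse of z is binned, so "very high"
always means high risk.  Domain-level risk is the unweighted mean of the
direction-adjusted z-scores of the domain's traits.

Clinical likelihood ratios for conditioning come from either the subject's
Framingham Risk Score divided by the cohort mean FRS, or a z-score-based
model: by default the equal-variance Gaussian-shift likelihood ratio
LR(z) = exp(delta*z - delta^2/2) for a case/control mean separation of
``delta`` SD units; alternatively empirical LRs from labelled cohort bins.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import math
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

logger = logging.getLogger(__name__)

DOMAINS = ("immunological", "metabolic", "cardiovascular", "musculoskeletal",
           "respiratory", "cognitive", "psychiatric", "oncological")


class RiskCategory(enum.IntEnum):
    """Five-level risk scale; integer order makes comparisons natural."""

    very_low = 0
    low = 1
    intermediate = 2
    high = 3
    very_high = 4

    def __str__(self) -> str:  # noqa: D105
        return self.name


class TraitConfig(BaseModel):
    """How one clinical trait maps into the risk framework."""

    name: str
    direction: Literal["risk-increasing-high", "risk-increasing-low"]
    domain: str
    linked_disease: Optional[str] = None
    heritability: Optional[float] = Field(None, gt=0.0, le=1.0)


def load_trait_config(path: str | Path) -> dict[str, TraitConfig]:
    payload = json.loads(Path(path).read_text())
    cfgs = [TraitConfig(**entry) for entry in payload]
    return {c.name: c for c in cfgs}


# ---------------------------------------------------------------------------
# z-scores
# ---------------------------------------------------------------------------

def visit_average(clinical: pd.DataFrame, max_visits: int = 3) -> pd.DataFrame:
    """Per-subject trait means over the first ``min(max_visits, available)`` visits.

    Expects the long format (subject_id, sex, visit, trait, value); returns a
    wide subject x trait frame with a ``sex`` column.
    """
    required = {"subject_id", "visit", "trait", "value"}
    if not required.issubset(clinical.columns):
        raise ValueError(f"clinical table must have columns {sorted(required)}")
    first = clinical.sort_values("visit", kind="stable").groupby(
        ["subject_id", "trait"], sort=True).head(max_visits)
    wide = first.pivot_table(index="subject_id", columns="trait",
                             values="value", aggfunc="mean")
    wide.columns.name = None
    if "sex" in clinical.columns:
        wide.insert(0, "sex", clinical.groupby("subject_id")["sex"].first())
    return wide


def zscore(cohort_values: Sequence[float], x: float) -> float:
    """Standardise ``x`` against the cohort (n-1 SD).  Errors on zero spread."""
    arr = np.asarray(cohort_values, dtype=float)
    if arr.size < 2:
        raise ValueError("zscore needs a cohort of at least 2 values")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("cohort standard deviation is zero")
    return float((x - arr.mean()) / sd)


def cohort_zscores(means: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores of a wide subject x trait table of visit means."""
    traits = [c for c in means.columns if c != "sex"]
    out = pd.DataFrame(index=means.index)
    for trait in traits:
        col = means[trait].astype(float)
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"trait {trait!r} has zero cohort standard deviation")
        out[trait] = (col - col.mean()) / sd
    return out


def adjusted_z(z: float, direction: str) -> float:
    """Risk-direction adjustment: invert traits whose high values are protective."""
    if direction == "risk-increasing-high":
        return z
    if direction == "risk-increasing-low":
        return -z
    raise ValueError(f"unknown trait direction {direction!r}")


def bin_category(z: float, direction: str = "risk-increasing-high") -> RiskCategory:
    """Five-level bin of a (direction-adjusted) z-score.

    Bins: z < -2 very_low; [-2, -1) low; [-1, 1] intermediate; (1, 2] high;
    > 2 very_high.  Boundary membership is frozen as written.
    """
    if not np.isfinite(z):
        raise ValueError(f"z must be finite, got {z}")
    za = adjusted_z(float(z), direction)
    if za < -2:
        return RiskCategory.very_low
    if za < -1:
        return RiskCategory.low
    if za <= 1:
        return RiskCategory.intermediate
    if za <= 2:
        return RiskCategory.high
    return RiskCategory.very_high


def domain_score(z_by_trait: Mapping[str, float],
                 trait_configs: Mapping[str, TraitConfig],
                 domain: str) -> tuple[float, RiskCategory]:
    """Unweighted mean of direction-adjusted z-scores of the domain's traits."""
    zs = [adjusted_z(z_by_trait[name], cfg.direction)
          for name, cfg in trait_configs.items()
          if cfg.domain == domain and name in z_by_trait]
    if not zs:
        raise ValueError(f"no traits mapped to domain {domain!r}")
    mean_z = float(np.mean(zs))
    return mean_z, bin_category(mean_z)


# ---------------------------------------------------------------------------
# clinical likelihood ratios
# ---------------------------------------------------------------------------

def frs_lr(subject_mean_frs: float, cohort_mean_frs: float) -> float:
    """Framingham-score likelihood ratio: subject mean over cohort mean."""
    if cohort_mean_frs <= 0:
        raise ValueError(f"cohort mean FRS must be > 0, got {cohort_mean_frs}")
    return subject_mean_frs / cohort_mean_frs


def compute_frs(*args, **kwargs):
    """Framingham equations are intentionally not implemented.

    FRS values are consumed as input columns computed externally (the
    published equations/calculators); this stub exists so the omission is
    explicit rather than silent.
    """
    raise NotImplementedError(
        "riskpipe does not implement the Framingham equations; supply FRS "
        "values as input columns computed with the published calculator.")


@dataclasses.dataclass
class EmpiricalLrBins:
    """Empirical LR(z) from a labelled cohort: P(bin|case)/P(bin|control)."""

    edges: np.ndarray      # increasing bin edges, open at both ends
    lr: np.ndarray         # len(edges) + 1 values

    @classmethod
    def from_labelled(cls, z: Sequence[float], is_case: Sequence[bool],
                      edges: Sequence[float] = (-2.0, -1.0, 1.0, 2.0),
                      pseudo: float = 0.5) -> "EmpiricalLrBins":
        z = np.asarray(z, dtype=float)
        is_case = np.asarray(is_case, dtype=bool)
        edges_arr = np.asarray(edges, dtype=float)
        idx = np.searchsorted(edges_arr, z, side="right")
        k = len(edges_arr) + 1
        case_counts = np.bincount(idx[is_case], minlength=k) + pseudo
        control_counts = np.bincount(idx[~is_case], minlength=k) + pseudo
        lr = (case_counts / case_counts.sum()) / (control_counts / control_counts.sum())
        return cls(edges=edges_arr, lr=lr)

    def __call__(self, z: float) -> float:
        return float(self.lr[np.searchsorted(self.edges, z, side="right")])


def clinical_lr_from_z(z: float, delta: float | None = None,
                       bins: EmpiricalLrBins | None = None) -> float:
    """LR for a clinical z-score under a configured case/control model.

    Default model: cases and controls normal with unit variance and means
    ``delta`` apart, giving LR(z) = exp(delta*z - delta^2/2) (the ratio of
    the two densities at z, controls centred at 0).  Pass ``bins`` to use
    empirical labelled-cohort LRs instead.  Exactly one model must be
    configured.
    """
    if bins is not None and delta is not None:
        raise ValueError("configure either delta or bins, not both")
    if bins is not None:
        return bins(z)
    if delta is None:
        raise ValueError("clinical_lr_from_z requires a configured model: pass "
                         "delta (Gaussian-shift) or bins (EmpiricalLrBins)")
    return math.exp(delta * z - delta * delta / 2.0)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ClinicalProfile:
    subject_id: str
    sex: str
    trait_means: dict[str, float]
    z: dict[str, float]
    categories: dict[str, RiskCategory]
    domain_z: dict[str, float]
    domain_categories: dict[str, RiskCategory]
    frs: dict[str, float] = dataclasses.field(default_factory=dict)


def build_profiles(clinical: pd.DataFrame,
                   trait_configs: Mapping[str, TraitConfig],
                   max_visits: int = 3) -> dict[str, ClinicalProfile]:
    """Visit-average, z-score, bin and aggregate a whole cohort.

    Traits present in the data but absent from the configuration are ignored
    with a log note; domains with no measured trait are absent from the
    domain maps.
    """
    means = visit_average(clinical, max_visits=max_visits)
    traits = [c for c in means.columns if c != "sex"]
    unknown = [t for t in traits if t not in trait_configs]
    if unknown:
        logger.info("traits without configuration ignored: %s", ", ".join(unknown))
    known = [t for t in traits if t in trait_configs]
    zmat = cohort_zscores(means[known])

    domains_present = sorted({trait_configs[t].domain for t in known})
    profiles: dict[str, ClinicalProfile] = {}
    for subject in means.index:
        z_by_trait = {t: float(zmat.loc[subject, t]) for t in known}
        categories = {t: bin_category(z_by_trait[t], trait_configs[t].direction)
                      for t in known}
        domain_z, domain_cat = {}, {}
        for d in domains_present:
            dz, dc = domain_score(z_by_trait, trait_configs, d)
            domain_z[d], domain_cat[d] = dz, dc
        profiles[subject] = ClinicalProfile(
            subject_id=str(subject),
            sex=str(means.loc[subject, "sex"]) if "sex" in means.columns else "",
            trait_means={t: float(means.loc[subject, t]) for t in known},
            z=z_by_trait,
            categories=categories,
            domain_z=domain_z,
            domain_categories=domain_cat,
        )
    missing_domains = [d for d in DOMAINS if d not in domains_present]
    if missing_domains:
        logger.info("domains with no measured trait: %s", ", ".join(missing_domains))
    return profiles


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "visit", "trait", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"clinical TSV must have columns {sorted(required)}")
    return df
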