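"""Condition genetic risk on clinical status; gridiron assembly; concordance.

Two conditioning routes adjust the baseline (pre-test) risk without touching
the genotypic likelihood ratios:

* ``frs_ratio`` — the proper Bayes update on the clinical LR,
  adjusted = p * LR / (1 + p * (LR - 1)), algebraically identical to
  multiplying the pre-test odds by LR.
* ``heritability_scaled`` — the heritability-weighted literal scaling
  adjusted = p * 2 * h^2 * LR, so with h^2 = 0.5 the multiplier is exactly
  the clinical LR and with h^2 = 0.3 it is 60% of it.  The product can
  exceed 1; it is clipped just below 1 with a warning.  Multiplying a
  probability (rather than odds) is statistically non-standard but is the
  operation this route defines.

The gridiron is the joint eight-domain display of five-level clinical
categories against five-level genetic categories, the latter obtained by
ranking a subject's genetic score within the cohort at percentile cutoffs
2.5/16/84/97.5 (mirroring the +-1/+-2 SD clinical bins).  Concordance is a
direction comparison: genetic risk above/below neutral (LR vs 1, or category
vs intermediate) against clinical category above/below intermediate.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Literal, Mapping, Optional, Sequence

import numpy as np

from .clinical_risk import RiskCategory
from .genetic_risk import PostTestAssessment

logger = logging.getLogger(__name__)

#: combined LRs within this closed band count as directionally neutral
LR_NEUTRAL_BAND = (0.95, 1.05)

#: percentile cutoffs mirroring the +-1 / +-2 SD clinical bins
GENETIC_PERCENTILE_CUTOFFS = (2.5, 16.0, 84.0, 97.5)

_CLIP = 1.0 - 1e-9

ConditioningMethod = Literal["frs_ratio", "heritability_scaled"]
Concordance = Literal["concordant", "discordant", "indeterminate"]


def condition_frs(prior: float, clinical_lr: float) -> float:
    """Bayes-update the baseline risk with a clinical likelihood ratio."""
    if not (0.0 < prior < 1.0):
        raise ValueError(f"prior must be in (0, 1), got {prior}")
    if clinical_lr <= 0:
        raise ValueError(f"clinical LR must be > 0, got {clinical_lr}")
    return prior * clinical_lr / (1.0 + prior * (clinical_lr - 1.0))


def condition_heritability(prior: float, h2: float, clinical_lr: float) -> float:
    """Scale the baseline risk by 2 * h^2 * LR (clipped below 1, with warning)."""
    if not (0.0 < prior < 1.0):
        raise ValueError(f"prior must be in (0, 1), got {prior}")
    if not (0.0 < h2 <= 1.0):
        raise ValueError(f"heritability must be in (0, 1], got {h2}")
    if clinical_lr <= 0:
        raise ValueError(f"clinical LR must be > 0, got {clinical_lr}")
    adjusted = prior * 2.0 * h2 * clinical_lr
    if adjusted >= 1.0:
        logger.warning("heritability-scaled prior %.4g exceeds 1 "
                       "(p=%.4g, h2=%.2f, LR=%.4g); clipping", adjusted, prior,
                       h2, clinical_lr)
        adjusted = _CLIP
    return adjusted


@dataclasses.dataclass
class ConditionedAssessment:
    """A risk-o-gram row after the baseline was conditioned on clinical status."""

    disease: str
    original_prior: float
    clinical_lr: float
    method: ConditioningMethod
    adjusted_prior: float
    combined_lr: float              # genotypic; identical before and after
    post_test_probability: float
    rank_before: int
    rank_after: int = 0


def condition_assessments(assessments: Sequence[PostTestAssessment],
                          clinical_lr_by_disease: Mapping[str, float],
                          method: ConditioningMethod,
                          h2_by_disease: Mapping[str, float] | None = None,
                          ) -> list[ConditionedAssessment]:
    """Re-seed each disease's genotypic update with a clinically adjusted baseline.

    Diseases without a clinical LR keep their original baseline (LR treated
    as 1 through the frs_ratio identity).  The genotypic combined LR is
    carried over untouched; ranks are recomputed on the adjusted post-test
    probabilities (descending, ties by disease name).
    """
    ranked = sorted(assessments,
                    key=lambda a: (-a.post_test_probability, a.disease))
    rank_before = {a.disease: i + 1 for i, a in enumerate(ranked)}

    out: list[ConditionedAssessment] = []
    for a in assessments:
        lr = float(clinical_lr_by_disease.get(a.disease, 1.0))
        if method == "frs_ratio":
            adjusted = condition_frs(a.pre_test_probability, lr)
        elif method == "heritability_scaled":
            if h2_by_disease is None or a.disease not in h2_by_disease:
                if a.disease in clinical_lr_by_disease:
                    raise ValueError(f"no heritability configured for {a.disease}")
                adjusted = a.pre_test_probability  # unconditioned disease
            else:
                adjusted = condition_heritability(a.pre_test_probability,
                                                  h2_by_disease[a.disease], lr)
        else:
            raise ValueError(f"unknown conditioning method {method!r}")
        pre_odds = adjusted / (1.0 - adjusted)
        post_odds = pre_odds * a.combined_lr
        out.append(ConditionedAssessment(
            disease=a.disease, original_prior=a.pre_test_probability,
            clinical_lr=lr, method=method, adjusted_prior=adjusted,
            combined_lr=a.combined_lr,
            post_test_probability=post_odds / (1.0 + post_odds),
            rank_before=rank_before[a.disease],
        ))
    out_ranked = sorted(out, key=lambda c: (-c.post_test_probability, c.disease))
    for i, c in enumerate(out_ranked):
        c.rank_after = i + 1
    return out


def genetic_category(value: float, cohort_values: Sequence[float]) -> RiskCategory:
    """Five-level percentile rank of a genetic score within its cohort.

    Cutoffs at the 2.5th/16th/84th/97.5th percentiles of the cohort
    distribution.  A degenerate (zero-spread) distribution yields
    ``intermediate`` with a warning.
    """
    arr = np.asarray(cohort_values, dtype=float)
    if arr.size < 20:
        raise ValueError("genetic_category needs a cohort of at least 20 scores")
    if np.ptp(arr) == 0:
        logger.warning("degenerate genetic-score distribution; returning intermediate")
        return RiskCategory.intermediate
    cuts = np.percentile(arr, GENETIC_PERCENTILE_CUTOFFS)
    # value <= 2.5th pctile -> very_low ... value > 97.5th -> very_high
    idx = int(np.searchsorted(cuts, value, side="left"))
    return RiskCategory(idx)


def _direction_from_lr(combined_lr: float,
                       neutral_band: tuple[float, float] = LR_NEUTRAL_BAND) -> int:
    lo, hi = neutral_band
    if combined_lr > hi:
        return 1
    if combined_lr < lo:
        return -1
    return 0


def _direction_from_category(category: RiskCategory) -> int:
    return int(np.sign(int(category) - int(RiskCategory.intermediate)))


def classify_concordance(genetic: float | RiskCategory,
                         clinical_category: RiskCategory,
                         neutral_band: tuple[float, float] = LR_NEUTRAL_BAND,
                         ) -> Concordance:
    """Directional agreement of genetic and clinical risk.

    The genetic side may be a combined LR (neutral within ``neutral_band``)
    or a five-level category (neutral at intermediate).  Either side neutral
    gives ``indeterminate``; same non-neutral direction is ``concordant``,
    opposite is ``discordant``.
    """
    if isinstance(genetic, RiskCategory):
        g = _direction_from_category(genetic)
    else:
        g = _direction_from_lr(float(genetic), neutral_band)
    c = _direction_from_category(clinical_category)
    if g == 0 or c == 0:
        return "indeterminate"
    return "concordant" if g == c else "discordant"


@dataclasses.dataclass
class GridironCell:
    """(domain, clinical category, genetic category) with a concordance flag."""

    domain: str
    clinical_category: Optional[RiskCategory]
    genetic_category: Optional[RiskCategory]
    concordance: Optional[Concordance]    # None when one side is missing


def build_gridiron(clinical_domain_categories: Mapping[str, RiskCategory],
                   genetic_domain_categories: Mapping[str, RiskCategory],
                   ) -> list[GridironCell]:
    """One cell per domain; domains seen on a single side carry a missing flag."""
    domains = sorted(set(clinical_domain_categories) | set(genetic_domain_categories))
    cells = []
    for d in domains:
        clin = clinical_domain_categories.get(d)
        gen = genetic_domain_categories.get(d)
        if clin is None or gen is None:
            logger.debug("gridiron: domain %s present on one side only", d)
            cells.append(GridironCell(d, clin, gen, None))
        else:
            cells.append(GridironCell(d, clin, gen, classify_concordance(gen, clin)))
    return cells


def concordance_summary(cells: Sequence[GridironCell]) -> dict:
    """Counts by flag plus the concordant:discordant ratio (None if undefined)."""
    counts = {"concordant": 0, "discordant": 0, "indeterminate": 0, "missing": 0}
    for c in cells:
        counts[c.concordance if c.concordance is not None else "missing"] += 1
    ratio = (counts["concordant"] / counts["discordant"]
             if counts["discordant"] else None)
    return {**counts, "ratio": ratio}
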