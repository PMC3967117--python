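"""Ingest, validate, filter and LD-prune GWAS case-control association records.

The catalog is a flat TSV with one row per study x SNP x disease, carrying the
genotype frequencies in cases and controls that the likelihood-ratio engine
consumes.  Curation keeps a SNP for a disease only when at least one of its
studies, in the configured ancestry, reaches genome-wide significance
(P < 1e-6 by default), and then keeps a single representative per haplotype
block — the SNP with the smallest best P-value among SNPs linked at
r^2 >= 0.8, blocks being the connected components of the linkage graph.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FREQ_CASE_COLS = ["freq0_cases", "freq1_cases", "freq2_cases"]
FREQ_CONTROL_COLS = ["freq0_controls", "freq1_controls", "freq2_controls"]

CATALOG_COLUMNS = [
    "disease", "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "study_id", "n_cases", "n_controls", "sample_size", "p_value",
    "ancestry", "block_id", *FREQ_CASE_COLS, *FREQ_CONTROL_COLS,
]

FREQ_TOL = 1e-6

_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


def is_strand_ambiguous(effect_allele: str, other_allele: str) -> bool:
    """A/T and C/G SNPs cannot be oriented across strands without frequency info."""
    return frozenset((effect_allele.upper(), other_allele.upper())) in _AMBIGUOUS_PAIRS


def validate_catalog(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw catalog into (valid, rejected-with-reason) row sets.

    Checks per row: frequency triples sum to 1 within ``FREQ_TOL`` and lie in
    [0, 1]; sample_size equals n_cases + n_controls; p_value in (0, 1].
    """
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"catalog is missing required column(s): {missing}")

    reasons = pd.Series("", index=df.index, dtype=object)

    fc = df[FREQ_CASE_COLS].to_numpy(dtype=float)
    fu = df[FREQ_CONTROL_COLS].to_numpy(dtype=float)
    bad_case_sum = np.abs(fc.sum(axis=1) - 1.0) > FREQ_TOL
    bad_control_sum = np.abs(fu.sum(axis=1) - 1.0) > FREQ_TOL
    bad_range = ((fc < 0) | (fc > 1)).any(axis=1) | ((fu < 0) | (fu > 1)).any(axis=1)
    bad_size = (df["n_cases"].to_numpy() + df["n_controls"].to_numpy()
                != df["sample_size"].to_numpy())
    p = df["p_value"].to_numpy(dtype=float)
    bad_p = ~((p > 0) & (p <= 1))

    reasons[bad_case_sum] += "case frequencies do not sum to 1;"
    reasons[bad_control_sum] += "control frequencies do not sum to 1;"
    reasons[bad_range] += "frequency outside [0, 1];"
    reasons[bad_size] += "sample_size != n_cases + n_controls;"
    reasons[bad_p] += "p_value outside (0, 1];"

    bad = reasons != ""
    rejected = df.loc[bad].copy()
    rejected["reject_reason"] = reasons[bad]
    for idx, reason in reasons[bad].items():
        logger.warning("catalog row %s rejected: %s", idx, reason)
    return df.loc[~bad].copy(), rejected


def read_catalog(path: str | Path) -> pd.DataFrame:
    """Read and validate a catalog TSV; invalid rows are dropped and logged."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep="\t", dtype={"chrom": str, "block_id": str},
                      float_precision="round_trip")
    valid, rejected = validate_catalog(raw)
    if len(rejected):
        logger.warning("read_catalog: dropped %d/%d invalid rows from %s",
                       len(rejected), len(raw), path)
    return valid.reset_index(drop=True)


def write_catalog(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def filter_significant(records: pd.DataFrame, ancestry: str = "European",
                       threshold: float = 1e-6) -> pd.DataFrame:
    """Keep SNP x disease pairs significant in at least one ancestry-matched study.

    All studies of a retained SNP are kept (the LR weighting uses every
    study), including studies that did not themselves reach significance.
    Ancestry matching is exact string equality.
    """
    hit = (records["p_value"] < threshold) & (records["ancestry"] == ancestry)
    keys = records.loc[hit, ["disease", "snp_id"]].drop_duplicates()
    out = records.merge(keys, on=["disease", "snp_id"], how="inner")
    logger.info("filter_significant: %d/%d SNP-disease pairs retained",
                len(keys), records[["disease", "snp_id"]].drop_duplicates().shape[0])
    return out.reset_index(drop=True)


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _blocks_from_r2(snp_ids: list[str], ld: pd.DataFrame,
                    r2_threshold: float) -> dict[str, str]:
    """Connected components of the r^2 >= threshold graph over the given SNPs."""
    for col in ("snp_a", "snp_b", "r2"):
        if col not in ld.columns:
            raise ValueError(f"LD table is missing column {col!r}")
    uf = _UnionFind()
    known = set(snp_ids)
    seen_in_ld = set(ld["snp_a"]) | set(ld["snp_b"])
    for row in ld.itertuples(index=False):
        if row.snp_a in known and row.snp_b in known and row.r2 >= r2_threshold:
            uf.union(row.snp_a, row.snp_b)
    for s in snp_ids:
        if s not in seen_in_ld:
            logger.warning("ld_prune: SNP %s has no LD information; treated as its own block", s)
    return {s: uf.find(s) for s in snp_ids}


def ld_prune(records: pd.DataFrame, ld: pd.DataFrame | None = None,
             r2_threshold: float = 0.8) -> pd.DataFrame:
    """Within each haplotype block keep only the most significant SNP.

    Blocks come either from a precomputed ``block_id`` column (``ld=None``) or
    from a pairwise (snp_a, snp_b, r2) table, where blocks are the transitive
    closure of pairs with r^2 >= ``r2_threshold``.  Per disease and block the
    SNP with the smallest best (minimum over studies) P-value survives; ties
    break on (chrom, pos, snp_id).
    """
    if records.empty:
        return records.copy()
    out_parts = []
    for disease, sub in records.groupby("disease", sort=False):
        snp_ids = sub["snp_id"].drop_duplicates().tolist()
        if ld is None:
            block_of = dict(sub[["snp_id", "block_id"]].drop_duplicates().itertuples(index=False))
        else:
            block_of = _blocks_from_r2(snp_ids, ld, r2_threshold)
        best = (sub.groupby("snp_id")
                   .agg(best_p=("p_value", "min"), chrom=("chrom", "first"),
                        pos=("pos", "first"))
                   .reset_index())
        best["block"] = best["snp_id"].map(block_of)
        winners = (best.sort_values(["best_p", "chrom", "pos", "snp_id"], kind="stable")
                       .groupby("block", sort=False).head(1)["snp_id"])
        out_parts.append(sub[sub["snp_id"].isin(set(winners))])
    return pd.concat(out_parts, ignore_index=True)


def curate(records: pd.DataFrame, ancestry: str = "European",
           p_threshold: float = 1e-6, ld: pd.DataFrame | None = None,
           r2_threshold: float = 0.8,
           drop_strand_ambiguous: bool = True) -> pd.DataFrame:
    """Full curation: significance filter, then LD pruning, then ambiguity drop."""
    out = filter_significant(records, ancestry=ancestry, threshold=p_threshold)
    out = ld_prune(out, ld=ld, r2_threshold=r2_threshold)
    if drop_strand_ambiguous:
        amb = out.apply(lambda r: is_strand_ambiguous(r["effect_allele"],
                                                      r["other_allele"]), axis=1)
        if amb.any():
            dropped = out.loc[amb, "snp_id"].unique()
            logger.warning("curate: excluding %d strand-ambiguous SNP(s): %s",
                           len(dropped), ", ".join(dropped))
            out = out.loc[~amb]
    return out.reset_index(drop=True)
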