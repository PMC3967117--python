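"""Likelihood-ratio computation, Bayesian updating, VCF dosage matching."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from riskpipe.genetic_risk import (DiseasePrior, SnpGenotypeLR, build_riskogram,
                                   combine_post_test, compute_catalog_lrs,
                                   compute_snp_lr, genotype_lookup,
                                   posterior_matrix, read_vcf_dosages)
from tests.conftest import make_record, records_frame


def _prior(p=0.1, disease="t2d", sex="F"):
    return DiseasePrior(disease=disease, sex=sex, pre_test_probability=p)


def _lr_entry(snp_id, lrs, disease="t2d"):
    return SnpGenotypeLR(snp_id=snp_id, disease=disease,
                         lr_by_genotype={0: lrs[0], 1: lrs[1], 2: lrs[2]},
                         n_studies=1, total_weight=1000)


class TestSnpLr:
    def test_single_study_is_the_frequency_ratio(self):
        rec = records_frame([make_record(freq_cases=(0.50, 0.30, 0.20),
                                         freq_controls=(0.25, 0.50, 0.25))])
        lr = compute_snp_lr(rec)
        assert lr.lr_by_genotype[0] == pytest.approx(2.0, abs=1e-14)
        assert lr.lr_by_genotype[1] == pytest.approx(0.6, abs=1e-14)
        assert lr.lr_by_genotype[2] == pytest.approx(0.8, abs=1e-14)

    def test_identical_frequencies_give_unit_lr(self):
        f = (0.4, 0.45, 0.15)
        lr = compute_snp_lr(records_frame([make_record(freq_cases=f,
                                                       freq_controls=f)]))
        assert all(v == pytest.approx(1.0, abs=1e-14)
                   for v in lr.lr_by_genotype.values())

    def test_two_studies_weighted_in_log_space(self):
        """Per-study genotype-0 ratios 2 and 4 at sizes 100 and 300."""
        rec = records_frame([
            make_record(study_id="s0", n_cases=50, n_controls=50,
                        freq_cases=(0.50, 0.30, 0.20),
                        freq_controls=(0.25, 0.55, 0.20)),
            make_record(study_id="s1", n_cases=150, n_controls=150,
                        freq_cases=(0.80, 0.10, 0.10),
                        freq_controls=(0.20, 0.70, 0.10)),
        ])
        lr = compute_snp_lr(rec)
        # independent direct evaluation of the weighted sum
        expected = math.exp((100 * math.log(2) + 300 * math.log(4)) / 400)
        assert lr.lr_by_genotype[0] == pytest.approx(expected, rel=1e-12)
        assert lr.total_weight == 400

    def test_control_expectation_identity_single_study(self):
        """sum_g F(g|controls) * LR(g) = 1 exactly for one study."""
        rec = records_frame([make_record(freq_cases=(0.38, 0.47, 0.15),
                                         freq_controls=(0.44, 0.46, 0.10))])
        lr = compute_snp_lr(rec)
        total = sum(rec.iloc[0][f"freq{g}_controls"] * lr.lr_by_genotype[g]
                    for g in range(3))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_zero_frequency_continuity_corrected(self, caplog):
        rec = records_frame([make_record(freq_cases=(0.6, 0.4, 0.0),
                                         freq_controls=(0.5, 0.45, 0.05))])
        with caplog.at_level("WARNING"):
            lr = compute_snp_lr(rec)
        assert "continuity" in caplog.text
        assert all(np.isfinite(v) and v > 0 for v in lr.lr_by_genotype.values())

    def test_mixed_snp_records_rejected(self):
        rec = records_frame([make_record(snp_id="rs1"), make_record(snp_id="rs2")])
        with pytest.raises(ValueError, match="single SNP"):
            compute_snp_lr(rec)


class TestCombinePostTest:
    def test_unit_lrs_leave_prior_unchanged(self):
        lrs = {"rs1": _lr_entry("rs1", (1.0, 1.0, 1.0))}
        out = combine_post_test(_prior(0.5), lrs, {"rs1": 1})
        assert out.post_test_probability == pytest.approx(0.5, abs=1e-15)

    def test_single_lr_two_matches_hand_bayes(self):
        """p=0.1, LR=2: odds 1/9 -> 2/9 -> probability 2/11."""
        lrs = {"rs1": _lr_entry("rs1", (0.8, 2.0, 3.0))}
        out = combine_post_test(_prior(0.1), lrs, {"rs1": 1})
        assert out.post_test_probability == pytest.approx(2 / 11, abs=1e-15)
        assert out.combined_lr == pytest.approx(2.0, abs=1e-15)

    def test_cancelling_lrs_return_prior(self):
        lrs = {"rs1": _lr_entry("rs1", (2.0, 1.0, 1.0)),
               "rs2": _lr_entry("rs2", (0.5, 1.0, 1.0))}
        out = combine_post_test(_prior(0.1), lrs, {"rs1": 0, "rs2": 0})
        assert out.post_test_probability == pytest.approx(0.1, abs=1e-12)

    def test_missing_genotype_is_neutral_and_reported(self):
        lrs = {"rs1": _lr_entry("rs1", (1.0, 2.0, 4.0)),
               "rs2": _lr_entry("rs2", (0.5, 1.0, 2.0))}
        out = combine_post_test(_prior(0.1), lrs, {"rs1": 1, "rs2": None})
        assert out.skipped_snps == ["rs2"]
        assert out.n_snps == 1
        assert out.combined_lr == pytest.approx(2.0)

    def test_odds_probability_consistency(self):
        lrs = {"rs1": _lr_entry("rs1", (0.7, 1.1, 1.9))}
        out = combine_post_test(_prior(0.37), lrs, {"rs1": 2})
        assert out.post_test_probability == pytest.approx(
            out.post_test_odds / (1 + out.post_test_odds), abs=1e-12)

    @given(st.floats(0.01, 0.99), st.floats(0.1, 5.0), st.floats(1.001, 3.0))
    def test_posterior_strictly_increasing_in_any_lr(self, p, lr1, bump):
        base = {"rs1": _lr_entry("rs1", (lr1,) * 3),
                "rs2": _lr_entry("rs2", (0.9, 1.0, 1.2))}
        bumped = {"rs1": _lr_entry("rs1", (lr1 * bump,) * 3),
                  "rs2": base["rs2"]}
        g = {"rs1": 0, "rs2": 2}
        low = combine_post_test(_prior(p), base, g).post_test_probability
        high = combine_post_test(_prior(p), bumped, g).post_test_probability
        assert high > low

    def test_posterior_matrix_matches_scalar_path(self, rng):
        tables = [_lr_entry(f"rs{i}", tuple(rng.uniform(0.5, 2.0, 3)))
                  for i in range(4)]
        dosages = rng.integers(0, 3, size=(30, 4)).astype(float)
        dosages[0, 2] = np.nan
        vec = posterior_matrix(tables, dosages, prior=0.2)
        for i in range(30):
            genotypes = {t.snp_id: (None if np.isnan(dosages[i, j]) else int(dosages[i, j]))
                         for j, t in enumerate(tables)}
            scalar = combine_post_test(
                _prior(0.2), {t.snp_id: t for t in tables}, genotypes)
            assert vec[i] == pytest.approx(scalar.post_test_probability, abs=1e-12)


class TestGenotypeLookup:
    def _write_vcf(self, path, sites, samples=("S1", "S2")):
        lines = ["##fileformat=VCFv4.2", "##contig=<ID=chrS,length=100000>",
                 '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
                 "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples)]
        for pos, ref, alt, gts in sites:
            lines.append(f"chrS\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                         + "\t".join(gts))
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_direct_match_counts_effect_on_ref(self, tmp_path):
        vcf = self._write_vcf(tmp_path / "a.vcf",
                              [(100, "A", "G", ["0/1", "0/0"])])
        cat = records_frame([make_record(pos=100, effect_allele="A",
                                         other_allele="G")])
        g = genotype_lookup(vcf, cat, "S1")
        assert g["rs1"] == 1
        assert genotype_lookup(vcf, cat, "S2")["rs1"] == 2  # REF/REF = 2 copies of A

    def test_swapped_orientation(self, tmp_path):
        vcf = self._write_vcf(tmp_path / "b.vcf",
                              [(100, "G", "A", ["1/1", "0/1"])])
        cat = records_frame([make_record(pos=100, effect_allele="A",
                                         other_allele="G")])
        assert genotype_lookup(vcf, cat, "S1")["rs1"] == 2

    def test_allele_mismatch_is_missing(self, tmp_path, caplog):
        vcf = self._write_vcf(tmp_path / "c.vcf",
                              [(100, "C", "T", ["0/1", "0/1"])])
        cat = records_frame([make_record(pos=100, effect_allele="A",
                                         other_allele="G")])
        with caplog.at_level("WARNING"):
            g = genotype_lookup(vcf, cat, "S1")
        assert g["rs1"] is None
        assert "orientation" in caplog.text

    def test_strand_ambiguous_excluded(self, tmp_path):
        vcf = self._write_vcf(tmp_path / "d.vcf",
                              [(100, "A", "T", ["0/1", "0/1"])])
        cat = records_frame([make_record(pos=100, effect_allele="A",
                                         other_allele="T")])
        assert genotype_lookup(vcf, cat, "S1")["rs1"] is None

    def test_simulated_vcf_matches_naive_reparser(self, small_study):
        """Dosages from the cyvcf2 path equal an independent text parse."""
        from riskpipe.association_catalog import read_catalog

        cat = read_catalog(small_study["catalog"])
        dosages = read_vcf_dosages(small_study["vcf"], cat)

        # naive line-by-line oracle
        text = small_study["vcf"].read_text().splitlines()
        header = next(l for l in text if l.startswith("#CHROM")).split("\t")
        samples = header[9:]
        keys = cat.drop_duplicates("snp_id").set_index("snp_id")
        for line in text:
            if line.startswith("#"):
                continue
            f = line.split("\t")
            snp_id, ref, alt = f[2], f[3], f[4]
            eff = keys.loc[snp_id, "effect_allele"]
            for sample, gt in zip(samples, f[9:]):
                alt_count = gt.count("1")
                expected = alt_count if alt == eff else 2 - alt_count
                assert dosages.loc[sample, snp_id] == expected


class TestRiskogram:
    def test_sorted_descending_with_name_tiebreak(self):
        def assess(d, post):
            lrs = {"rs1": _lr_entry("rs1", (post / 0.1 / (1 - post) * (1 - 0.1),) * 3, d)}
            return combine_post_test(_prior(0.1, disease=d), lrs, {"rs1": 0})

        a = assess("alpha", 0.3)
        b = assess("beta", 0.2)
        c = assess("aaa", 0.2)
        df = build_riskogram([b, a, c])
        assert list(df["disease"]) == ["alpha", "aaa", "beta"]
        assert list(df["rank"]) == [1, 2, 3]

    def test_null_lrs_rank_by_prior(self):
        outs = []
        for d, p in [("x", 0.3), ("y", 0.1), ("z", 0.2)]:
            lrs = {"rs1": _lr_entry("rs1", (1.0, 1.0, 1.0), d)}
            outs.append(combine_post_test(_prior(p, disease=d), lrs, {"rs1": 1}))
        df = build_riskogram(outs)
        assert list(df["disease"]) == ["x", "z", "y"]

    def test_random_assessments_match_resort_oracle(self, rng):
        outs = []
        for i in range(20):
            p = float(rng.uniform(0.05, 0.6))
            lr = float(rng.uniform(0.3, 3.0))
            lrs = {"rs1": _lr_entry("rs1", (lr,) * 3, f"d{i}")}
            outs.append(combine_post_test(_prior(p, disease=f"d{i}"), lrs, {"rs1": 1}))
        df = build_riskogram(outs)
        oracle = sorted(((o.post_test_probability, o.disease) for o in outs),
                        key=lambda t: (-t[0], t[1]))
        assert list(df["disease"]) == [d for _, d in oracle]

    def test_direction_flags(self):
        lrs_up = {"rs1": _lr_entry("rs1", (2.0,) * 3)}
        lrs_dn = {"rs1": _lr_entry("rs1", (0.5,) * 3)}
        up = combine_post_test(_prior(0.1, disease="a"), lrs_up, {"rs1": 0})
        dn = combine_post_test(_prior(0.1, disease="b"), lrs_dn, {"rs1": 0})
        df = build_riskogram([up, dn]).set_index("disease")
        assert df.loc["a", "direction"] == "increased"
        assert df.loc["b", "direction"] == "decreased"


class TestCatalogLrs:
    def test_grouped_by_disease_and_snp(self, small_study):
        from riskpipe.association_catalog import read_catalog

        cat = read_catalog(small_study["catalog"])
        lrs = compute_catalog_lrs(cat)
        assert set(lrs) == {"obesity", "hypertriglyceridemia"}
        for disease, table in lrs.items():
            for snp_id, entry in table.items():
                assert entry.n_studies == 3
                assert all(v > 0 for v in entry.lr_by_genotype.values())
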