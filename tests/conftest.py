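import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from riskpipe.synthetic_data import SimulationConfig, TraitSim

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


def make_record(disease="t2d", snp_id="rs1", chrom="chrS", pos=100,
                effect_allele="A", other_allele="G", study_id="s0",
                n_cases=500, n_controls=500, p_value=1e-8,
                ancestry="European", block_id="b1",
                freq_cases=(0.30, 0.50, 0.20), freq_controls=(0.40, 0.45, 0.15)):
    """One association-catalog row as a dict, with sensible defaults."""
    return {
        "disease": disease, "snp_id": snp_id, "chrom": chrom, "pos": pos,
        "effect_allele": effect_allele, "other_allele": other_allele,
        "study_id": study_id, "n_cases": n_cases, "n_controls": n_controls,
        "sample_size": n_cases + n_controls, "p_value": p_value,
        "ancestry": ancestry, "block_id": block_id,
        "freq0_cases": freq_cases[0], "freq1_cases": freq_cases[1],
        "freq2_cases": freq_cases[2],
        "freq0_controls": freq_controls[0], "freq1_controls": freq_controls[1],
        "freq2_controls": freq_controls[2],
    }


def records_frame(rows):
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_config():
    """Two diseases, few SNPs/subjects: fast but exercises every stage."""
    return SimulationConfig(
        seed=11, n_subjects=40, n_snps_per_disease=4,
        diseases=["obesity", "hypertriglyceridemia"],
        prevalence_by_disease_and_sex={
            "obesity": {"M": 0.35, "F": 0.40},
            "hypertriglyceridemia": {"M": 0.30, "F": 0.25},
        },
        traits=[
            TraitSim(name="bmi", domain="metabolic", liability_corr=0.5,
                     loc=27.6, scale=5.9, linked_disease="obesity",
                     heritability=0.50),
            TraitSim(name="triglycerides", domain="metabolic",
                     liability_corr=0.45, loc=130.0, scale=85.0,
                     linked_disease="hypertriglyceridemia", heritability=0.30),
            TraitSim(name="hdl_cholesterol", domain="cardiovascular",
                     direction="risk-increasing-low", liability_corr=-0.4,
                     loc=55.0, scale=14.0),
        ],
    )


@pytest.fixture(scope="session")
def small_study(small_config, tmp_path_factory):
    """A full simulated study on disk (catalog/VCF/clinical/priors/manifest)."""
    from riskpipe.synthetic_data import simulate_study

    out = tmp_path_factory.mktemp("study")
    paths = simulate_study(small_config, out)
    return paths


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
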