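import numpy as np
import pandas as pd
import pytest

from crpdecomp.config import (
    GeneratorConfig,
    GroupCovariates,
    ThetaParams,
)
from crpdecomp.genotypes import GenotypeMatrix
from crpdecomp.phewas import PhecodeEntry, PhecodeMap, load_toy_map


def make_covariates(**kw):
    defaults = dict(
        age_mean=55.0, age_sd=8.0, female_p=0.5,
        bmi_mean=27.0, bmi_sd=4.0,
        townsend_mean=0.0, townsend_sd=3.0,
        pc1_mean=0.0, pc1_sd=1.0, pc2_mean=0.0, pc2_sd=1.0,
        smoking={"never": 0.6, "previous": 0.25, "current": 0.14,
                 "prefer_not_to_answer": 0.01},
        insomnia={"never_rarely": 0.3, "sometimes": 0.45, "usually": 0.24,
                  "prefer_not_to_answer": 0.01},
        mdd_p=0.05,
    )
    defaults.update(kw)
    return GroupCovariates(**defaults)


def make_config(**kw):
    """Small two-group configuration for fast unit tests."""
    defaults = dict(
        n_participants=500,
        n_variants=300,
        n_reference_per_pop=30,
        fst=0.15,
        ancestral_maf_range=(0.05, 0.5),
        group_proportions={"Black": 0.5, "White": 0.5},
        group_theta={"Black": ThetaParams(0.88, 0.10),
                     "White": ThetaParams(0.0, 0.005)},
        identity_crossover=0.29,
        identity_slope=50.0,
        identity_mode="logistic",
        covariate_params={"Black": make_covariates(townsend_mean=2.0),
                          "White": make_covariates()},
        recruitment_years=(2006, 2010),
        crp_effects={"intercept": 0.3, "ethnicity": 0.08, "age": 0.02,
                     "sex_male": -0.06},
        crp_sigma=1.0,
        disease_params={},
        seed=0,
    )
    defaults.update(kw)
    return GeneratorConfig(**defaults).validate()


@pytest.fixture
def small_config():
    return make_config()


@pytest.fixture(scope="session")
def toy_map() -> PhecodeMap:
    return load_toy_map()


def make_null_map(n_diseases: int = 50) -> PhecodeMap:
    """Synthetic phecode map of independent null diseases (no cross-exclusions)."""
    entries = {}
    for k in range(n_diseases):
        code = f"{900 + k}"
        entries[code] = PhecodeEntry(code, {f"Z{k:02d}"},
                                     [(900.0 + k, 900.0 + k)], "Null", f"null {k}")
    return PhecodeMap(entries=entries)


def geno(dosages, chrom="1", pos=None, ref=None, alt=None, sample_prefix="s"):
    """Build a GenotypeMatrix from a dense samples x variants array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    pos = pos if pos is not None else list(range(100, 100 + m))
    ref = ref if ref is not None else ["A"] * m
    alt = alt if alt is not None else ["G"] * m
    variants = pd.DataFrame({
        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
        "id": [f"{chrom}:{p}" for p in pos],
    })
    ids = np.array([f"{sample_prefix}{i}" for i in range(n)], dtype=object)
    return GenotypeMatrix(ids, variants, dosages)
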