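import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from introgress import genotype_core as gc
from introgress import synthetic_data as sd

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_breed_freqs():
    """Balding-Nichols frequencies for a Zebu/Charolais pair (F_st 0.1)."""
    return sd.simulate_breed_frequencies(
        2000, 2, 0.1, seed=7, breed_names=["ZB", "CH"]
    )


@pytest.fixture(scope="session")
def recovery_cohort(two_breed_freqs):
    """40 ZB + 40 CH purebreds and 40 admixed samples with known ancestry."""
    q = np.vstack(
        [
            np.tile([1.0, 0.0], (40, 1)),
            np.tile([0.0, 1.0], (40, 1)),
            sd.random_q_matrix(40, 2, seed=8),
        ]
    )
    labels = ["ZB"] * 40 + ["CH"] * 40 + ["CAN"] * 40
    g, truths = sd.simulate_admixed_cohort(
        two_breed_freqs, q, missing_rate=0.02, seed=9, group_labels=labels
    )
    return g, q


def make_matrix(dosage, chrom=None, groups=None, alleles=None):
    """Small-matrix builder for hand-constructed tests."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    snps = sd.default_snp_map(m)
    if chrom is not None:
        snps["chrom"] = chrom
    if alleles is not None:
        snps["allele1"] = [a[0] for a in alleles]
        snps["allele2"] = [a[1] for a in alleles]
    if groups is None:
        groups = ["G"] * n
    samples = pd.DataFrame({"fid": groups, "iid": [f"s{i}" for i in range(n)]})
    return gc.GenotypeMatrix(samples, snps, dosage)
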