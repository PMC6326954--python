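import numpy as np
import pytest

from relapsekit import CohortMetadata, GenotypeMatrix, SimConfig, VariantRecord, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """151 samples x 400 variants, mild LD, no planted effects."""
    cfg = SimConfig(
        n_samples=151,
        n_variants=400,
        seed=11,
        prevalence_target=0.31,
        ld_rho=0.4,
        ld_block_size=8,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def signal_cohort():
    """150 samples x 300 variants with 20 planted effects in LD blocks."""
    cfg = SimConfig(
        n_samples=150,
        n_variants=300,
        seed=23,
        n_causal=20,
        causal_beta=1.0,
        maf_range=(0.2, 0.5),
        prevalence_target=0.31,
        ld_rho=0.7,
        ld_block_size=8,
    )
    return simulate_cohort(cfg)


def make_matrix(dosages, gq=None, dp=None, chroms=None, prefix="V"):
    """Hand-built GenotypeMatrix from a dense integer array (-1 = missing)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    variants = [
        VariantRecord(
            chrom=(chroms[j] if chroms else "1"),
            pos=1000 + j,
            id=f"{prefix}{j}",
            ref="A",
            alt=("G",),
        )
        for j in range(m)
    ]
    return GenotypeMatrix(
        [f"s{i}" for i in range(n)],
        variants,
        dosages,
        missing=dosages == -1,
        call_gq=None if gq is None else np.asarray(gq),
        call_dp=None if dp is None else np.asarray(dp),
    )


def make_metadata(y, rng=None, **extra_columns):
    """Minimal metadata table with plausible covariates."""
    import pandas as pd

    y = np.asarray(y, dtype=int)
    n = len(y)
    rng = rng or np.random.default_rng(0)
    table = pd.DataFrame(
        {
            "relapse": y,
            "donor_age": rng.normal(49, 12, n).round(1),
            "recipient_age": rng.normal(51, 12, n).round(1),
            "diagnosis": rng.choice(["AML", "ALL", "lymphoma_myeloma", "other"], n),
            "graft_type": rng.choice(["peripheral_blood", "bone_marrow"], n, p=[0.76, 0.24]),
            "sex": rng.choice(["male", "female"], n),
            "transplant_direction": rng.choice(
                ["male_to_male", "male_to_female", "female_to_male", "female_to_female"], n
            ),
            "batch": rng.choice(["center_A", "center_B"], n),
            **extra_columns,
        },
        index=[f"s{i}" for i in range(n)],
    )
    table.index.name = "sample_id"
    return CohortMetadata(table)
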