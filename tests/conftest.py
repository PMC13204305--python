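import numpy as np
import pandas as pd
import pytest

from lrpathomics.synthetic import (
    CohortTruth,
    SlideTruth,
    default_planted_pairs,
    simulate_cohort,
    simulate_slide,
)


@pytest.fixture(scope="session")
def small_cohort():
    """n=200 cohort with 2 planted pairs among a 40-pair catalog."""
    truth = CohortTruth(
        planted_pairs=default_planted_pairs(2),
        betas=[0.8, 0.8],
        latent_rho=0.7,
        censor_rate=0.2,
        seed=42,
    )
    expr, surv, catalog, truth = simulate_cohort(200, 120, 40, truth)
    return expr, surv, catalog, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort whose hazard is independent of every pair (betas all zero)."""
    truth = CohortTruth(
        planted_pairs=default_planted_pairs(2),
        betas=[0.0, 0.0],
        latent_rho=0.0,
        censor_rate=0.2,
        seed=7,
    )
    expr, surv, catalog, truth = simulate_cohort(200, 120, 40, truth)
    return expr, surv, catalog, truth


@pytest.fixture(scope="session")
def textured_slide():
    """6-class 4x4 slide with texture, plus its planted truth."""
    img, truth = simulate_slide(
        6, (4, 4), background_frac=0.25, truth=SlideTruth(seed=3), tumor_frac=0.4
    )
    return img, truth


@pytest.fixture(scope="session")
def clean_slide():
    """6-class 4x4 slide with zero texture noise (exactly decodable)."""
    img, truth = simulate_slide(
        6, (4, 4), background_frac=0.25, truth=SlideTruth(seed=3),
        tumor_frac=0.4, texture_noise=0.0,
    )
    return img, truth


@pytest.fixture
def toy_expr():
    """Tiny normalized expression matrix for L-R scoring unit tests."""
    expr = pd.DataFrame(
        {
            "s1": [1.0, 3.0, 5.0, 0.0],
            "s2": [2.0, 1.0, 4.0, 1.0],
            "s3": [3.0, 4.0, 3.0, 2.0],
            "s4": [4.0, 3.0, 2.0, 3.0],
            "s5": [5.0, 5.0, 1.0, 4.0],
        },
        index=["L1", "R1", "R2", "L2"],
    )
    expr.attrs["normalized"] = True
    return expr
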