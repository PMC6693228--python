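import numpy as np
import pandas as pd
import pytest

from refcompass import ExpressionMatrix, SampleInfo, SyntheticConfig, generate_cohort
from refcompass.cohort_io import pair_cohort


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples with easily-checked values."""
    df = pd.DataFrame(
        [[100.0, 200.0, 100.0, 50.0],
         [10.0, 10.0, 10.0, 10.0],
         [3.0, 1.0, 0.0, 7.0]],
        index=["G1", "G2", "G3"],
        columns=["T1", "T2", "N1", "N2"],
    )
    return ExpressionMatrix(df)


@pytest.fixture
def four_samples() -> list[SampleInfo]:
    return [
        SampleInfo("T1", "P1", "tumor", "II", "negative", "well"),
        SampleInfo("T2", "P2", "tumor", "III", "positive", "poor"),
        SampleInfo("N1", "P1", "normal", "II", "negative", "well"),
        SampleInfo("N2", "P2", "normal", "III", "positive", "poor"),
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort reused across read-only tests."""
    cfg = SyntheticConfig(n_pairs=30, n_genes_total=600, seed=11,
                          class_counts={"hallmark_up": 10, "hallmark_down": 5,
                                        "classical_ref": 12, "stable_ref": 20,
                                        "transport_panel": 8,
                                        "coexpr_partner": 15,
                                        "background": 530},
                          outlier_subset_size=3)
    matrix, samples, truth = generate_cohort(cfg)
    return matrix, samples, truth, pair_cohort(samples)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort at the default configuration."""
    cfg = SyntheticConfig(seed=7)
    matrix, samples, truth = generate_cohort(cfg)
    return matrix, samples, truth, pair_cohort(samples)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
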