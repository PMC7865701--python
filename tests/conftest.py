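import numpy as np
import pandas as pd
import pytest

from scinfer import DisruptionMatrix, build_disruption_matrix


@pytest.fixture
def tiny_matrix() -> DisruptionMatrix:
    """4 samples x 2 genes covering all four (a, b) disruption states."""
    data = pd.DataFrame(
        [[1, 1], [1, 0], [0, 1], [0, 0]],
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
        columns=["gA", "gB"],
    )
    return DisruptionMatrix(data)


@pytest.fixture
def variant_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s1", "s2", "s3"],
            "gene": ["gA", "gB", "gA", "gC"],
            "consequence": [
                "missense_variant",
                "stop_gained",
                "synonymous_variant",
                "missense_variant",
            ],
            "sift_score": [0.01, np.nan, np.nan, 0.3],
            "esp_af": [np.nan, 0.0001, 0.01, np.nan],
            "kg_af": [np.nan, 0.001, np.nan, 0.5],
        }
    )


@pytest.fixture(scope="session")
def small_planted_cohort():
    """Fast end-to-end cohort with one strong planted pair."""
    from scinfer import CellCohortConfig, simulate_cell_cohort

    cfg = CellCohortConfig(
        n_samples=200,
        n_genes=10,
        disruption_freqs=tuple([0.3] * 10),
        planted_pairs=(("G001", "G002", -3.0),),
        n_drugs=3,
        shared_effect_drugs=("drug_2",),
        seed=11,
    )
    return simulate_cell_cohort(cfg)
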