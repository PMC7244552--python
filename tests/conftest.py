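import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from absanchor import ExtractionRecord, TaxonCountTable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_table() -> TaxonCountTable:
    """3 samples x 3 taxa with easy round numbers."""
    return TaxonCountTable(
        pd.DataFrame(
            {
                "Akkermansia(g)": [60, 10, 0],
                "Bacteroides(g)": [30, 70, 100],
                "Lactobacillus(g)": [10, 20, 0],
            },
            index=["s1", "s2", "s3"],
        )
    )


@pytest.fixture
def extraction_record() -> ExtractionRecord:
    return ExtractionRecord(
        sample_id="s1",
        dpcr_concentration=250.0,
        elution_volume=100.0,
        dead_volume=400.0,
        extraction_volume=200.0,
        sample_mass=0.05,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
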