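import math

import numpy as np
import pandas as pd
import pytest

from wgrs import (
    GenotypeMatrix,
    PhenotypeTable,
    WeightEntry,
    WeightPanel,
    default_allele_freqs,
    default_panel,
)


@pytest.fixture(scope="session")
def panel3() -> WeightPanel:
    """Three-SNP toy panel with weights ln 1.5, ln 2.0, ln 1.2."""
    return WeightPanel(
        (
            WeightEntry("rs1", "1", 100, "A", "G", 1.5),
            WeightEntry("rs2", "1", 200, "C", "T", 2.0),
            WeightEntry("rs3", "2", 300, "G", "A", 1.2),
        )
    )


@pytest.fixture(scope="session")
def panel26() -> WeightPanel:
    return default_panel()


@pytest.fixture(scope="session")
def freqs26() -> np.ndarray:
    return default_allele_freqs()


@pytest.fixture()
def small_genotypes(panel3) -> GenotypeMatrix:
    counts = pd.DataFrame(
        [[1.0, 2.0, 0.0], [0.0, np.nan, 1.0], [np.nan, np.nan, 2.0]],
        index=pd.Index(["S1", "S2", "S3"], name="sample_id"),
        columns=panel3.snp_ids,
    )
    return GenotypeMatrix(counts)


@pytest.fixture()
def small_phenotypes() -> PhenotypeTable:
    data = pd.DataFrame(
        {
            "sex": [1.0, 0.0, 1.0],
            "is_case": [1.0, 1.0, 0.0],
            "family_history": [1.0, np.nan, np.nan],
            "early_onset": [0.0, 1.0, np.nan],
            "bilateral": [1.0, 0.0, np.nan],
            "ectopic": [0.0, 0.0, np.nan],
            "recurrence": [1.0, np.nan, np.nan],
        },
        index=pd.Index(["S1", "S2", "S3"], name="sample_id"),
    )
    return PhenotypeTable(data)


def logit_2x2_or(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Closed-form 2x2 log-OR and Woolf SE (events a/c, non-events b/d)."""
    return math.log(a * d / (b * c)), math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
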