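import numpy as np
import pandas as pd
import pytest

from mitoepi.io import GenotypeMatrix, PhenotypeTable, VariantInfo


@pytest.fixture()
def tiny_matrix():
    """Hand-built 5 samples x 4 variants matrix with known missingness."""
    variants = [
        VariantInfo("v1", "1", 100, "A", "G"),
        VariantInfo("v2", "1", 200, "C", "T"),
        VariantInfo("v3", "2", 300, "G", "A"),
        VariantInfo("m1", "chrMT", 50, "T", "C"),
    ]
    nan = np.nan
    dosages = np.array([
        [0, 1, 2, 0],
        [1, nan, 1, 1],
        [2, 0, nan, 0],
        [nan, nan, nan, nan],
        [1, 1, 0, 1],
    ], dtype=float)
    return GenotypeMatrix([f"s{i}" for i in range(1, 6)], variants, dosages)


@pytest.fixture()
def pheno_five():
    df = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(1, 6)],
        "bmi": [22.0, 25.5, 31.2, 19.8, 27.0],
        "age": [30.0, 41.0, 25.0, 33.0, 29.0],
        "sex": [0.0, 1.0, 0.0, 1.0, 1.0],
    })
    return PhenotypeTable(df)
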