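import numpy as np
import pandas as pd
import pytest

from zooscankit.standardization import AllometricRegistry
from zooscankit.synthetic import default_comau_community


@pytest.fixture(scope="session")
def registry():
    return AllometricRegistry.default()


@pytest.fixture(scope="session")
def community():
    return default_comau_community()


@pytest.fixture()
def simple_objects():
    """Hand-built object table: 3 measured copepods + 1 junk + 1 multi."""
    return pd.DataFrame(
        {
            "object_id": [f"s1_obj{i}" for i in range(5)],
            "sample_id": ["s1"] * 5,
            "taxon": ["Copepoda", "Copepoda", "Copepoda", "detritus", "Copepoda"],
            "area_mm2": [0.5, 0.8, 1.2, 0.4, np.nan],
            "major_mm": [1.2, 1.5, 1.8, 1.0, np.nan],
            "minor_mm": [0.5, 0.6, 0.7, 0.4, np.nan],
            "split_fraction": ["1/4"] * 5,
            "status": ["validated"] * 3 + ["junk_category", "validated"],
            "multiple_flag": [False, False, False, False, True],
        }
    )
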