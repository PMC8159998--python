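from pathlib import Path

import pandas as pd
import pytest

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def reference_constants() -> pd.DataFrame:
    """Frozen equilibrium constants from an independent reference
    implementation (see header of the CSV for provenance)."""
    return pd.read_csv(DATA / "reference_constants.csv", comment="#")


@pytest.fixture(scope="session")
def reference_speciation() -> pd.DataFrame:
    """Frozen reference speciation on a seeded subsample of the bay-range
    (TA, DIC, S, T) grid."""
    return pd.read_csv(DATA / "reference_speciation.csv", comment="#")
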