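from pathlib import Path

import pandas as pd
import pytest

from runbox import SuccessModel, joint_cl_distributions

DATA = Path(__file__).parent / "data"

FULL_RANGE = range(10, 101)


@pytest.fixture(scope="session")
def table1() -> pd.DataFrame:
    """Published reference table of limits and operating characteristics
    for N = 10..100 (expected values for reproduction tests)."""
    df = pd.read_csv(DATA / "table1.tsv", sep="\t", na_values=["NA"])
    assert len(df) == 91
    return df


@pytest.fixture(scope="session")
def null_model() -> SuccessModel:
    return SuccessModel.from_shift(0)


@pytest.fixture(scope="session")
def shift08_model() -> SuccessModel:
    return SuccessModel.from_shift(0.8)


@pytest.fixture(scope="session")
def dists_null_full(null_model):
    """Exact rational joint distributions, no shift, N = 10..100."""
    return joint_cl_distributions(FULL_RANGE, null_model)


@pytest.fixture(scope="session")
def dists_shift08_full(shift08_model):
    """Extended-precision joint distributions at shift 0.8, N = 10..100."""
    return joint_cl_distributions(FULL_RANGE, shift08_model)
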