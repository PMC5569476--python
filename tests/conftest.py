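import numpy as np
import pandas as pd
import pytest

from snparray.genotypes import GenotypeMatrix


def make_gm(call_rows: dict[str, list[str]], samples: list[str]) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {marker: [call, ...]} string rows."""
    return GenotypeMatrix(pd.DataFrame.from_dict(call_rows, orient="index",
                                                 columns=samples))


@pytest.fixture
def tiny_gm() -> GenotypeMatrix:
    """Three markers x four samples covering every call state."""
    return make_gm({
        "m1": ["AA", "AA", "AB", "BB"],
        "m2": ["AA", "AB", "NG", "--"],
        "m3": ["BB", "BB", "BB", "BB"],
    }, ["s1", "s2", "s3", "s4"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
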