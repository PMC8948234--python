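import numpy as np
import pandas as pd
import pytest

from invnet.simulate import CohortParams, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic two-class cohort with ground truth."""
    return generate_cohort(CohortParams(seed=1))


@pytest.fixture(scope="session")
def small_expr():
    """A tiny deterministic genes x samples log2 matrix."""
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(20)]
    samples = [f"s{i}" for i in range(12)]
    return pd.DataFrame(rng.normal(5, 1, size=(20, 12)), index=genes,
                        columns=samples)
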