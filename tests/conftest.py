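import numpy as np
import pandas as pd
import pytest

from kogatype import AbundanceTable, CohortSpec, simulate_paired_cohort


@pytest.fixture
def tiny_counts():
    """2x2 counts table with known row sums 4 and 4."""
    df = pd.DataFrame(
        [[2, 2], [1, 3]], index=["s1", "s2"], columns=["taxonA", "taxonB"]
    )
    return AbundanceTable(df, "counts")


@pytest.fixture
def small_cohort():
    """A 40-subject planted cohort, cheap enough for unit tests."""
    spec = CohortSpec(n_subjects=40, depth=5000, seed=42)
    return simulate_paired_cohort(spec)


def make_relative(rows, sample_ids=None, taxa=None, body_site="unspecified"):
    arr = np.asarray(rows, dtype=float)
    sample_ids = sample_ids or [f"s{i}" for i in range(arr.shape[0])]
    taxa = taxa or [f"t{i}" for i in range(arr.shape[1])]
    return AbundanceTable(
        pd.DataFrame(arr, index=sample_ids, columns=taxa), "relative", body_site
    )
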