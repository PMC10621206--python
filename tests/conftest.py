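import numpy as np
import pandas as pd
import pytest

from snpsig.matrix import MISSING, GenotypeMatrix
from snpsig.phenotype import CohortAssignment


def make_matrix(states, snp_ids=None, sample_ids=None, chrom="1", positions=None):
    """Build a small GenotypeMatrix from a nested list of states."""
    states = np.asarray(states, dtype=np.int8)
    n, m = states.shape
    snp_ids = snp_ids or [f"snp{j}" for j in range(m)]
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    positions = positions if positions is not None else (np.arange(m) + 1) * 1000
    snp_map = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "minor_is_alt": [True] * m,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GenotypeMatrix(sample_ids, snp_ids, states, snp_map)


def cohort_from_bools(case_flags, sample_ids):
    return CohortAssignment.from_labels(np.asarray(case_flags, dtype=bool), sample_ids)


@pytest.fixture
def tiny_matrix():
    # 6 samples x 3 SNPs with one missing call
    return make_matrix(
        [
            [0, 1, 2],
            [1, 1, 0],
            [1, 0, 0],
            [2, 1, 1],
            [0, MISSING, 0],
            [0, 0, 1],
        ]
    )
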