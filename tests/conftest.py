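"""Shared fixtures: small deterministic cohorts and item matrices."""

import math

import numpy as np
import pandas as pd
import pytest

from twinace.data_io import CohortTable, Twin, TwinPairRecord
from twinace.simulate import UnivariateSimSpec, simulate_pairs


def make_cohort(values, zygosities, trait="y", sexes=None, years=None):
    """Build a cohort from a list of (twin1, twin2) value tuples."""
    records = []
    for i, ((v1, v2), zyg) in enumerate(zip(values, zygosities)):
        sx = sexes[i] if sexes else ("F", "F")
        yr = years[i] if years else 2000
        records.append(TwinPairRecord(
            f"p{i}", zyg,
            Twin(sex=sx[0], birth_year=yr, phenotypes={trait: v1}),
            Twin(sex=sx[1], birth_year=yr, phenotypes={trait: v2})))
    return CohortTable(records, [trait])


@pytest.fixture
def toy_cohort():
    """Three pairs, mixed zygosity, one missing cell — oracle-sized."""
    return make_cohort(
        [(0.3, -0.5), (1.1, 0.2), (math.nan, 0.8)],
        ["MZ", "DZ_SS", "MZ"])


@pytest.fixture
def small_sim_cohort():
    """400 simulated pairs with a moderate genetic signal."""
    spec = UnivariateSimSpec(0.5, 0.0, 0.5, n_mz=200, n_dz=200, seed=7,
                             trait="y")
    return simulate_pairs(spec)


@pytest.fixture
def item_matrix():
    """Six individuals x four items with one missing cell."""
    from twinace.preprocess import ItemResponseMatrix

    data = pd.DataFrame({
        "i1": [1.0, 0.5, 0.0, 1.0, 0.0, 0.5],
        "i2": [1.0, 0.0, 0.0, 0.5, 0.5, 0.5],
        "i3": [0.5, 0.5, 0.0, 1.0, 0.0, 1.0],
        "i4": [1.0, 0.0, np.nan, 1.0, 0.0, 0.5],
    })
    return ItemResponseMatrix(data)
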