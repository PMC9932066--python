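import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from pollinet.netbuild import RECORD_COLUMNS
from pollinet.synthetic_data import SyntheticConfig, generate_dataset


def make_records(rows) -> pd.DataFrame:
    """Build a record table from (site, round, plant, visitor, group, count)
    tuples."""
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


@pytest.fixture(scope="session")
def small_dataset():
    """A compact 8-site synthetic dataset shared by read-only tests."""
    cfg = SyntheticConfig(
        n_sites=8,
        seed=42,
        pool_sizes={"wild_bee": 40, "hoverfly": 15, "butterfly": 10, "plant": 30},
    )
    landscape, records, predictors = generate_dataset(cfg)
    return cfg, landscape, records, predictors


@pytest.fixture
def toy_records():
    return make_records(
        [
            ("siteA", "r1", "Achillea millefolium", "Bombus sp001", "wild_bee", 2),
            ("siteA", "r2", "Achillea millefolium", "Bombus sp001", "wild_bee", 3),
            ("siteA", "r1", "Centaurea jacea", "Bombus sp002", "wild_bee", 1),
            ("siteA", "r1", "Daucus carota", "Eristalis sp001", "hoverfly", 4),
            ("siteA", "r2", "Centaurea jacea", "Apis mellifera", "honey_bee", 2),
            ("siteB", "r1", "Achillea millefolium", "Pieris sp001", "butterfly", 1),
            ("siteB", "r1", "Centaurea jacea", "Bombus sp001", "wild_bee", 2),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
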