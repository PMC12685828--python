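from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from micronet.synthetic import CommunityDesign, _make_metadata
from micronet.tables_io import FeatureTable


@pytest.fixture
def meta18() -> pd.DataFrame:
    """The balanced 3 treatments x 2 locations x 3 blocks metadata."""
    return _make_metadata(CommunityDesign())


@pytest.fixture
def small_table() -> FeatureTable:
    counts = np.array(
        [
            [10, 0, 3, 7],
            [5, 5, 5, 5],
            [0, 12, 1, 2],
        ]
    )
    return FeatureTable(
        ["t1", "t2", "t3"], ["s1", "s2", "s3", "s4"], counts
    )


def balanced_values(meta: pd.DataFrame, rng: np.random.Generator,
                    treatment_effect: dict[str, float] | None = None,
                    location_effect: dict[str, float] | None = None,
                    sd: float = 1.0) -> pd.Series:
    """Gaussian response with optional factor effects, aligned to meta."""
    y = rng.normal(0.0, sd, size=len(meta))
    if treatment_effect:
        y += np.array([treatment_effect.get(t, 0.0)
                       for t in meta["treatment"]])
    if location_effect:
        y += np.array([location_effect.get(l, 0.0)
                       for l in meta["location"]])
    return pd.Series(y, index=meta.index)
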