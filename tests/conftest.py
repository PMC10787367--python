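import numpy as np
import pandas as pd
import pytest

from coabnet.data_model import FeatureTable, SampleMeta


@pytest.fixture
def small_relative_table() -> FeatureTable:
    data = pd.DataFrame(
        {
            "s1": [0.5, 0.25, 0.25],
            "s2": [0.2, 0.3, 0.5],
        },
        index=["f1", "f2", "f3"],
    )
    return FeatureTable(data, kind="species", scale="relative")


@pytest.fixture
def crossed_meta() -> list[SampleMeta]:
    """Fully crossed 3 groups x 3 days x 2 calves design."""
    meta = []
    for group in ("CON", "RMT", "RFT"):
        for ci in (1, 2):
            for day in (15, 35, 56):
                meta.append(
                    SampleMeta(
                        sample_id=f"{group}{ci:02d}_d{day}",
                        calf_id=f"{group}{ci:02d}",
                        group=group,
                        day=day,
                        total_reads=100_000,
                    )
                )
    return meta


@pytest.fixture
def crossed_table(crossed_meta) -> FeatureTable:
    rng = np.random.default_rng(42)
    cols = [m.sample_id for m in crossed_meta]
    vals = rng.dirichlet(np.ones(5), size=len(cols)).T
    return FeatureTable(pd.DataFrame(vals, index=[f"f{i}" for i in range(5)], columns=cols),
                        kind="species", scale="relative")
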