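import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from endopersist import AbundanceTable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_table(counts, taxa=None, samples=None, metadata=None):
    counts = np.asarray(counts)
    taxa = taxa or [f"t{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    meta = None
    if metadata is not None:
        meta = pd.DataFrame(metadata, index=samples)
    return AbundanceTable(pd.DataFrame(counts, index=taxa, columns=samples), meta)


@pytest.fixture
def tiny_table():
    return make_table([[5, 3], [0, 7], [2, 2]])


@pytest.fixture
def seasonal_metadata():
    def build(n_per_season=5, seasons=("spring", "summer", "autumn", "winter")):
        rows = []
        for season in seasons:
            for r in range(n_per_season):
                rows.append(
                    {
                        "site": "control",
                        "tissue": "aerial",
                        "season": season,
                        "replicate": r + 1,
                    }
                )
        return rows

    return build
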