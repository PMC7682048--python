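import numpy as np
import pandas as pd
import pytest

from mloy.io import SampleData
from mloy.simulate import SignalModel


@pytest.fixture(scope="session")
def small_model() -> SignalModel:
    """Reduced probe counts for fast per-probe simulation in tests."""
    return SignalModel(n_auto_probes=600, n_msy_probes=80, n_par_probes=200)


@pytest.fixture(scope="session")
def noiseless_model() -> SignalModel:
    return SignalModel(
        sigma_auto=0.0,
        sigma_y=0.0,
        baf_noise=0.0,
        n_auto_probes=200,
        n_msy_probes=40,
        n_par_probes=100,
    )


def make_sample(sample_id="s1", **columns) -> SampleData:
    """Build a SampleData from parallel column lists."""
    n = len(columns["chrom"])
    df = pd.DataFrame(
        {
            "name": columns.get("name", [f"rs{i}" for i in range(n)]),
            "chrom": columns["chrom"],
            "position": columns["position"],
            "lrr": columns.get("lrr", np.zeros(n)),
            "baf": columns.get("baf", [np.nan] * n),
            "genotype": columns.get("genotype", [None] * n),
        }
    )
    return SampleData.from_dataframe(sample_id, df)
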