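import numpy as np
import pandas as pd
import pytest

from uromet import synthetic_data as sd


@pytest.fixture(scope="session")
def centroids():
    return sd.make_centroids()


@pytest.fixture(scope="session")
def variant_sim():
    """Matched pair with all five artifact classes planted."""
    rates = {cls: 0.06 for cls in ("low_depth", "low_vaf", "germline", "dbsnp_only", "blocklist")}
    return sd.gen_matched_variant_calls(20, 50, 30, artifact_config=rates, seed=11)


@pytest.fixture(scope="session")
def singlecell_sim():
    return sd.gen_singlecell_cohort(
        n_cells_per_image=250, images_per_sample=2, seed=5,
        batch_effects={"batch1": 1.3}, solidity_one_prob=0.02,
    )


def caller_table(sim, sample):
    """Concatenate one sample's per-caller tables."""
    return pd.concat(sim.calls[sample].values(), ignore_index=True)
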