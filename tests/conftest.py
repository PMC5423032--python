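import numpy as np
import pandas as pd
import pytest


def make_spot_frame(rows):
    """Build a spot-table frame from (sample, block, probe, rep, fg, bg) tuples."""
    df = pd.DataFrame(rows, columns=["sample_id", "block_id", "probe",
                                     "replicate", "foreground", "background"])
    df["is_control"] = df["probe"].isin({"BSA", "buffer"})
    return df


@pytest.fixture
def single_block():
    """One block, three probes, backgrounds {85, 90, 95} (mean 90, SD 5)."""
    return make_spot_frame([
        ("s1", "b1", "A", 1, 95.0, 85.0),
        ("s1", "b1", "B", 1, 100.0, 90.0),
        ("s1", "b1", "C", 1, 300.0, 95.0),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
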