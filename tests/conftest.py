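import numpy as np
import pandas as pd
import pytest

import mndprofiler as mp


@pytest.fixture
def tiny_count_matrix():
    """Two genes, two samples, with the lengths used in worked examples."""
    counts = pd.DataFrame(
        {"s1": [100, 900], "s2": [10, 0]}, index=["A", "B"], dtype=np.int64
    )
    lengths = pd.Series([500, 2000], index=["A", "B"])
    return mp.CountMatrix(counts=counts, gene_lengths=lengths)


@pytest.fixture
def two_donor_sheet():
    return mp.SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["CN_D1", "CN_D2", "F_D1", "F_D2"],
                "donor_id": ["D1", "D2", "D1", "D2"],
                "cell_type": ["CN", "CN", "F", "F"],
            }
        )
    )


@pytest.fixture(scope="session")
def canonical_run():
    """One seeded canonical-fixture pipeline run shared across tests."""
    cfg = mp.canonical_config(seed=0)
    cm, sheet, truth = mp.simulate_counts(cfg)
    floored = mp.apply_detection_floor(mp.rpkm(cm))
    means = mp.donor_mean(floored, sheet)
    panel = truth.to_panel()
    classifications = mp.classify_panel(means, panel)
    summary = mp.summarize(classifications, panel)
    return cfg, cm, sheet, truth, means, panel, classifications, summary
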