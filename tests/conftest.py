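import numpy as np
import pandas as pd
import pytest

from orchardnet.containers import CountMatrix, SampleMetadata
from orchardnet.io import parse_newick
from orchardnet.simulate import scenario_presets, simulate_community


@pytest.fixture
def toy_tree():
    """Three-leaf rooted tree with total branch length 5."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def small_matrix():
    return CountMatrix(
        ["t1", "t2", "t3"],
        ["s1", "s2"],
        np.array([[3, 0], [1, 2], [0, 4]]),
    )


@pytest.fixture
def two_strata_metadata():
    rows = []
    for i in range(5):
        rows.append(dict(sample_id=f"IPM_drive_row_s{i+1:03d}", land_use="IPM",
                         location="drive_row", site_id="a", plot_id="a1", subplot_id=f"a1{i}"))
        rows.append(dict(sample_id=f"grassland_s{i+1:03d}", land_use="grassland",
                         location="none", site_id="g", plot_id="g1", subplot_id=f"g1{i}"))
    return SampleMetadata(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def tiny_community():
    """Full artifact set from the tiny_fixture preset (seconds to run)."""
    return simulate_community(scenario_presets("tiny_fixture", seed=5))
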