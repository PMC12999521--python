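import numpy as np
import pandas as pd
import pytest

from thermotree.trees import CalibratedTree


@pytest.fixture
def balanced_four() -> CalibratedTree:
    """Ultrametric 4-tip balanced tree of depth 2."""
    return CalibratedTree.from_newick("((t1:1,t2:1):1,(t3:1,t4:1):1);")


@pytest.fixture
def star_five() -> CalibratedTree:
    """5-tip star tree (all tips attach directly to the root)."""
    return CalibratedTree.from_newick("(t1:1,t2:1,t3:1,t4:1,t5:1);")


@pytest.fixture
def five_tip_asym() -> CalibratedTree:
    """Non-trivial ultrametric 5-tip tree used against dense-matrix oracles."""
    return CalibratedTree.from_newick(
        "(((a:1,b:1):1,c:2):1,(d:1.5,e:1.5):1.5);"
    )


@pytest.fixture
def assay_records() -> pd.DataFrame:
    """Small hand-built assay table covering two plots and both directions."""
    rows = []
    rng = np.random.default_rng(0)
    for plot, elev in (("P01", 300.0), ("P02", 1500.0)):
        for i in range(10):
            rows.append(
                {
                    "individual_id": f"{plot}_max{i}",
                    "otu_id": f"OTU_{i % 4}",
                    "family": "FamA",
                    "order": "Diptera",
                    "region": "neotropics",
                    "plot_id": plot,
                    "elevation": elev,
                    "direction": "ctmax",
                    "shocked": "no",
                    "observer": f"obs{i % 2 + 1}",
                    "ct_value": float(40 + rng.integers(0, 5)),
                }
            )
            rows.append(
                {
                    "individual_id": f"{plot}_min{i}",
                    "otu_id": f"OTU_{i % 4}",
                    "family": "FamA",
                    "order": "Diptera",
                    "region": "neotropics",
                    "plot_id": plot,
                    "elevation": elev,
                    "direction": "ctmin",
                    "shocked": "no",
                    "observer": f"obs{i % 2 + 1}",
                    "ct_value": float(4 + rng.integers(0, 4)),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def plot_normals() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plot_id": ["P01", "P02"],
            "elevation": [300.0, 1500.0],
            "bio1": [24.3, 18.0],
            "bio5": [30.0, 23.5],
            "bio5_ssp585": [33.5, 27.0],
        }
    )
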