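import numpy as np
import pandas as pd
import pytest

import treehet as th


@pytest.fixture
def tree_012():
    """Average-linkage dendrogram of the 1-d points {0, 1, 10}.

    Leaves a, b (weights 1, 1) merge at height 1; the pair joins the third
    leaf (weight 9.5) at height 9.5 (average of 10 and 9); total weight 20.
    """
    D = th.lesion_distance_matrix(th.PointCloud("p", np.array([[0.0], [1.0], [10.0]])))
    return th.average_linkage_dendrogram(D, labels=["a", "b", "c"])


@pytest.fixture
def cherry95():
    """Two leaves of weight 9.5 under the root: the eps=1 pruning of tree_012."""
    return th.MergeTree(np.array([2, 2, -1]), np.array([0.0, 0.0, 9.5]), ["a", "c", None])


def cherry(w1: float, w2: float) -> th.MergeTree:
    hi = max(w1, w2)
    return th.MergeTree(np.array([2, 2, -1]), np.array([hi - w1, hi - w2, hi]))


@pytest.fixture
def small_table():
    """3-lesion table over the default 40-feature schema."""
    schema = th.default_schema()
    rng = np.random.default_rng(0)
    feats = pd.DataFrame(rng.normal(size=(3, 40)), columns=schema.features)
    return th.RadiomicTable(
        pd.Series(["P1", "P1", "P2"]),
        pd.Series(["L1", "L2", "L1"]),
        pd.Series([1.0, 2.0, 3.0]),
        feats,
    ), schema
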