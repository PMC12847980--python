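import numpy as np
import pytest

from topoqspr import build_graph, data


@pytest.fixture
def glycine_graph():
    # N-C-C(=O)-O backbone: 5 heavy atoms, degrees {1, 2, 3, 1, 1}
    return build_graph([(1, 2), (2, 3), (3, 4), (3, 5)])


@pytest.fixture
def glycine_partition():
    return data.drug_partition("glycine")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def study_tables():
    """(properties, recomputed index table) aligned on the nine drugs."""
    import pandas as pd

    from topoqspr import INDEX_IDS, compute_all

    props = data.drug_properties()
    idx = pd.DataFrame(
        [{i: compute_all(data.drug_partition(d))[i] for i in INDEX_IDS}
         for d in data.DRUGS],
        index=list(data.DRUGS),
    )
    return props, idx
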