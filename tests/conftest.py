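import numpy as np
import pandas as pd
import pytest

import phyloexpr as px


@pytest.fixture(scope="session")
def primate():
    return px.primate_tree()


@pytest.fixture(scope="session")
def small_tree():
    # 5 tips, non-trivial nesting, ultrametric depth 2
    return px.Phylogeny.from_newick(
        "((A:1,B:1):1,(C:0.5,(D:0.3,E:0.3):0.2):1.5);"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_counts():
    df = pd.DataFrame(
        {
            "s1": [50, 10, 200, 30, 5],
            "s2": [45, 12, 180, 25, 0],
            "s3": [55, 9, 210, 35, 8],
            "s4": [60, 11, 190, 28, 4],
        },
        index=[f"g{i}" for i in range(1, 6)],
    )
    return px.ExpressionMatrix(df, scale="counts")
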