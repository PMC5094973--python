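import numpy as np
import pandas as pd
import pytest

from progdyn import ExpressionMatrix, GeneSet, StageDesign


@pytest.fixture
def tiny_matrix():
    """3 genes × 4 samples, two classes."""
    values = pd.DataFrame(
        [[5.0, 5.2, 7.1, 7.3],
         [6.0, 6.1, 4.0, 3.9],
         [5.5, 5.4, 5.5, 5.6]],
        index=["G1", "G2", "G3"],
        columns=["n1", "n2", "t1", "t2"],
    )
    ann = pd.Series(["normal", "normal", "tumor", "tumor"], index=values.columns)
    return ExpressionMatrix(values, ann)


@pytest.fixture
def four_stage_design():
    stages = ("normal", "hyperplasia", "dysplasia", "tumor")
    samples = [f"{s}_{r}" for s in stages for r in (1, 2, 3)]
    ann = pd.Series([s.rsplit("_", 1)[0] for s in samples], index=samples)
    return StageDesign(stages, ann)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_gene_set(name, members):
    return GeneSet.from_members(name, members)
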