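import numpy as np
import pandas as pd
import pytest

from hcpnorm.matrix import CountMatrix, ExpressionMatrix, GeneAnnotation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts():
    counts = np.array(
        [
            [0, 5, 40, 31],
            [2, 7, 35, 29],
            [1, 6, 50, 33],
        ]
    )
    return CountMatrix(counts, ["s1", "s2", "s3"], ["g1", "g2", "g3", "g4"])


@pytest.fixture
def small_annotation():
    table = pd.DataFrame(
        {
            "chrom": ["chr1"] * 4,
            "tss": [1_000_000, 2_000_000, 3_000_000, 4_000_000],
            "strand": ["+", "-", "+", "-"],
            "length_bp": [1000, 2000, 1500, 800],
            "gc_fraction": [0.35, 0.5, 0.6, 0.45],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )
    return GeneAnnotation(table)


@pytest.fixture
def random_expression(rng):
    n, g = 20, 30
    values = rng.standard_normal((n, g))
    return ExpressionMatrix(
        values, [f"s{i}" for i in range(n)], [f"g{j}" for j in range(g)]
    )
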