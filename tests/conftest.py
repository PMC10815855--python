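import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sysgen.types import ExpressionMatrix, GenotypeMatrix

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_genotypes() -> GenotypeMatrix:
    """Three strains x four markers over two chromosomes."""
    markers = pd.DataFrame(
        {
            "chrom": ["1", "1", "2", "2"],
            "pos_mb": [10.0, 20.0, 5.0, 30.0],
            "pos_cm": [0.0, 5.0, 0.0, 12.0],
        },
        index=pd.Index(["m1", "m2", "m3", "m4"], name="marker"),
    )
    codes = pd.DataFrame(
        [[0, 0, 1, 1], [1, 1, 0, 0], [0, 1, 1, 0]],
        index=pd.Index(["BXD1", "BXD2", "BXD3"], name="strain"),
        columns=markers.index,
        dtype=np.int8,
    )
    return GenotypeMatrix(codes, markers)


@pytest.fixture
def small_expression() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(8)]
    samples = [f"s{i}" for i in range(10)]
    vals = pd.DataFrame(8.0 + rng.standard_normal((8, 10)), index=genes, columns=samples)
    ann = pd.DataFrame(
        {"chrom": ["1"] * 4 + ["2"] * 4, "pos_mb": [10.0, 20, 30, 40, 10, 20, 30, 40]},
        index=pd.Index(genes, name="gene"),
    )
    return ExpressionMatrix(vals, ann)
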