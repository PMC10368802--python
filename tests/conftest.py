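import numpy as np
import pytest

from codemerge.data_model import (
    LOG_NORMALIZED,
    RAW_COUNTS,
    ClusterPartition,
    ExpressionMatrix,
)


def make_expr(values, layer_kind=LOG_NORMALIZED, prefix=("cell", "gene")):
    values = np.asarray(values, dtype=float)
    t, f = values.shape
    return ExpressionMatrix(
        values,
        [f"{prefix[0]}{i}" for i in range(t)],
        [f"{prefix[1]}{j}" for j in range(f)],
        layer_kind,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_expr(rng):
    """50 cells x 20 genes of sparse-ish log-scale values."""
    vals = rng.gamma(1.0, 1.0, size=(50, 20)) * (rng.random((50, 20)) < 0.5)
    return make_expr(vals)


@pytest.fixture
def two_group_expr(rng):
    """Two well-separated 30-cell groups: genes 0-2 mark A, genes 3-5 mark B."""
    vals = rng.gamma(0.5, 1.0, size=(60, 12)) * (rng.random((60, 12)) < 0.3)
    vals[:30, 0:3] += rng.gamma(5.0, 1.0, size=(30, 3))
    vals[30:, 3:6] += rng.gamma(5.0, 1.0, size=(30, 3))
    expr = make_expr(vals)
    part = ClusterPartition(["A"] * 30 + ["B"] * 30, expr.cell_ids)
    return expr, part


@pytest.fixture
def counts_expr(rng):
    vals = rng.poisson(2.0, size=(10, 6)).astype(float)
    vals[0, :] = [1, 0, 2, 0, 3, 1]  # guarantee a nonzero first row
    return make_expr(vals, layer_kind=RAW_COUNTS)
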