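import numpy as np
import pytest

from spadama import (
    CellTypeLabels,
    ExpressionMatrix,
    FixtureSpec,
    make_ground_truth_st,
    make_reference,
)


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    values = np.array([[1.0, 2.0], [3.0, 4.0], [0.0, 5.0]])
    return ExpressionMatrix(values, ["s1", "s2", "s3"], ["g1", "g2"], "spots")


@pytest.fixture
def exclusive_reference() -> tuple[ExpressionMatrix, CellTypeLabels]:
    """Three types x four cells; gene k is expressed only in type k."""
    rng = np.random.default_rng(0)
    n_per, K, G = 4, 3, 3
    values = rng.uniform(0.0, 0.2, size=(n_per * K, G))
    labels = []
    for k in range(K):
        values[k * n_per:(k + 1) * n_per, k] += 5.0
        labels += [f"t{k}"] * n_per
    ref = ExpressionMatrix(values, [f"c{i}" for i in range(n_per * K)],
                           [f"g{j}" for j in range(G)], "cells")
    return ref, CellTypeLabels(labels, [f"t{k}" for k in range(K)])


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    return FixtureSpec(K=4, G=120, markers_per_type=15, cells_per_type=60,
                       n_spots=120, signal=8.0, seed=7)


@pytest.fixture(scope="session")
def small_fixture(small_spec):
    ref, labels = make_reference(small_spec)
    st, truth = make_ground_truth_st(small_spec, ref, labels)
    return ref, labels, st, truth
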