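import numpy as np
import pytest

from scassign.core_data import AnnotatedMatrix


@pytest.fixture
def tiny_counts():
    """5 cells x 4 genes with hand-checkable count patterns."""
    counts = np.array([
        [1, 0, 2, 0],
        [0, 3, 0, 0],
        [5, 1, 1, 1],
        [0, 0, 0, 4],
        [2, 2, 2, 2],
    ], dtype=float)
    m = AnnotatedMatrix(counts, [f"c{i}" for i in range(5)],
                        [f"g{j}" for j in range(4)])
    m.set_layer("counts", m.values.copy())
    return m


@pytest.fixture
def two_triangles():
    from scassign.core_data import NeighborGraph
    return NeighborGraph(6, {(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)}, 2)
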