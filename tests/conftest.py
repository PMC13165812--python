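import numpy as np
import pytest

from atompool.graph_io import Graph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_graph(n: int, p: float, rng: np.random.Generator, feature_dim: int = 1) -> Graph:
    """Erdos-Renyi graph with symmetric {0,1} adjacency and zero diagonal."""
    upper = rng.random((n, n)) < p
    a = np.triu(upper, k=1).astype(np.int8)
    a = a + a.T
    return Graph(adjacency=a, features=np.ones((n, feature_dim)), label=0)


@pytest.fixture
def random_graph_factory():
    return random_graph


def write_two_triangles(directory, name="TRI"):
    """Minimal TU fixture: two disjoint triangles, labels 1 and 2."""
    edges = [(1, 2), (2, 1), (2, 3), (3, 2), (1, 3), (3, 1),
             (4, 5), (5, 4), (5, 6), (6, 5), (4, 6), (6, 4)]
    (directory / f"{name}_A.txt").write_text(
        "".join(f"{u}, {v}\n" for u, v in edges)
    )
    (directory / f"{name}_graph_indicator.txt").write_text("1\n1\n1\n2\n2\n2\n")
    (directory / f"{name}_graph_labels.txt").write_text("1\n2\n")
    return name


@pytest.fixture
def two_triangle_dir(tmp_path):
    name = write_two_triangles(tmp_path)
    return tmp_path, name
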