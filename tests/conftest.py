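import networkx as nx
import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def star_net() -> nx.Graph:
    """3-node star: center A with leaves B, C."""
    return nx.Graph([("A", "B"), ("A", "C")])


@pytest.fixture
def star_profiles():
    """The worked normal/tumor pair on the star (center value arbitrary)."""
    normal = pd.Series({"A": 5.0, "B": 2.0, "C": 2.0}, name="normal")
    tumor = pd.Series({"A": 5.0, "B": 1.0, "C": 3.0}, name="tumor")
    return normal, tumor


@pytest.fixture
def random_instance():
    """Factory for a random connected network + positive profile pair."""

    def make(seed: int, n: int = 12, p: float = 0.35, allow_zeros: bool = False):
        rng = np.random.default_rng(seed)
        net = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
        largest = max(nx.connected_components(net), key=len)
        net = nx.relabel_nodes(nx.Graph(net.subgraph(largest)), {i: f"g{i}" for i in largest})
        genes = sorted(net.nodes)
        low = 0.0 if allow_zeros else 0.1
        x = pd.Series(rng.uniform(low, 10.0, len(genes)), index=genes, name="X")
        y = pd.Series(rng.uniform(low, 10.0, len(genes)), index=genes, name="Y")
        return net, x, y

    return make


@pytest.fixture
def expression_tsv(tmp_path):
    """Write a small genes × samples TSV and return its path."""

    def write(rows: dict[str, list], samples: list[str], name: str = "expr.tsv"):
        path = tmp_path / name
        lines = ["gene\t" + "\t".join(samples)]
        for gene, values in rows.items():
            lines.append(gene + "\t" + "\t".join(str(v) for v in values))
        path.write_text("\n".join(lines) + "\n")
        return path

    return write


@pytest.fixture
def edge_tsv(tmp_path):
    def write(edges: list[tuple], name: str = "net.tsv"):
        path = tmp_path / name
        path.write_text("\n".join("\t".join(str(f) for f in e) for e in edges) + "\n")
        return path

    return write
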