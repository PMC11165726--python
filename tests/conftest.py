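import networkx as nx
import pytest


def build_fig2_graph(case: str) -> tuple[nx.Graph, set[str], set[str]]:
    """Toy interactomes with drugs at known closest distances.

    Returns (graph, drug targets, disease genes); the worked d_c values are
    1.5, 1.5, 3.25 and 1.0 respectively.
    """
    if case == "drug1":
        g = nx.Graph(
            [("T1", "PSC1"), ("T2", "PSC1"), ("T3", "X1"), ("X1", "PSC2"),
             ("T4", "X2"), ("X2", "PSC3")]
        )
        return g, {"T1", "T2", "T3", "T4"}, {"PSC1", "PSC2", "PSC3"}
    if case == "drug2":
        g = nx.Graph([("U1", "PSC1"), ("U2", "Y1"), ("Y1", "PSC2")])
        return g, {"U1", "U2"}, {"PSC1", "PSC2"}
    if case == "drug3":
        g = nx.Graph(
            [("O1", "A1"), ("A1", "A2"), ("A2", "PSC1"),
             ("O2", "B1"), ("B1", "B2"), ("B2", "PSC1"),
             ("O3", "C1"), ("C1", "C2"), ("C2", "PSC2"),
             ("O4", "D1"), ("D1", "D2"), ("D2", "D3"), ("D3", "PSC3")]
        )
        return g, {"O1", "O2", "O3", "O4"}, {"PSC1", "PSC2", "PSC3"}
    if case == "drug4":
        g = nx.Graph([("P1", "PSC3"), ("P2", "PSC3"), ("P3", "PSC2")])
        return g, {"P1", "P2", "P3"}, {"PSC2", "PSC3"}
    raise ValueError(case)


FIG2_EXPECTED = {"drug1": 1.5, "drug2": 1.5, "drug3": 3.25, "drug4": 1.0}


@pytest.fixture
def write_edges(tmp_path):
    """Write an edge-list file from a list of text lines; returns the path."""

    def _write(lines, name="edges.tsv"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


def random_graph(n_nodes: int, seed: int, p: float = 0.12) -> nx.Graph:
    """Random test graph with string node labels (may be disconnected)."""
    g = nx.gnp_random_graph(n_nodes, p, seed=seed)
    return nx.relabel_nodes(g, {i: f"N{i:03d}" for i in g.nodes})
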