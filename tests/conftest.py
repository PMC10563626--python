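import networkx as nx
import pandas as pd
import pytest


@pytest.fixture
def toy_association_table(tmp_path):
    """Small association table: gene A in 2 records, B in 1, C in 3,
    one multi-gene cell, one intergenic cell and one gene-less row."""
    rows = [
        ("GCST1", "rs1", "A", "schizophrenia"),
        ("GCST1", "rs2", "A; C", "schizophrenia"),
        ("GCST2", "rs3", "B", "schizophrenia"),
        ("GCST2", "rs4", "C", "schizophrenia"),
        ("GCST3", "rs5", "C", "schizophrenia"),
        ("GCST3", "rs6", "", "schizophrenia"),
    ]
    path = tmp_path / "assoc.tsv"
    pd.DataFrame(
        rows, columns=["study_accession", "variant_id", "reported_genes", "trait"]
    ).to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def bridged_cliques():
    """Two 5-cliques joined by one unit-weight edge (11 edges per clique + 1)."""
    g = nx.Graph()
    for base in (0, 5):
        members = [f"n{i}" for i in range(base, base + 5)]
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                g.add_edge(a, b, weight=1.0)
    g.add_edge("n0", "n5", weight=1.0)
    return g


@pytest.fixture
def two_triangles():
    g = nx.Graph()
    for base in ("a", "b"):
        nodes = [f"{base}{i}" for i in range(3)]
        for i in range(3):
            g.add_edge(nodes[i], nodes[(i + 1) % 3], weight=1.0)
    return g
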