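"""Score-thresholded PPI graphs and their clustering.

A STRING-style weighted edge list is thresholded at a combined-score floor
(0.4 = medium confidence) to form an undirected graph. Clusters are found
with an in-repo Markov Cluster (MCL) algorithm — alternating expansion
(matrix power) and inflation (entrywise power with column renormalization)
of the column-stochastic transition matrix until a fixed point — whose
cluster count then seeds a spectral k-means refinement, mimicking a
two-step quality-control clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from synoverlap.errors import ParameterError, ValidationError


@dataclass
class PPIGraph:
    """Undirected weighted PPI graph after score thresholding.

    ``isolated`` lists node-universe members that lost every edge to the
    threshold (they are excluded from the graph itself).
    """

    graph: nx.Graph
    min_score: float
    score_scale: str  # "0-1" or "0-1000"
    isolated: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class Partition:
    """A disjoint clustering of graph nodes."""

    clusters: list[set[str]]
    method: str
    parameters: dict
    converged: bool = True
    attractor_map: dict | None = None

    def __post_init__(self):
        if any(not c for c in self.clusters):
            raise ValidationError("partition contains an empty cluster")
        all_nodes = [n for c in self.clusters for n in c]
        if len(all_nodes) != len(set(all_nodes)):
            raise ValidationError("partition clusters are not disjoint")

    def labels(self) -> dict[str, int]:
        return {node: i for i, cluster in enumerate(self.clusters) for node in cluster}

    def sizes(self) -> list[int]:
        return sorted((len(c) for c in self.clusters), reverse=True)

    def to_frame(self) -> pd.DataFrame:
        labels = self.labels()
        return pd.DataFrame(
            {
                "protein_id": sorted(labels),
                "cluster_id": [labels[n] for n in sorted(labels)],
                "method": self.method,
                "parameters": repr(self.parameters),
            }
        )


def build_graph(edges, min_score: float = 0.4, node_universe=None) -> PPIGraph:
    """Build a thresholded PPI graph from (a, b, score) edge records.

    If any raw score exceeds 1 the whole file is read on the STRING 0-1000
    scale and divided by 1000. Duplicate undirected pairs collapse to their
    maximum score; self-edges are ignored. Nodes of ``node_universe``
    without a surviving edge are reported in ``isolated``.
    """
    if isinstance(edges, pd.DataFrame):
        records = list(edges.itertuples(index=False, name=None))
    else:
        records = [tuple(e) for e in edges]
    scores = [float(r[2]) for r in records]
    if any(s < 0 or s > 1000 for s in scores):
        raise ValidationError("scores must lie in [0, 1] or [0, 1000]")
    scale = "0-1000" if any(s > 1 for s in scores) else "0-1"
    divisor = 1000.0 if scale == "0-1000" else 1.0

    graph = nx.Graph()
    for (a, b, s), raw in zip(((str(r[0]), str(r[1]), float(r[2])) for r in records), records):
        score = s / divisor
        if a == b or score < min_score:
            continue
        if graph.has_edge(a, b):
            graph[a][b]["weight"] = max(graph[a][b]["weight"], score)
        else:
            graph.add_edge(a, b, weight=score)

    isolated: list[str] = []
    if node_universe is not None:
        isolated = sorted(set(map(str, node_universe)) - set(graph.nodes))
    return PPIGraph(graph=graph, min_score=min_score, score_scale=scale, isolated=isolated)


def read_edge_list(path, min_score: float = 0.4, node_universe=None) -> PPIGraph:
    """Read a TSV edge list (protein_a, protein_b, combined_score)."""
    frame = pd.read_csv(path, sep="\t")
    cols = list(frame.columns[:3])
    return build_graph(frame[cols], min_score=min_score, node_universe=node_universe)


def _transition_matrix(graph: nx.Graph, nodes: list[str], self_loop: float,
                       weighted: bool) -> np.ndarray:
    adj = nx.to_numpy_array(graph, nodelist=nodes, weight="weight" if weighted else None)
    adj = adj + self_loop * np.eye(len(nodes))
    return adj / adj.sum(axis=0, keepdims=True)


def _clusters_from_limit(matrix: np.ndarray, nodes: list[str]) -> tuple[list[set[str]], dict]:
    """Read clusters from the attractor structure of a converged MCL matrix.

    Attractors are nodes with positive return probability (nonzero
    diagonal); an attractor's cluster is the set of nodes that flow into
    it (nonzero entries of its row). Overlapping attractor systems are
    merged; any node flowing into several clusters goes to the largest one
    (ties to the cluster with the lexicographically smallest member).
    """
    eps = 1e-12
    attractors = [i for i in range(len(nodes)) if matrix[i, i] > eps]
    raw: list[set[int]] = []
    for a in attractors:
        basin = {j for j in range(len(nodes)) if matrix[a, j] > eps} | {a}
        merged = False
        for cluster in raw:
            if cluster & basin:
                cluster |= basin
                merged = True
                break
        if merged:
            # cascading merges: re-coalesce any clusters now overlapping
            changed = True
            while changed:
                changed = False
                for i in range(len(raw)):
                    for j in range(i + 1, len(raw)):
                        if raw[i] & raw[j]:
                            raw[i] |= raw.pop(j)
                            changed = True
                            break
                    if changed:
                        break
        else:
            raw.append(basin)
    assigned: dict[int, int] = {}
    for node in range(len(nodes)):
        containing = [ci for ci, cluster in enumerate(raw) if node in cluster]
        if not containing:
            raw.append({node})  # numerically orphaned node -> singleton
            containing = [len(raw) - 1]
        best = min(containing, key=lambda ci: (-len(raw[ci]), min(nodes[x] for x in raw[ci])))
        assigned[node] = best
    clusters: dict[int, set[str]] = {}
    for node, ci in assigned.items():
        clusters.setdefault(ci, set()).add(nodes[node])
    attractor_map = {nodes[a]: assigned[a] for a in attractors}
    return list(clusters.values()), attractor_map


def mcl_cluster(
    graph: PPIGraph | nx.Graph,
    inflation: float = 1.3,
    expansion: int = 2,
    self_loop: float = 1.0,
    prune: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-8,
    weighted: bool = True,
) -> Partition:
    """Markov clustering of a PPI graph.

    The column-stochastic transition matrix (edge weights plus a
    ``self_loop`` on every node) is alternately expanded (raised to the
    ``expansion``-th matrix power) and inflated (entrywise power
    ``inflation`` followed by column renormalization), with entries below
    ``prune`` removed, until the largest entrywise change drops under
    ``tol``. Clusters are the attractor basins of the limit matrix. Higher
    inflation yields more, smaller clusters.
    """
    g = graph.graph if isinstance(graph, PPIGraph) else graph
    if g.number_of_nodes() == 0:
        raise ParameterError("cannot cluster an empty graph")
    if inflation <= 1:
        raise ParameterError(f"inflation must be > 1, got {inflation}")
    nodes = sorted(g.nodes)
    matrix = _transition_matrix(g, nodes, self_loop, weighted)
    converged = False
    for _ in range(max_iter):
        expanded = np.linalg.matrix_power(matrix, expansion)
        inflated = np.power(expanded, inflation)
        inflated[inflated < prune] = 0.0
        colsums = inflated.sum(axis=0, keepdims=True)
        colsums[colsums == 0] = 1.0
        inflated /= colsums
        if np.max(np.abs(inflated - matrix)) < tol:
            matrix = inflated
            converged = True
            break
        matrix = inflated
    if not converged:
        warnings.warn(
            f"MCL did not converge within {max_iter} iterations; "
            "returning the partition of the last iterate",
            stacklevel=2,
        )
    clusters, attractor_map = _clusters_from_limit(matrix, nodes)
    return Partition(
        clusters=clusters,
        method="MCL",
        parameters={"inflation": inflation, "expansion": expansion,
                    "self_loop": self_loop, "prune": prune, "weighted": weighted},
        converged=converged,
        attractor_map=attractor_map,
    )


def kmeans_refine(
    graph: PPIGraph | nx.Graph,
    k: int,
    seed: int,
    restarts: int = 100,
    weighted: bool = True,
) -> Partition:
    """Spectral k-means refinement of a PPI graph clustering.

    Nodes are embedded by the leading k eigenvectors of the
    symmetric-normalized adjacency D^{-1/2} A D^{-1/2} (rows unit-
    normalized) and clustered with k-means using ``restarts`` random
    initializations from ``seed``; the best-inertia solution is kept. The
    result is deterministic given (graph, k, seed).
    """
    g = graph.graph if isinstance(graph, PPIGraph) else graph
    nodes = sorted(g.nodes)
    if not 1 <= k <= len(nodes):
        raise ParameterError(f"k must be in [1, {len(nodes)}], got {k}")
    adj = nx.to_numpy_array(g, nodelist=nodes, weight="weight" if weighted else None)
    degree = adj.sum(axis=1)
    degree[degree == 0] = 1.0
    d_inv_sqrt = 1.0 / np.sqrt(degree)
    sym = adj * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    eigvals, eigvecs = np.linalg.eigh(sym)
    embedding = eigvecs[:, np.argsort(eigvals)[::-1][:k]]
    norms = np.linalg.norm(embedding, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    embedding = embedding / norms
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(embedding)
    clusters: dict[int, set[str]] = {}
    for node, label in zip(nodes, km.labels_):
        clusters.setdefault(int(label), set()).add(node)
    return Partition(
        clusters=list(clusters.values()),
        method="kmeans",
        parameters={"k": k, "seed": seed, "restarts": restarts, "weighted": weighted},
    )


def select_clusters(partition: Partition, min_size: int = 4) -> list[set[str]]:
    """Clusters with at least ``min_size`` members, largest first.

    Ties in size break on the lexicographically smallest member.
    """
    kept = [c for c in partition.clusters if len(c) >= min_size]
    return sorted(kept, key=lambda c: (-len(c), min(c)))
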