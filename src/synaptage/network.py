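"""Pearson co-expression graph construction and Markov clustering (MCL).

Filtered proteins become nodes of an undirected graph; an edge joins two
proteins when the Pearson correlation of their sample-expression vectors
reaches the threshold (default r >= 0.95, positive correlations only —
profiles moving together). The graph is then clustered with the Markov
Cluster algorithm: the edge-weight matrix with self-loops is made
column-stochastic and alternately expanded (matrix power, simulating flow)
and inflated (elementwise power plus column renormalization, sharpening
flow) until the process converges onto attractor components, which are read
out as clusters.

The MCL iteration is implemented here from first principles (dense numpy);
the graph container is a :class:`networkx.Graph`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .tables import AbundanceTable


def build_graph(
    table: AbundanceTable,
    proteins=None,
    r_threshold: float = 0.95,
    region: str | None = None,
    use_absolute: bool = False,
) -> nx.Graph:
    """Threshold the all-pairs Pearson correlation matrix into a graph.

    Expression vectors take all samples of the requested region (or all
    regions), ordered young -> mid -> old. Proteins with constant vectors
    have undefined correlation and are excluded with a warning. By default
    only r >= r_threshold creates an edge; ``use_absolute`` also links
    strong anticorrelations.
    """
    if not 0 < r_threshold <= 1:
        raise ValueError("r_threshold must be in (0, 1]")
    proteins = list(proteins) if proteins is not None else table.protein_ids
    regions = [region] if region is not None else table.regions
    cols: list[str] = []
    for age in table.age_order:
        for r in regions:
            cols.extend(table.sample_ids(r, age))
    mat = table.values.loc[proteins, cols].to_numpy(dtype=float)
    if mat.shape[1] < 3:
        raise ValueError("need at least 3 sample values per protein")
    sd = mat.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"excluding {int(constant.sum())} constant-expression protein(s) "
            f"(undefined correlation): {[p for p, c in zip(proteins, constant) if c][:5]}",
            stacklevel=2,
        )
    keep = [p for p, c in zip(proteins, constant) if not c]
    graph = nx.Graph(r_threshold=r_threshold)
    graph.add_nodes_from(keep)
    if len(keep) >= 2:
        corr = np.corrcoef(mat[~constant])
        score = np.abs(corr) if use_absolute else corr
        ii, jj = np.where(np.triu(score >= r_threshold, k=1))
        for i, j in zip(ii, jj):
            graph.add_edge(keep[i], keep[j], weight=float(corr[i, j]))
    return graph


@dataclass(frozen=True)
class MclParams:
    """MCL control parameters. Inflation (default 2.2) sets cluster granularity."""

    inflation: float = 2.2
    expansion: int = 2
    max_iterations: int = 200
    convergence_tol: float = 1e-8
    prune_threshold: float = 1e-7

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")


@dataclass
class ClusterSet:
    """Disjoint clusters sorted by descending size (ties: smallest member id)."""

    clusters: list[list[str]]
    converged: bool
    n_iterations: int

    def __post_init__(self) -> None:
        self.clusters = [sorted(c) for c in self.clusters]
        self.clusters.sort(key=lambda c: (-len(c), c[0]))

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def singletons(self) -> list[list[str]]:
        return [c for c in self.clusters if len(c) == 1]

    @property
    def non_singletons(self) -> list[list[str]]:
        return [c for c in self.clusters if len(c) > 1]

    def membership(self) -> dict[str, int]:
        return {p: i for i, c in enumerate(self.clusters) for p in c}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (p, i, len(c)) for i, c in enumerate(self.clusters) for p in c
        ]
        return pd.DataFrame(rows, columns=["protein_id", "cluster_id", "cluster_size"]).set_index(
            "protein_id"
        )


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    s = m.sum(axis=0)
    s[s == 0] = 1.0
    return m / s


def mcl_iterate(matrix: np.ndarray, params: MclParams):
    """Run the expansion/inflation loop on a column-stochastic matrix.

    Yields the matrix after each full iteration (already pruned and
    renormalized), so callers can verify column-stochasticity; iteration
    stops at convergence or max_iterations.
    """
    m = matrix
    for _ in range(params.max_iterations):
        expanded = np.linalg.matrix_power(m, params.expansion)
        inflated = _normalize_columns(np.power(expanded, params.inflation))
        inflated[inflated < params.prune_threshold] = 0.0
        inflated = _normalize_columns(inflated)
        change = float(np.abs(inflated - m).max())
        m = inflated
        yield m
        if change < params.convergence_tol:
            return


def mcl_cluster(graph: nx.Graph, params: MclParams = MclParams()) -> ClusterSet:
    """Cluster a weighted graph with the Markov Cluster algorithm.

    Self-loops are added with weight equal to each node's maximum incident
    edge weight (1.0 for isolated nodes) before column normalization.
    Clusters are read from the converged matrix as attractor systems; every
    node is assigned to the attractor holding its largest steady-state mass,
    ties going to the attractor system with the smallest member. Deterministic
    for fixed parameters; if the loop hits max_iterations the current
    interpretation is returned with ``converged=False``.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = w
    loop = adj.max(axis=1)
    loop[loop == 0] = 1.0
    adj[np.diag_indices(n)] = loop
    m = _normalize_columns(adj)

    n_iter, converged = 0, False
    prev = m
    for m in mcl_iterate(prev, params):
        n_iter += 1
        if np.abs(m - prev).max() < params.convergence_tol:
            converged = True
        prev = m
    final = prev

    tau = max(params.prune_threshold, 1e-9)
    attractors = [i for i in range(n) if final[i, i] > tau]
    if not attractors:  # pathological; treat max-mass rows as attractors
        attractors = list(np.unique(final.argmax(axis=0)))
    # attractor systems: attractors sharing support belong to one cluster
    parent = {a: a for a in attractors}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in attractors:
        for b in attractors:
            if a < b and (final[a, b] > tau or final[b, a] > tau):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    att_rows = final[attractors, :]
    assignment = {}
    for j in range(n):
        col = att_rows[:, j]
        if col.max() <= 0:
            assignment[j] = None  # unattached: its own singleton
        else:
            assignment[j] = find(attractors[int(col.argmax())])
    groups: dict = {}
    for j, root in assignment.items():
        key = root if root is not None else ("singleton", j)
        groups.setdefault(key, []).append(nodes[j])
    return ClusterSet(clusters=list(groups.values()), converged=converged, n_iterations=n_iter)


def write_edgelist(graph: nx.Graph, path) -> None:
    """Edge list TSV: protein_a, protein_b, r."""
    rows = [(u, v, d.get("weight", 1.0)) for u, v, d in graph.edges(data=True)]
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "r"]).to_csv(path, sep="\t", index=False)


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
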