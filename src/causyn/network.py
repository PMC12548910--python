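"""Cell-line-specific PPI subnetwork construction.

Each cell line's target proteins are used as seed nodes in the global PPI
graph. A connected subgraph containing the seeds is grown greedily along
shortest paths: every seed starts as its own fragment, and the two fragments
joined by the globally shortest inter-fragment path are merged repeatedly
(adding that path's intermediate nodes and edges) until a single fragment
remains. This approximates the minimum-edge Steiner subgraph; for unit
weights the result is a tree whose edge count lies between the Steiner
optimum and the sum of pairwise seed distances.

Determinism: ties among equal-length candidate paths are broken
lexicographically on (sorted endpoint pair, path node sequence), and all
graph traversals use sorted adjacency, so identical inputs always produce
identical node orders and edge sets.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .io import CellLineProfile, PPINetwork

logger = logging.getLogger(__name__)

__all__ = [
    "SpecificNetwork",
    "ExpressionGraph",
    "shortest_paths_from",
    "build_specific_network",
    "induced_expression_graph",
]


@dataclass
class SpecificNetwork:
    """A cell line's specific topology: ordered nodes + undirected edges."""

    nodes: list[str]
    edges: set[tuple[str, str]] = field(default_factory=set)
    cell_line_id: str | None = None
    seeds: set[str] = field(default_factory=set)

    @property
    def adjacency(self) -> np.ndarray:
        """Binary adjacency Asp over the node order."""
        index = {n: i for i, n in enumerate(self.nodes)}
        A = np.zeros((len(self.nodes), len(self.nodes)))
        for u, v in self.edges:
            A[index[u], index[v]] = A[index[v], index[u]] = 1.0
        return A


@dataclass
class ExpressionGraph:
    """Node-feature column vector Ce (Gn x 1) on the specific topology."""

    nodes: list[str]
    adjacency: np.ndarray
    features: np.ndarray  # Gn x 1
    cell_line_id: str | None = None


def _sorted_adjacency(network: PPINetwork) -> dict[str, list[str]]:
    adj: dict[str, list[str]] = {n: [] for n in network.nodes}
    for u, v in network.edges:
        adj[u].append(v)
        adj[v].append(u)
    return {n: sorted(nbrs) for n, nbrs in sorted(adj.items())}


def _bfs_dist(adj: dict[str, list[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _lex_shortest_path(
    adj: dict[str, list[str]],
    dist_u: dict[str, int],
    dist_v: dict[str, int],
    u: str,
    v: str,
) -> list[str]:
    """Lexicographically smallest minimum-hop path u -> v.

    A node x lies on some shortest u-v path iff dist_u[x] + dist_v[x] equals
    the u-v distance; walking forward and always taking the smallest eligible
    neighbor yields the lexicographically smallest node sequence.
    """
    total = dist_u[v]
    path = [u]
    current = u
    while current != v:
        step = dist_u[current] + 1
        nxt = min(
            n
            for n in adj[current]
            if dist_u.get(n) == step and n in dist_v and step + dist_v[n] == total
        )
        path.append(nxt)
        current = nxt
    return path


def shortest_paths_from(
    network: PPINetwork, source: str
) -> dict[str, tuple[list[str], int]]:
    """Minimum-hop paths from ``source`` to every reachable node.

    Returns ``{target: (path, hop_count)}`` including the trivial
    ``source -> source`` entry; unreachable nodes are absent. Unit edge
    weights, so Dijkstra reduces to breadth-first search; paths are the
    lexicographically smallest among the shortest.
    """
    if source not in network.nodes:
        raise ValueError(f"source {source!r} not in network")
    adj = _sorted_adjacency(network)
    dist = _bfs_dist(adj, source)
    out: dict[str, tuple[list[str], int]] = {}
    for target, d in dist.items():
        dist_t = _bfs_dist(adj, target)
        out[target] = (_lex_shortest_path(adj, dist, dist_t, source, target), d)
    return out


def build_specific_network(
    network: PPINetwork,
    seeds: set[str],
    cell_line_id: str | None = None,
    induced_edges: bool = False,
) -> SpecificNetwork:
    """Grow a connected seed-covering subgraph with near-minimal edge count.

    Seeds absent from the network are dropped with a warning. If the seeds
    span several global components, only the component holding the most seeds
    is kept (ties: the component containing the smallest seed id); seeds in
    dropped components are discarded, mirroring isolated-node removal.

    With ``induced_edges=True`` the full induced subgraph on the selected
    nodes is returned instead of only the path edges (ablation variant that
    keeps the raw PPI edges among selected nodes).
    """
    if not seeds:
        raise ValueError("seed set is empty")
    known = sorted(s for s in seeds if s in network.nodes)
    missing = sorted(set(seeds) - set(known))
    if missing:
        logger.warning("dropping %d seeds absent from network: %s", len(missing), missing)
    if not known:
        raise ValueError("no seeds present in the network")

    adj = _sorted_adjacency(network)

    # group seeds by global connected component
    comp_of: dict[str, int] = {}
    comp_id = 0
    for s in known:
        if s in comp_of:
            continue
        for node in _bfs_dist(adj, s):
            comp_of.setdefault(node, comp_id)
        comp_id += 1
    groups: dict[int, list[str]] = {}
    for s in known:
        groups.setdefault(comp_of[s], []).append(s)
    kept = max(sorted(groups.values(), key=lambda g: min(g)), key=len)
    if len(kept) < len(known):
        logger.warning(
            "seeds span %d components; keeping %d of %d seeds",
            len(groups), len(kept), len(known),
        )

    kept = sorted(kept)
    nodes: list[str] = list(kept)
    edges: set[tuple[str, str]] = set()
    fragments: list[set[str]] = [{s} for s in kept]
    dist_cache: dict[str, dict[str, int]] = {}

    def dist_from(n: str) -> dict[str, int]:
        if n not in dist_cache:
            dist_cache[n] = _bfs_dist(adj, n)
        return dist_cache[n]

    while len(fragments) > 1:
        best: tuple[int, tuple[str, str], list[str], int, int] | None = None
        for i in range(len(fragments)):
            for u in sorted(fragments[i]):
                du = dist_from(u)
                for j in range(i + 1, len(fragments)):
                    for v in sorted(fragments[j]):
                        if v not in du:
                            continue
                        d = du[v]
                        key = (u, v) if u <= v else (v, u)
                        if best is not None and (d, key) >= best[:2]:
                            continue
                        path = _lex_shortest_path(adj, du, dist_from(v), u, v)
                        cand = (d, key, path, i, j)
                        if best is None or cand[:3] < best[:3]:
                            best = cand
        if best is None:
            break  # remaining fragments mutually unreachable (cannot happen after grouping)
        _, _, path, i, j = best
        for n in path:
            if n not in nodes:
                nodes.append(n)
        for a, b in zip(path[:-1], path[1:]):
            edges.add((a, b) if a <= b else (b, a))
        fragments[i] |= fragments[j] | set(path)
        del fragments[j]

    if induced_edges:
        node_set = set(nodes)
        for u in nodes:
            for v in adj[u]:
                if v in node_set:
                    edges.add((u, v) if u <= v else (v, u))

    return SpecificNetwork(
        nodes=nodes, edges=edges, cell_line_id=cell_line_id, seeds=set(kept)
    )


def induced_expression_graph(
    specific: SpecificNetwork, profile: CellLineProfile
) -> ExpressionGraph:
    """Attach the profile's expression values to the specific topology.

    The feature vector Ce (Gn x 1) follows the network's node order exactly;
    a node without an expression value is an error naming the gene.
    """
    values = []
    for gene in specific.nodes:
        if gene not in profile.expression:
            raise ValueError(
                f"profile {profile.cell_line_id!r} has no expression for gene {gene!r}"
            )
        values.append(profile.expression[gene])
    return ExpressionGraph(
        nodes=list(specific.nodes),
        adjacency=specific.adjacency,
        features=np.asarray(values, dtype=float).reshape(-1, 1),
        cell_line_id=profile.cell_line_id,
    )
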