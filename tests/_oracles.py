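"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the library's own algorithms: d-separation is decided
by exhaustively enumerating every undirected simple path and applying the
blocking rules; small least-squares systems are solved directly from the
normal equations.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def enumerate_paths_d_separated(graph: nx.DiGraph, a: str, b: str, given: set) -> bool:
    """d-separation by exhaustive path enumeration.

    A path is blocked iff some interior node is (i) a collider whose
    descendants (including itself) avoid the conditioning set, or (ii) a
    non-collider inside the conditioning set.  a and b are d-separated iff
    every undirected simple path between them is blocked.
    """
    undirected = graph.to_undirected()
    desc_cache = {n: nx.descendants(graph, n) | {n} for n in graph.nodes}
    for path in nx.all_simple_paths(undirected, a, b):
        blocked = False
        for i in range(1, len(path) - 1):
            prev, node, nxt = path[i - 1], path[i], path[i + 1]
            is_collider = graph.has_edge(prev, node) and graph.has_edge(nxt, node)
            if is_collider:
                if not (desc_cache[node] & given):
                    blocked = True
                    break
            else:
                if node in given:
                    blocked = True
                    break
        if not blocked:
            return False
    return True


def random_dag(rng: np.random.Generator, max_nodes: int = 6) -> nx.DiGraph:
    """A random DAG on 2..max_nodes nodes with edges along a random order."""
    n = int(rng.integers(2, max_nodes + 1))
    names = [f"v{i}" for i in range(n)]
    order = rng.permutation(n)
    g = nx.DiGraph()
    g.add_nodes_from(names)
    p = rng.uniform(0.2, 0.6)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(names[order[i]], names[order[j]])
    return g


def all_d_separation_queries(graph: nx.DiGraph):
    """Yield every (a, b, conditioning subset) query for a small graph."""
    nodes = sorted(graph.nodes)
    for a, b in itertools.combinations(nodes, 2):
        others = [n for n in nodes if n not in (a, b)]
        for r in range(len(others) + 1):
            for sub in itertools.combinations(others, r):
                yield a, b, set(sub)


def normal_equations_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Solve OLS directly from the normal equations (X'X) beta = X'y."""
    return np.linalg.solve(X.T @ X, X.T @ y)
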