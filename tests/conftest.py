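"""Shared fixtures and brute-force graph oracles.

The oracles here deliberately re-derive d-separation and the back-door
criterion by exhaustive path enumeration, independently of the library's
implementation, so the two routes can be compared on small random DAGs.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from causalinfo import ChainGraph, fixture, random_model


# -- path-enumeration oracles ----------------------------------------------

def _all_paths(dag: nx.DiGraph, a: str, b: str):
    """All simple paths between a and b in the skeleton, as node sequences."""
    skel = dag.to_undirected(as_view=False)
    return nx.all_simple_paths(skel, a, b)


def _is_collider(dag: nx.DiGraph, u: str, w: str, v: str) -> bool:
    return dag.has_edge(u, w) and dag.has_edge(v, w)


def _path_blocked(dag: nx.DiGraph, path, Z: set) -> bool:
    """Standard blocking: some non-collider on the path is in Z, or some
    collider has neither itself nor any descendant in Z."""
    for k in range(1, len(path) - 1):
        u, w, v = path[k - 1], path[k], path[k + 1]
        if _is_collider(dag, u, w, v):
            if w not in Z and not (nx.descendants(dag, w) & Z):
                return True
        elif w in Z:
            return True
    return False


def dsep_oracle(dag: nx.DiGraph, A, B, Z) -> bool:
    Z = set(Z)
    for a, b in itertools.product(A, B):
        for path in _all_paths(dag, a, b):
            if not _path_blocked(dag, path, Z):
                return False
    return True


def backdoor_oracle(dag: nx.DiGraph, X, Y, Z) -> bool:
    """Literal per-path reading: no Z-node descends from X, and every path
    between x and y whose first edge points into x is blocked."""
    Z = set(Z)
    for x in X:
        if nx.descendants(dag, x) & Z:
            return False
    for x, y in itertools.product(X, Y):
        for path in _all_paths(dag, x, y):
            if len(path) >= 2 and dag.has_edge(path[1], path[0]):
                if not _path_blocked(dag, path, Z):
                    return False
    return True


def random_dag(seed: int, n_nodes: int, p: float = 0.45) -> ChainGraph:
    """Seeded random DAG over n0..n{k-1} with forward edges of density p."""
    rng = np.random.default_rng(seed)
    names = [f"n{i}" for i in range(n_nodes)]
    edges = [
        (names[i], names[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < p
    ]
    return ChainGraph(names, edges)


def random_binary_model(seed: int, n_nodes: int, p: float = 0.45):
    g = random_dag(seed, n_nodes, p)
    return random_model(g, {v: (0, 1) for v in g.nodes}, seed=seed,
                        numeric=g.nodes)


# -- model fixtures ---------------------------------------------------------

@pytest.fixture(scope="session")
def two_node():
    return fixture("two_node")


@pytest.fixture(scope="session")
def triangle():
    return fixture("triangle")


@pytest.fixture(scope="session")
def collider():
    return fixture("collider")


@pytest.fixture(scope="session")
def fig2():
    return fixture("fig2_style")
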