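"""Chain graphs, DAGs, d-separation, and the back-door criterion.

A chain graph is a mixed graph with directed and undirected edges in which
no semi-directed cycle (a cycle traversing directed edges forward and
undirected edges either way, using at least one directed edge) exists.  The
maximal connected sets of the undirected skeleton are the *chain
components*; a DAG is the special case in which every chain component is a
singleton.  Components admit a topological order in which every directed
edge points from an earlier to a later component, which is the order used
for factorisation and sampling.
"""

from __future__ import annotations

import itertools
from typing import Iterable

import networkx as nx

from .errors import GraphStructureError, InputError

__all__ = [
    "ChainGraph",
    "d_separated",
    "satisfies_backdoor",
    "enumerate_backdoor_sets",
    "to_dot",
]


def _as_nodeset(g: "ChainGraph", X, what: str = "node set") -> frozenset:
    if isinstance(X, str):
        X = (X,)
    X = frozenset(X)
    unknown = X - set(g.nodes)
    if unknown:
        raise InputError(f"{what} contains unknown node(s): {sorted(unknown)}")
    return X


def _require_disjoint(*sets) -> None:
    for (na, a), (nb, b) in itertools.combinations(sets, 2):
        common = a & b
        if common:
            raise InputError(f"{na} and {nb} overlap on {sorted(common)}")


class ChainGraph:
    """Validated chain graph over named nodes.

    Parameters
    ----------
    nodes
        Ordered iterable of node names; the order fixes axis and output
        ordering everywhere downstream.
    directed_edges
        Iterable of ``(tail, head)`` pairs.
    undirected_edges
        Iterable of unordered pairs.

    Raises
    ------
    InputError
        If an edge endpoint is not a declared node.
    GraphStructureError
        On self-loops, conflicting edges, or (semi-)directed cycles; the
        exception's ``cycle`` attribute names one offending cycle.
    """

    def __init__(self, nodes: Iterable[str], directed_edges=(), undirected_edges=()):
        self._nodes = tuple(dict.fromkeys(nodes))
        self._index = {v: i for i, v in enumerate(self._nodes)}
        de, ue = set(), set()
        for u, v in directed_edges:
            self._check_endpoint(u), self._check_endpoint(v)
            if u == v:
                raise GraphStructureError(f"self-loop on {u!r}", cycle=(u, u))
            de.add((u, v))
        for u, v in undirected_edges:
            self._check_endpoint(u), self._check_endpoint(v)
            if u == v:
                raise GraphStructureError(f"self-loop on {u!r}", cycle=(u, u))
            ue.add(frozenset((u, v)))
        for u, v in de:
            if (v, u) in de:
                raise GraphStructureError(
                    f"directed cycle {u!r} -> {v!r} -> {u!r}", cycle=(u, v, u)
                )
            if frozenset((u, v)) in ue:
                raise GraphStructureError(
                    f"pair ({u!r}, {v!r}) has both a directed and an undirected edge",
                    cycle=(u, v),
                )
        self._directed = frozenset(de)
        self._undirected = frozenset(ue)
        self._components, self._component_of = self._validate_and_order()

    def _check_endpoint(self, v):
        if v not in self._index:
            raise InputError(f"edge endpoint {v!r} is not a declared node")

    def _validate_and_order(self):
        skel = nx.Graph()
        skel.add_nodes_from(self._nodes)
        skel.add_edges_from(tuple(e) for e in self._undirected)
        comps = [
            tuple(sorted(c, key=self._index.__getitem__))
            for c in nx.connected_components(skel)
        ]
        comp_of = {v: i for i, c in enumerate(comps) for v in c}
        cdag = nx.DiGraph()
        cdag.add_nodes_from(range(len(comps)))
        for u, v in self._directed:
            cu, cv = comp_of[u], comp_of[v]
            if cu == cv:
                raise GraphStructureError(
                    f"semi-directed cycle: directed edge {u!r} -> {v!r} inside an "
                    f"undirected component {comps[cu]}",
                    cycle=(u, v),
                )
            cdag.add_edge(cu, cv)
        try:
            order = list(nx.lexicographical_topological_sort(cdag))
        except nx.NetworkXUnfeasible:
            cyc = nx.find_cycle(cdag)
            names = [comps[c][0] for c, _ in cyc] + [comps[cyc[0][0]][0]]
            raise GraphStructureError(
                f"semi-directed cycle through {names}", cycle=names
            ) from None
        ordered = tuple(comps[i] for i in order)
        comp_index = {members: k for k, members in enumerate(ordered)}
        comp_of_node = {v: comp_index[c] for c in ordered for v in c}
        return ordered, comp_of_node

    # -- basic structure ---------------------------------------------------
    @property
    def nodes(self) -> tuple:
        return self._nodes

    @property
    def directed_edges(self) -> frozenset:
        return self._directed

    @property
    def undirected_edges(self) -> frozenset:
        return self._undirected

    @property
    def is_dag(self) -> bool:
        return not self._undirected

    @property
    def chain_components(self) -> tuple:
        """Partition of the nodes into chain components, topologically ordered."""
        return self._components

    def component_of(self, node: str) -> tuple:
        self._check_endpoint(node)
        return self._components[self._component_of[node]]

    def node_order(self, nodes) -> tuple:
        """Return ``nodes`` sorted into declaration order."""
        return tuple(sorted(_as_nodeset(self, nodes), key=self._index.__getitem__))

    # -- kinship -----------------------------------------------------------
    def parents(self, X) -> frozenset:
        """Union of directed-edge parents of the members of ``X``, minus X."""
        X = _as_nodeset(self, X)
        return frozenset(u for (u, v) in self._directed if v in X) - X

    def component_parents(self, component) -> tuple:
        """pa(tau): parents of a chain component, in declaration order."""
        return self.node_order(self.parents(component))

    def children(self, X) -> frozenset:
        X = _as_nodeset(self, X)
        return frozenset(v for (u, v) in self._directed if u in X) - X

    def descendants(self, X, strict: bool = True) -> frozenset:
        """Nodes reachable from ``X`` along directed edges.

        On a chain graph, reachability is taken at component level: entering
        a chain component reaches all of its members (they are generated
        jointly).  Members of X's own components are not descendants.
        ``strict=False`` additionally includes ``X`` itself.
        """
        X = _as_nodeset(self, X)
        cdag = nx.DiGraph()
        cdag.add_nodes_from(range(len(self._components)))
        for u, v in self._directed:
            cdag.add_edge(self._component_of[u], self._component_of[v])
        start = {self._component_of[x] for x in X}
        reach = set()
        for c in start:
            reach |= nx.descendants(cdag, c)
        reach -= start
        out = frozenset(v for c in reach for v in self._components[c])
        return out | X if not strict else out - X

    def digraph(self) -> nx.DiGraph:
        """The directed part as a networkx DiGraph (all nodes included)."""
        d = nx.DiGraph()
        d.add_nodes_from(self._nodes)
        d.add_edges_from(self._directed)
        return d


# -- d-separation and the back-door criterion ------------------------------

def _require_dag(g: ChainGraph, op: str):
    if not g.is_dag:
        raise InputError(f"{op} requires a DAG; this graph has undirected edges")


def d_separated(g: ChainGraph, A, B, Z=()) -> bool:
    """True iff ``Z`` d-separates ``A`` from ``B`` in the DAG ``g``.

    Standard d-separation: every path between A and B is blocked by Z.
    Symmetric in A and B. Empty A or B is vacuously separated.
    """
    _require_dag(g, "d-separation")
    A, B, Z = (_as_nodeset(g, s, n) for s, n in ((A, "A"), (B, "B"), (Z, "Z")))
    _require_disjoint(("A", A), ("B", B), ("Z", Z))
    if not A or not B:
        return True
    return nx.is_d_separator(g.digraph(), set(A), set(B), set(Z))


def satisfies_backdoor(g: ChainGraph, X, Y, Z=()) -> bool:
    """Back-door criterion for ``Z`` relative to the ordered pair ``(X, Y)``.

    Two conditions: (1) no node of Z is a descendant of (any member of) X;
    (2) Z blocks every path between X and Y that contains an arrow into X.
    Condition 2 is evaluated pairwise over (x, y) via the standard
    equivalence: d-separation of x and y given Z in the graph with the
    outgoing edges of x removed.
    """
    _require_dag(g, "back-door criterion")
    X, Y, Z = (_as_nodeset(g, s, n) for s, n in ((X, "X"), (Y, "Y"), (Z, "Z")))
    _require_disjoint(("X", X), ("Y", Y), ("Z", Z))
    if Z & g.descendants(X):
        return False
    base = g.digraph()
    for x in X:
        pruned = base.copy()
        pruned.remove_edges_from(list(pruned.out_edges(x)))
        for y in Y:
            if not nx.is_d_separator(pruned, {x}, {y}, set(Z)):
                return False
    return True


def enumerate_backdoor_sets(g: ChainGraph, X, Y, max_size: int) -> list:
    """All back-door sets for (X, Y) up to ``max_size``.

    Candidates are subsets of the non-descendants of X excluding X and Y,
    returned ordered by size and then lexicographically by node name.
    """
    if max_size < 0:
        raise InputError("max_size must be >= 0")
    X = _as_nodeset(g, X, "X")
    Y = _as_nodeset(g, Y, "Y")
    pool = sorted(set(g.nodes) - g.descendants(X) - X - Y)
    out = []
    for k in range(min(max_size, len(pool)) + 1):
        for combo in itertools.combinations(pool, k):
            if satisfies_backdoor(g, X, Y, combo):
                out.append(frozenset(combo))
    return out


# -- export ----------------------------------------------------------------

def to_dot(g: ChainGraph, name: str = "G") -> str:
    """Graphviz DOT rendering: ``->`` for directed edges, ``--`` for
    undirected ones, with non-singleton chain components as clusters."""
    lines = [f"digraph {name} {{"]
    for k, comp in enumerate(g.chain_components):
        if len(comp) > 1:
            lines.append(f'  subgraph cluster_{k} {{ label="component {k}";')
            lines.extend(f'    "{v}";' for v in comp)
            lines.append("  }")
        else:
            lines.append(f'  "{comp[0]}";')
    for u, v in sorted(g.directed_edges):
        lines.append(f'  "{u}" -> "{v}";')
    for e in sorted(map(sorted, g.undirected_edges)):
        lines.append(f'  "{e[0]}" -> "{e[1]}" [dir=none, style=solid];')
    lines.append("}")
    return "\n".join(lines) + "\n"
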