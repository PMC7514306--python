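"""Canonical time-series graphs and closed-form directed-information sums.

Two competing time-series definitions of directed information exist in the
literature, differing in whether the instantaneous ("present") sample of
the source series is conditioned on:

* with the present:      I(X^n -> Y^n) = sum_i I(X^i ; Y_i | Y^{i-1})
* without the present:   I(X^n -> Y^n) = sum_i I(X^{i-1} ; Y_i | Y^{i-1})

Both are special cases of the general interventional definition evaluated
on different graphs.  ``g1`` is the fully time-ordered DAG (2n nodes in a
total order, every forward arrow), where the general definition reduces to
the first (Massey) sum.  ``g2`` aligns the two series at shared time
points with all strictly-forward arrows and no instantaneous ones, giving
the second sum; ``g2z`` adds a third, confounding series.  ``h1`` models
instantaneous coupling explicitly as a chain graph: ``g2`` plus an
undirected edge inside every pair {X_i, Y_i}, which then forms a chain
component; the general chain-graph definition again yields the
no-present sum.  ``bidirectional`` is the noisy-copy counterexample graph
(arrows X_{i-1} -> Y_i and Y_{i-1} -> X_i only), on which transfer entropy
vanishes in the deterministic-copy limit even though X directly drives Y
-- the reason transfer entropy must be read as a no-confounding statistic,
not an effect size.

Nodes are named ``X.1 .. X.n``, ``Y.1 .. Y.n`` (and ``Z.1 .. Z.n``) so the
closed forms can locate the series programmatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import resolve_base
from .errors import InputError
from .graphs import ChainGraph
from .measures import InfoValue, mutual_information
from .models import ComponentTable, DiscreteModel, JointTable, joint_table, random_model

__all__ = [
    "KINDS",
    "CanonicalSpec",
    "build_canonical",
    "di_full_ordering",
    "di_partial_ordering",
    "di_chain_graph",
    "massey_di",
    "transfer_entropy",
]

KINDS = ("g1", "g2", "g2z", "h1", "h1z", "bidirectional")
_BINARY = (0, 1)


@dataclass
class CanonicalSpec:
    """Recipe for a canonical time-series model.

    ``epsilon`` applies to the ``bidirectional`` kind only: if set, all
    arrows are binary symmetric noisy copies with flip probability epsilon
    (initial states uniform); if None, conditional rows are drawn
    Dirichlet(1) from ``seed``, as for every other kind.
    """

    kind: str
    n: int
    seed: int = 0
    epsilon: Optional[float] = None
    domains: Optional[dict] = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise InputError(f"unknown canonical kind {self.kind!r}; one of {KINDS}")
        if self.n < 1:
            raise InputError("n must be >= 1")
        if self.epsilon is not None:
            if self.kind != "bidirectional":
                raise InputError("epsilon applies to the bidirectional kind only")
            if not 0.0 <= self.epsilon <= 1.0:
                raise InputError("epsilon must lie in [0, 1]")


def _name(series: str, i: int) -> str:
    return f"{series}.{i}"


def _hist(series: str, upto: int) -> list:
    """X^upto = [X.1, ..., X.upto]; empty when upto < 1."""
    return [_name(series, k) for k in range(1, upto + 1)]


def _series_nodes(n: int, series: str) -> list:
    # interleaved by time so the node order is a topological order
    return [_name(s, i) for i in range(1, n + 1) for s in series]


def build_canonical(spec: CanonicalSpec) -> DiscreteModel:
    """Construct the canonical model for ``spec``; the result carries
    ``meta['kind']`` and ``meta['n']`` so the closed forms can check they
    are applied to the graph they were derived for."""
    n, kind = spec.n, spec.kind
    series = "XYZ" if kind in ("g2z", "h1z") else "XY"
    nodes = _series_nodes(n, series)
    domains = dict(spec.domains or {})
    for v in nodes:
        domains.setdefault(v, _BINARY)

    def t(v):  # time index of a node
        return int(v.split(".")[1])

    directed, undirected = [], []
    if kind == "g1":
        # total order X.1 < Y.1 < X.2 < Y.2 < ...; every forward arrow
        for i, u in enumerate(nodes):
            directed.extend((u, v) for v in nodes[i + 1:])
    elif kind == "bidirectional":
        for i in range(2, n + 1):
            directed.append((_name("X", i - 1), _name("Y", i)))
            directed.append((_name("Y", i - 1), _name("X", i)))
    else:  # g2 / g2z / h1 / h1z: all strictly forward arrows, none at equal times
        # the conditioning series Z is an exogenous confounder: it feeds X
        # and Y but receives arrows only from its own past
        directed = [
            (u, v) for u in nodes for v in nodes
            if t(u) < t(v) and not (v.startswith("Z") and not u.startswith("Z"))
        ]
        if kind in ("h1", "h1z"):
            undirected = [(_name("X", i), _name("Y", i)) for i in range(1, n + 1)]

    g = ChainGraph(nodes, directed, undirected)
    if spec.epsilon is not None:
        m = _noisy_copy_model(g, domains, spec.epsilon)
    else:
        m = random_model(g, domains, seed=spec.seed, alpha=1.0)
    m.meta.update(kind=kind, n=n, epsilon=spec.epsilon, seed=spec.seed)
    return m


def _noisy_copy_model(g: ChainGraph, domains, eps: float) -> DiscreteModel:
    """Binary symmetric channels: each node copies its single parent and
    flips with probability eps; initial nodes are uniform."""
    tables = []
    for comp in g.chain_components:
        (v,) = comp
        parents = g.component_parents(comp)
        if not parents:
            tables.append(ComponentTable(comp, (), np.array([0.5, 0.5])))
        else:
            (p,) = parents
            tables.append(ComponentTable(
                comp, parents, np.array([[1 - eps, eps], [eps, 1 - eps]])
            ))
    return DiscreteModel(g, domains, tables)


# -- closed-form sums -------------------------------------------------------

def _require_kind(m: DiscreteModel, allowed, op: str) -> int:
    kind = m.meta.get("kind")
    if kind not in allowed:
        raise InputError(f"{op} applies to canonical kind(s) {allowed}, got {kind!r}")
    return int(m.meta["n"])


def _sum_terms(t: JointTable, terms, base) -> InfoValue:
    base = resolve_base(base)
    total = 0.0
    for A, B, Z in terms:
        total += mutual_information(t, A, B, Z, base=base).value
    return InfoValue(total, base)


def di_full_ordering(m: DiscreteModel, direction: str = "forward",
                     base: str | None = None) -> InfoValue:
    """Directed information on the fully ordered DAG ``g1``.

    forward:  sum_i I(X^i ; Y_i | Y^{i-1})   (present included)
    reverse:  sum_i I(Y^{i-1} ; X_i | X^{i-1})
    Terms with an empty argument set are 0; empty conditioning sets are
    unconditional.
    """
    n = _require_kind(m, ("g1",), "di_full_ordering")
    t = joint_table(m)
    if direction == "forward":
        terms = [(_hist("X", i), [_name("Y", i)], _hist("Y", i - 1))
                 for i in range(1, n + 1)]
    elif direction == "reverse":
        terms = [(_hist("Y", i - 1), [_name("X", i)], _hist("X", i - 1))
                 for i in range(1, n + 1)]
    else:
        raise InputError("direction must be 'forward' or 'reverse'")
    return _sum_terms(t, terms, base)


def di_partial_ordering(m: DiscreteModel, conditional: bool = False,
                        base: str | None = None) -> InfoValue:
    """Directed information on the aligned-series DAG ``g2``:
    sum_i I(X^{i-1} ; Y_i | Y^{i-1}), i.e. without the present sample.
    With ``conditional=True`` (requires the ``g2z`` kind) each conditioning
    set gains Z^{i-1}."""
    allowed = ("g2z",) if conditional else ("g2", "g2z")
    n = _require_kind(m, allowed, "di_partial_ordering")
    t = joint_table(m)
    terms = [
        (_hist("X", i - 1), [_name("Y", i)],
         _hist("Y", i - 1) + (_hist("Z", i - 1) if conditional else []))
        for i in range(1, n + 1)
    ]
    return _sum_terms(t, terms, base)


def di_chain_graph(m: DiscreteModel, conditional: bool = False,
                   base: str | None = None) -> InfoValue:
    """Directed information on the chain graph ``h1`` (aligned series with
    undirected instantaneous edges): the same no-present sum as ``g2``,
    evaluated on the chain-graph joint."""
    allowed = ("h1z",) if conditional else ("h1", "h1z")
    n = _require_kind(m, allowed, "di_chain_graph")
    t = joint_table(m)
    terms = [
        (_hist("X", i - 1), [_name("Y", i)],
         _hist("Y", i - 1) + (_hist("Z", i - 1) if conditional else []))
        for i in range(1, n + 1)
    ]
    return _sum_terms(t, terms, base)


def massey_di(t: JointTable, n: int, base: str | None = None) -> InfoValue:
    """The with-present sum  sum_i I(X^i ; Y_i | Y^{i-1})  evaluated on any
    joint table over aligned series X.1..X.n, Y.1..Y.n."""
    _check_series(t, n)
    terms = [(_hist("X", i), [_name("Y", i)], _hist("Y", i - 1))
             for i in range(1, n + 1)]
    return _sum_terms(t, terms, base)


def transfer_entropy(t: JointTable, n: int, base: str | None = None) -> InfoValue:
    """Transfer entropy I(X^{n-1} ; Y_n | Y^{n-1}): the single last term of
    the no-present sum."""
    if n < 2:
        raise InputError("transfer entropy needs n >= 2")
    _check_series(t, n)
    return mutual_information(t, _hist("X", n - 1), [_name("Y", n)],
                              _hist("Y", n - 1), base=base)


def _check_series(t: JointTable, n: int):
    need = set(_hist("X", n)) | set(_hist("Y", n))
    missing = need - set(t.variables)
    if missing:
        raise InputError(
            f"table lacks series variable(s) {sorted(missing)}; expected "
            f"nodes named X.1..X.{n} and Y.1..Y.{n}"
        )
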