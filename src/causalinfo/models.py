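"""Discrete probability models on chain graphs.

A :class:`DiscreteModel` couples a validated :class:`~causalinfo.graphs.ChainGraph`
with finite per-node domains and one conditional table per chain component,
``P(tau | pa(tau))``.  The joint factorises as the product of these
component conditionals; for a DAG (all components singletons) this is the
usual Bayesian-network product ``prod_i P(X_i | pa(X_i))``.

Interventions follow the truncated-factorisation semantics: ``do(Y=y)``
replaces the factor of every chain component ``tau`` that intersects ``Y``
by ``P(tau \\ Y | pa(tau), tau ∩ Y)`` evaluated at ``y``, and puts point
mass on the intervened nodes.  With singleton components the replaced
factor is constant 1, i.e. the intervened factor is simply dropped, which
recovers the DAG definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import options
from .errors import (
    InputError,
    ModelValidationError,
    PositivityError,
    ResourceCapError,
    ZeroProbabilityError,
)
from .graphs import ChainGraph

__all__ = [
    "Intervention",
    "ComponentTable",
    "DiscreteModel",
    "JointTable",
    "joint_table",
    "intervene",
    "sample",
    "fit_empirical",
    "random_model",
]


class Intervention:
    """A do(.) argument: a partial assignment of nodes to values."""

    def __init__(self, assignments: Mapping[str, Any]):
        if len(set(assignments)) != len(assignments):
            raise InputError("intervention nodes must be distinct")
        self.assignments = dict(assignments)

    def __len__(self):
        return len(self.assignments)

    def __repr__(self):
        inner = ", ".join(f"{k}={v!r}" for k, v in self.assignments.items())
        return f"do({inner})"


def _as_do(do) -> dict:
    if do is None:
        return {}
    if isinstance(do, Intervention):
        return dict(do.assignments)
    return dict(do)


@dataclass
class ComponentTable:
    """Conditional table P(members | parents).

    ``probs`` has one axis per parent (in the recorded ``parents`` order)
    followed by one axis per member (in ``members`` order); each row (fixed
    parent assignment) sums to 1.
    """

    members: tuple
    parents: tuple
    probs: np.ndarray

    def __post_init__(self):
        self.members = tuple(self.members)
        self.parents = tuple(self.parents)
        self.probs = np.asarray(self.probs, dtype=float)


class DiscreteModel:
    """Chain-graph model with finite domains and component conditionals.

    Parameters
    ----------
    graph : ChainGraph
    domains : mapping node -> ordered sequence of values
    tables : iterable of ComponentTable, one per chain component
    numeric : nodes whose domain values are declared numeric (required for
        expectation-based effect measures; never inferred)
    """

    def __init__(self, graph: ChainGraph, domains: Mapping[str, Sequence],
                 tables, numeric=(), meta=None):
        self.graph = graph
        if set(domains) != set(graph.nodes):
            raise ModelValidationError("domains must cover exactly the graph nodes")
        self.domains = {v: tuple(domains[v]) for v in graph.nodes}
        for v, dom in self.domains.items():
            if len(dom) == 0 or len(set(dom)) != len(dom):
                raise ModelValidationError(f"domain of {v!r} must be non-empty and unique")
        self.numeric = frozenset(numeric)
        for v in self.numeric - set(graph.nodes):
            raise ModelValidationError(f"numeric flag on unknown node {v!r}")
        self.meta = dict(meta or {})
        self.tables: dict = {}
        for ct in tables:
            key = tuple(ct.members)
            if key in self.tables:
                raise ModelValidationError(f"duplicate table for component {key}")
            self.tables[key] = ct
        self._validate_tables()

    def _validate_tables(self):
        expected = {tuple(c) for c in self.graph.chain_components}
        got = set(self.tables)
        if expected != got:
            raise ModelValidationError(
                f"tables must cover the chain components exactly; "
                f"missing {sorted(expected - got)}, extra {sorted(got - expected)}"
            )
        tol = options.row_sum_tol
        for key, ct in self.tables.items():
            want_parents = self.graph.component_parents(key)
            if set(ct.parents) != set(want_parents):
                raise ModelValidationError(
                    f"component {key}: parents {ct.parents} do not match pa(tau)="
                    f"{want_parents}"
                )
            shape = tuple(len(self.domains[p]) for p in ct.parents) + tuple(
                len(self.domains[m]) for m in ct.members
            )
            if ct.probs.shape != shape:
                raise ModelValidationError(
                    f"component {key}: table shape {ct.probs.shape} != expected {shape}"
                )
            if np.any(ct.probs < 0):
                raise ModelValidationError(f"component {key}: negative probability")
            member_axes = tuple(range(len(ct.parents), ct.probs.ndim))
            sums = np.atleast_1d(ct.probs.sum(axis=member_axes))
            bad = np.argwhere(np.abs(sums - 1.0) > tol)
            if bad.size:
                row = tuple(int(i) for i in bad[0])
                raise ModelValidationError(
                    f"component {key}: row {row} sums to {sums[tuple(bad[0])]:.12g}, "
                    f"not 1 within {tol}"
                )

    @property
    def positive(self) -> bool:
        """True iff every conditional probability is strictly positive.

        Positivity is reported, not enforced, so deterministic limits stay
        representable.
        """
        return all(np.all(ct.probs > 0) for ct in self.tables.values())

    def component_table(self, member: str) -> ComponentTable:
        return self.tables[self.graph.component_of(member)]

    def value_index(self, node: str, value) -> int:
        try:
            return self.domains[node].index(value)
        except ValueError:
            raise InputError(f"value {value!r} not in domain of {node!r}") from None
        except KeyError:
            raise InputError(f"unknown node {node!r}") from None


class JointTable:
    """Exact probability table over an ordered set of variables.

    ``probs`` has one axis per variable; the carrier for observational,
    interventional, conditional and marginal distributions alike.
    """

    def __init__(self, variables, domains, probs, check: bool = True):
        self.variables = tuple(variables)
        self.domains = {v: tuple(domains[v]) for v in self.variables}
        self.probs = np.asarray(probs, dtype=float)
        expect = tuple(len(self.domains[v]) for v in self.variables)
        if self.probs.shape != expect:
            raise InputError(f"probability array shape {self.probs.shape} != {expect}")
        if check:
            if np.any(self.probs < -1e-12):
                raise ModelValidationError("negative probability in joint table")
            total = float(self.probs.sum())
            if not math.isclose(total, 1.0, rel_tol=0.0, abs_tol=1e-9):
                raise ModelValidationError(f"joint table sums to {total!r}, not 1")

    def axis(self, var: str) -> int:
        try:
            return self.variables.index(var)
        except ValueError:
            raise InputError(f"unknown variable {var!r}") from None

    def order(self, subset) -> tuple:
        """``subset`` sorted into this table's variable order."""
        subset = set(subset)
        unknown = subset - set(self.variables)
        if unknown:
            raise InputError(f"unknown variable(s): {sorted(unknown)}")
        return tuple(v for v in self.variables if v in subset)

    def marginal(self, keep) -> "JointTable":
        """Sum out every variable not in ``keep`` (order preserved)."""
        keep = self.order(keep)
        drop = tuple(i for i, v in enumerate(self.variables) if v not in keep)
        return JointTable(keep, self.domains, self.probs.sum(axis=drop), check=False)

    def condition(self, on: Mapping[str, Any]) -> "JointTable":
        """Renormalised slice at the assignment ``on`` over the remaining
        variables; raises :class:`ZeroProbabilityError` on a null event."""
        event = dict(on)
        pending = dict(event)
        idx = []
        for v in self.variables:
            if v in pending:
                val = pending.pop(v)
                try:
                    idx.append(self.domains[v].index(val))
                except ValueError:
                    raise InputError(f"value {val!r} not in domain of {v!r}") from None
            else:
                idx.append(slice(None))
        if pending:
            raise InputError(f"unknown variable(s): {sorted(pending)}")
        sliced = self.probs[tuple(idx)]
        mass = float(sliced.sum())
        if mass <= 0.0:
            raise ZeroProbabilityError(
                f"conditioning event has probability 0: {event}"
            )
        remaining = tuple(v for v in self.variables if isinstance(idx[self.axis(v)], slice))
        return JointTable(remaining, self.domains, sliced / mass, check=False)

    def prob(self, assignment: Mapping[str, Any]) -> float:
        """Probability of a full assignment."""
        if set(assignment) != set(self.variables):
            raise InputError("assignment must cover all variables")
        idx = tuple(self.domains[v].index(assignment[v]) for v in self.variables)
        return float(self.probs[idx])

    def expectation(self, var: str) -> float:
        """E[var] under this table; the domain values must be numeric."""
        m = self.marginal([var])
        vals = np.asarray(m.domains[var], dtype=float)
        return float(np.dot(m.probs, vals))


# -- factorisation and interventions ---------------------------------------

def _check_cap(m: DiscreteModel):
    size = 1
    for v in m.graph.nodes:
        size *= len(m.domains[v])
        if size > options.state_space_cap:
            raise ResourceCapError(
                f"joint state space exceeds the cap of {options.state_space_cap} "
                f"assignments; this is an exact, desk-scale method"
            )


def _broadcast(arr: np.ndarray, axes_vars, variables) -> np.ndarray:
    """Reshape a factor with axes ``axes_vars`` for broadcasting over the
    full variable order."""
    pos = {v: i for i, v in enumerate(variables)}
    perm = sorted(range(len(axes_vars)), key=lambda i: pos[axes_vars[i]])
    arr = arr.transpose(perm)
    sizes = dict(zip((axes_vars[i] for i in perm), arr.shape))
    return arr.reshape([sizes.get(v, 1) for v in variables])


def joint_table(m: DiscreteModel) -> JointTable:
    """Exact joint ``prod_tau P(tau | pa(tau))`` over all nodes."""
    _check_cap(m)
    variables = m.graph.nodes
    acc = np.ones(tuple(len(m.domains[v]) for v in variables))
    for key, ct in m.tables.items():
        acc = acc * _broadcast(ct.probs, ct.parents + ct.members, variables)
    return JointTable(variables, m.domains, acc)


def intervene(m: DiscreteModel, do) -> JointTable:
    """Interventional joint under ``do`` (an :class:`Intervention` or dict).

    Intervened nodes carry point mass at their target value; every chain
    component meeting the do-set contributes ``P(tau \\ do | pa(tau),
    tau ∩ do)`` instead of its full conditional. An empty ``do`` returns the
    observational joint.
    """
    do = _as_do(do)
    for v, val in do.items():
        m.value_index(v, val)  # validates node and value
    _check_cap(m)
    variables = m.graph.nodes
    acc = np.ones(tuple(len(m.domains[v]) for v in variables))
    for key, ct in m.tables.items():
        hit = [x for x in ct.members if x in do]
        if not hit:
            factor = ct.probs
        elif len(hit) == len(ct.members):
            factor = None  # fully intervened component: factor drops entirely
        else:
            free_axes = tuple(
                len(ct.parents) + i for i, x in enumerate(ct.members) if x not in do
            )
            denom = ct.probs.sum(axis=free_axes, keepdims=True)
            factor = np.divide(
                ct.probs, denom, out=np.zeros_like(ct.probs), where=denom > 0
            )
        if factor is not None:
            acc = acc * _broadcast(factor, ct.parents + ct.members, variables)
    # point mass on the intervened nodes
    for v, val in do.items():
        mask = np.zeros(len(m.domains[v]))
        mask[m.value_index(v, val)] = 1.0
        acc = acc * _broadcast(mask, (v,), variables)
    return JointTable(variables, m.domains, acc)


# -- sampling and plug-in fitting ------------------------------------------

def sample(m: DiscreteModel, n: int, seed: int) -> pd.DataFrame:
    """Ancestral sampling in component-topological order.

    Each chain component is drawn jointly from its conditional table given
    the already-sampled parents, i.e. the component conditionals are taken
    as the equilibria of the within-component sampling process.
    """
    if n < 0:
        raise InputError("n must be >= 0")
    rng = np.random.default_rng(seed)
    cols = {v: np.empty(n, dtype=int) for v in m.graph.nodes}
    for key in (tuple(c) for c in m.graph.chain_components):
        ct = m.tables[key]
        n_par = len(ct.parents)
        member_card = int(np.prod([len(m.domains[x]) for x in ct.members], dtype=int))
        flat = ct.probs.reshape((-1, member_card))
        if n_par:
            par_sizes = [len(m.domains[p]) for p in ct.parents]
            row = np.zeros(n, dtype=int)
            for p, size in zip(ct.parents, par_sizes):
                row = row * size + cols[p]
        else:
            row = np.zeros(n, dtype=int)
        cum = np.cumsum(flat, axis=1)
        u = rng.random(n)
        drawn = (cum[row] < u[:, None]).sum(axis=1)
        drawn = np.minimum(drawn, member_card - 1)
        for x in reversed(ct.members):
            card = len(m.domains[x])
            cols[x] = drawn % card
            drawn = drawn // card
    data = {v: [m.domains[v][i] for i in cols[v]] for v in m.graph.nodes}
    return pd.DataFrame(data, columns=list(m.graph.nodes))


def fit_empirical(data: pd.DataFrame, g: ChainGraph, domains,
                  numeric=()) -> DiscreteModel:
    """Plug-in model: component conditionals as empirical relative
    frequencies.  Parent rows never observed are set uniform and recorded in
    ``model.meta['uniform_rows']``."""
    domains = {v: tuple(domains[v]) for v in g.nodes}
    missing = set(g.nodes) - set(data.columns)
    if missing:
        raise InputError(f"data lacks column(s) for node(s): {sorted(missing)}")
    codes = {}
    for v in g.nodes:
        lookup = {val: i for i, val in enumerate(domains[v])}
        try:
            codes[v] = np.asarray([lookup[x] for x in data[v]], dtype=int)
        except KeyError as e:
            raise InputError(f"observed value {e.args[0]!r} not in domain of {v!r}") from None
    tables, uniform_rows = [], {}
    for key in (tuple(c) for c in g.chain_components):
        parents = g.component_parents(key)
        axes = parents + key
        shape = tuple(len(domains[a]) for a in axes)
        counts = np.zeros(shape)
        if len(data):
            np.add.at(counts, tuple(codes[a] for a in axes), 1.0)
        member_axes = tuple(range(len(parents), len(axes)))
        row_tot = counts.sum(axis=member_axes, keepdims=True)
        member_card = int(np.prod([len(domains[x]) for x in key], dtype=int))
        probs = np.divide(counts, row_tot, out=np.full_like(counts, 1.0 / member_card),
                          where=row_tot > 0)
        empty = np.argwhere(row_tot.reshape(tuple(len(domains[p]) for p in parents) or (1,)) == 0)
        if empty.size:
            uniform_rows[key] = [tuple(int(i) for i in r) for r in empty]
        tables.append(ComponentTable(key, parents, probs))
    return DiscreteModel(g, domains, tables, numeric=numeric,
                         meta={"uniform_rows": uniform_rows, "fitted_n": len(data)})


def random_model(g: ChainGraph, domains, seed: int, alpha: float = 1.0,
                 numeric=()) -> DiscreteModel:
    """Model with conditional rows drawn Dirichlet(alpha, ..., alpha).

    Each row's generator is seeded by ``(seed, component index, row index)``
    so editing one table never reshuffles the others.
    """
    if alpha <= 0:
        raise InputError("alpha must be > 0")
    domains = {v: tuple(domains[v]) for v in g.nodes}
    tables = []
    for ci, key in enumerate(tuple(c) for c in g.chain_components):
        parents = g.component_parents(key)
        par_shape = tuple(len(domains[p]) for p in parents)
        member_shape = tuple(len(domains[x]) for x in key)
        member_card = int(np.prod(member_shape, dtype=int))
        n_rows = int(np.prod(par_shape, dtype=int)) if par_shape else 1
        rows = np.empty((n_rows, member_card))
        for r in range(n_rows):
            rng = np.random.default_rng([int(seed), ci, r])
            rows[r] = rng.dirichlet([alpha] * member_card)
        tables.append(ComponentTable(key, parents, rows.reshape(par_shape + member_shape)))
    return DiscreteModel(g, domains, tables, numeric=numeric,
                         meta={"seed": int(seed), "alpha": float(alpha)})
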