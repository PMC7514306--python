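"""Exact information functionals over joint tables and discrete models.

Entropy, Kullback-Leibler divergence, (conditional) mutual information, the
weighted Jensen-Shannon divergence, and (conditional) directed information.

Directed information between disjoint node sets A and B,

    I(A -> B) = E_{P(A,B)} log [ P(A | B) / P(A | do(B)) ],

compares the observational conditional of A given B with the interventional
one in which B is forced; it vanishes iff the ordered pair (B, A) is
unconfounded, i.e. ``P(A|do(B=b)) = P(A|b)`` wherever ``P(b) > 0``.  Note
the convention: the *second* argument is the do() target.  The conditional
variant performs the intervention before conditioning on Z:
``P(A|do(B), Z) = P(A, Z|do(B)) / P(Z|do(B))``.

All sums run over support points only (``0 log 0 := 0``); a point with
observational mass but zero interventional mass is an absolute-continuity
violation and yields a flagged infinite value rather than an exception, so
deterministic limit studies remain runnable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .config import options, resolve_base
from .errors import InputError
from .models import DiscreteModel, Intervention, JointTable, intervene, joint_table

__all__ = [
    "InfoValue",
    "JSDWeights",
    "entropy",
    "kl",
    "mutual_information",
    "jsd_weighted",
    "directed_information",
    "conditional_directed_information",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class InfoValue:
    """An information quantity with its logarithm base.

    ``infinite`` marks an absolute-continuity violation (some p > 0 where
    q = 0), in which case ``value`` is ``math.inf``.
    """

    value: float
    base: str = "bits"
    infinite: bool = False

    def __float__(self):
        return float(self.value)

    def in_base(self, base: str) -> "InfoValue":
        base = resolve_base(base)
        if base == self.base or self.infinite:
            return InfoValue(self.value, base, self.infinite)
        factor = _LN2 if base == "nats" else 1.0 / _LN2
        return InfoValue(self.value * factor, base, self.infinite)

    def is_zero(self, tol: float | None = None) -> bool:
        if self.infinite:
            return False
        tol = options.zero_tol if tol is None else tol
        return abs(self.in_base("bits").value) <= tol


def _log(x: np.ndarray, base: str) -> np.ndarray:
    return np.log2(x) if base == "bits" else np.log(x)


def _same_support_shape(p: JointTable, q: JointTable, op: str):
    if p.variables != q.variables or p.domains != q.domains:
        raise InputError(f"{op} requires identical variable sets and domains")


def entropy(t: JointTable, base: str | None = None) -> InfoValue:
    """Shannon entropy  -sum p log p  with 0 log 0 := 0."""
    base = resolve_base(base)
    p = t.probs[t.probs > 0]
    return InfoValue(float(-(p * _log(p, base)).sum()), base)


def kl(P: JointTable, Q: JointTable, base: str | None = None) -> InfoValue:
    """Kullback-Leibler divergence D(P || Q) over a shared assignment space."""
    base = resolve_base(base)
    _same_support_shape(P, Q, "KL divergence")
    mask = P.probs > 0
    if np.any(Q.probs[mask] <= 0):
        return InfoValue(math.inf, base, infinite=True)
    p, q = P.probs[mask], Q.probs[mask]
    return InfoValue(float((p * _log(p / q, base)).sum()), base)


def _marg(arr: np.ndarray, keep_axes: tuple) -> np.ndarray:
    drop = tuple(i for i in range(arr.ndim) if i not in keep_axes)
    return arr.sum(axis=drop, keepdims=True)


def mutual_information(t: JointTable, A, B, given=(),
                       base: str | None = None) -> InfoValue:
    """(Conditional) mutual information I(A; B | given) from an exact table.

    Computed as the KL divergence between ``P(A,B,Z)`` and
    ``P(A|Z) P(B|Z) P(Z)`` over support points; symmetric in A and B.  An
    empty A or B gives 0 (boundary convention used by the time-series sums).
    """
    base = resolve_base(base)
    A, B, Z = (frozenset((s,)) if isinstance(s, str) else frozenset(s)
               for s in (A, B, given))
    if A & B or A & Z or B & Z:
        raise InputError("A, B and the conditioning set must be pairwise disjoint")
    if not A or not B:
        return InfoValue(0.0, base)
    sub = t.marginal(A | B | Z)
    a_axes = tuple(sub.variables.index(v) for v in sub.order(A))
    b_axes = tuple(sub.variables.index(v) for v in sub.order(B))
    z_axes = tuple(sub.variables.index(v) for v in sub.order(Z))
    pabz = sub.probs
    paz = _marg(pabz, a_axes + z_axes)
    pbz = _marg(pabz, b_axes + z_axes)
    pz = _marg(pabz, z_axes)
    mask = pabz > 0
    num = pabz[mask] * np.broadcast_to(pz, pabz.shape)[mask]
    den = (np.broadcast_to(paz, pabz.shape)[mask]
           * np.broadcast_to(pbz, pabz.shape)[mask])
    return InfoValue(float((pabz[mask] * _log(num / den, base)).sum()), base)


@dataclass(frozen=True)
class JSDWeights:
    """Mixture weights (pi_q, pi_r) for the weighted Jensen-Shannon
    divergence; must be nonnegative and sum to 1."""

    pi_q: float
    pi_r: float

    def __post_init__(self):
        if self.pi_q < 0 or self.pi_r < 0:
            raise InputError("JSD weights must be nonnegative")
        if abs(self.pi_q + self.pi_r - 1.0) > 1e-12:
            raise InputError("JSD weights must sum to 1")


def jsd_weighted(q: JointTable, r: JointTable, w: JSDWeights,
                 base: str | None = None) -> InfoValue:
    """Weighted Jensen-Shannon divergence
    ``H[pi_q q + pi_r r] - pi_q H[q] - pi_r H[r]``; nonnegative and bounded
    by the entropy of the weight vector."""
    base = resolve_base(base)
    _same_support_shape(q, r, "JSD")
    if not isinstance(w, JSDWeights):
        w = JSDWeights(*w)
    mix = JointTable(q.variables, q.domains,
                     w.pi_q * q.probs + w.pi_r * r.probs, check=False)
    val = (entropy(mix, base).value - w.pi_q * entropy(q, base).value
           - w.pi_r * entropy(r, base).value)
    return InfoValue(float(val), base)


# -- directed information ---------------------------------------------------

def _set_in_order(m: DiscreteModel, S) -> tuple:
    S = frozenset((S,)) if isinstance(S, str) else frozenset(S)
    return m.graph.node_order(S)


def _assignments(m: DiscreteModel, nodes: tuple):
    return itertools.product(*(m.domains[v] for v in nodes))


def directed_information(m: DiscreteModel, A, B,
                         base: str | None = None) -> InfoValue:
    """Directed information I(A -> B): do() is applied to ``B``."""
    base = resolve_base(base)
    A, B = _set_in_order(m, A), _set_in_order(m, B)
    if set(A) & set(B):
        raise InputError("A and B must be disjoint")
    if not A or not B:
        return InfoValue(0.0, base)
    sub = joint_table(m).marginal(set(A) | set(B))
    a_axes = tuple(sub.variables.index(v) for v in A)
    pab = sub.probs
    pb = _marg(pab, tuple(i for i in range(pab.ndim) if i not in a_axes))
    p_a_given_b = np.divide(pab, pb, out=np.zeros_like(pab), where=pb > 0)
    p_do = np.zeros_like(pab)
    for bvals in _assignments(m, B):
        t_do = intervene(m, dict(zip(B, bvals))).marginal(set(A))
        idx = tuple(
            slice(None) if v in A else sub.domains[v].index(bvals[B.index(v)])
            for v in sub.variables
        )
        p_do[idx] = t_do.probs
    mask = pab > 0
    if np.any(p_do[mask] <= 0):
        return InfoValue(math.inf, base, infinite=True)
    val = float((pab[mask] * _log(p_a_given_b[mask] / p_do[mask], base)).sum())
    return InfoValue(val, base)


def conditional_directed_information(m: DiscreteModel, A, B, Z,
                                     base: str | None = None) -> InfoValue:
    """Conditional directed information I(A -> B | Z).

    The intervention on B is performed before conditioning on Z:
    the denominator uses ``P(A|do(B), Z) = P(A, Z|do(B)) / P(Z|do(B))``.
    With an empty Z this coincides with :func:`directed_information`.
    """
    base = resolve_base(base)
    A, B, Z = _set_in_order(m, A), _set_in_order(m, B), _set_in_order(m, Z)
    if set(A) & set(B) or set(A) & set(Z) or set(B) & set(Z):
        raise InputError("A, B and Z must be pairwise disjoint")
    if not Z:
        return directed_information(m, A, B, base)
    if not A or not B:
        return InfoValue(0.0, base)
    sub = joint_table(m).marginal(set(A) | set(B) | set(Z))
    a_axes = tuple(sub.variables.index(v) for v in A)
    b_axes = tuple(sub.variables.index(v) for v in B)
    z_axes = tuple(sub.variables.index(v) for v in Z)
    pabz = sub.probs
    pbz = _marg(pabz, b_axes + z_axes)
    p_a_given_bz = np.divide(pabz, pbz, out=np.zeros_like(pabz), where=pbz > 0)
    p_do = np.zeros_like(pabz)
    for bvals in _assignments(m, B):
        t_do = intervene(m, dict(zip(B, bvals)))
        sub_do = t_do.marginal(set(A) | set(Z))
        arr = sub_do.probs
        az_a_axes = tuple(sub_do.variables.index(v) for v in A)
        pz_do = _marg(arr, tuple(i for i in range(arr.ndim) if i not in az_a_axes))
        cond = np.divide(arr, pz_do, out=np.zeros_like(arr), where=pz_do > 0)
        idx = tuple(
            slice(None) if v not in B else sub.domains[v].index(bvals[B.index(v)])
            for v in sub.variables
        )
        p_do[idx] = cond
    mask = pabz > 0
    if np.any(p_do[mask] <= 0):
        return InfoValue(math.inf, base, infinite=True)
    val = float((pabz[mask] * _log(p_a_given_bz[mask] / p_do[mask], base)).sum())
    return InfoValue(val, base)
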