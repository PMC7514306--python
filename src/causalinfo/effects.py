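"""Two-step information-theoretic causal deduction.

Step 1 (deconfounding): the ordered pair (X, Y) is unconfounded iff the
reverse directed information I(Y -> X) is zero; when it is not, a set Z of
non-descendants of X with I(Y -> X | Z) = 0 is an adjustment set, and such
sets coincide with the graphical back-door sets.  Step 2 (quantification):
in the unconfounded (or adjusted) setting, mutual information I(X;Y) equals
the weighted Jensen-Shannon divergence between the two interventional
outcome distributions q = P(Y|do(X=1)), r = P(Y|do(X=0)) with weights
P(X=1), P(X=0); conditionally, E_Z[JSD(r_z || q_z)] = I(X;Y|Z).  The ACE
and its z-stratum version (SCE) are the first-moment analogues.

Step-2 quantities are never computed for a pair that failed step 1 without
an adjustment set: mutual-information-type quantities carry a causal
meaning only after deconfounding.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import logger, options, resolve_base
from .errors import (
    ConsistencyError,
    InputError,
    PipelineOrderError,
    PositivityError,
    ZeroProbabilityError,
)
from .graphs import enumerate_backdoor_sets, satisfies_backdoor
from .measures import (
    InfoValue,
    JSDWeights,
    conditional_directed_information,
    directed_information,
    jsd_weighted,
    mutual_information,
)
from .models import DiscreteModel, JointTable, intervene, joint_table

__all__ = [
    "EffectReport",
    "check_unconfounded",
    "find_adjustment_set",
    "adjust",
    "ace",
    "sce",
    "effect_mi_with_jsd_check",
    "quantify_effect",
]


@dataclass
class EffectReport:
    """Outcome of the two-step procedure for an ordered pair (cause, outcome)."""

    cause: tuple
    outcome: tuple
    unconfounded: bool
    di_value: InfoValue
    identified: bool
    adjustment_set: Optional[frozenset] = None
    cdi_value: Optional[InfoValue] = None
    effect_mi: Optional[InfoValue] = None
    jsd_check: Optional[dict] = None
    ace: Optional[float] = None
    sce_by_z: Optional[dict] = None
    notes: list = field(default_factory=list)


def _ordered(m: DiscreteModel, S) -> tuple:
    S = (S,) if isinstance(S, str) else tuple(S)
    return m.graph.node_order(S)


def check_unconfounded(m: DiscreteModel, X, Y, tol: float | None = None):
    """Step 1 without adjustment: returns ``(unconfounded, I(Y -> X))``.

    The intervention target of the directed information is the cause X; the
    pair is unconfounded iff the value is zero (within tolerance)."""
    X, Y = _ordered(m, X), _ordered(m, Y)
    di = directed_information(m, Y, X)
    ok = di.is_zero(tol)
    logger.info("step 1: I(%s -> %s) = %.6g %s => %sconfounded",
                Y, X, di.value, di.base, "un" if ok else "")
    return ok, di


def find_adjustment_set(m: DiscreteModel, X, Y, max_size: int,
                        method: str = "both", tol: float | None = None):
    """Smallest (then lexicographically first) adjustment set within
    ``max_size``, or None.

    Candidates are subsets of the non-descendants of X excluding X and Y.
    ``method='cdi'`` accepts Z when I(Y -> X | Z) = 0; ``'backdoor'`` uses
    the graphical criterion; ``'both'`` evaluates the two routes on every
    candidate and raises :class:`ConsistencyError` if they ever disagree.
    """
    if max_size < 0:
        raise InputError("max_size must be >= 0")
    if method not in ("cdi", "backdoor", "both"):
        raise InputError("method must be 'cdi', 'backdoor' or 'both'")
    X, Y = _ordered(m, X), _ordered(m, Y)
    g = m.graph
    pool = sorted(set(g.nodes) - g.descendants(X) - set(X) - set(Y))
    for k in range(min(max_size, len(pool)) + 1):
        for combo in itertools.combinations(pool, k):
            Z = frozenset(combo)
            verdicts = {}
            if method in ("cdi", "both"):
                cdi = conditional_directed_information(m, Y, X, Z)
                verdicts["cdi"] = cdi.is_zero(tol)
            if method in ("backdoor", "both"):
                verdicts["backdoor"] = satisfies_backdoor(g, X, Y, Z)
            if method == "both" and verdicts["cdi"] != verdicts["backdoor"]:
                raise ConsistencyError(
                    f"information-theoretic and graphical routes disagree on "
                    f"Z={sorted(Z)}: {verdicts}"
                )
            if all(verdicts.values()):
                logger.info("step 1: adjustment set %s for (%s, %s)",
                            sorted(Z), X, Y)
                return Z
    return None


def adjust(m: DiscreteModel, X, Y, Z) -> dict:
    """Back-door adjustment: for each assignment x of X, the table
    ``sum_z P(Y | x, z) P(z)`` over Y.  Keys are value tuples in X's node
    order.  Raises :class:`PositivityError` when a needed stratum (x, z)
    has probability zero."""
    X, Y, Z = _ordered(m, X), _ordered(m, Y), _ordered(m, Z)
    if set(Z) & (set(X) | set(Y)):
        raise InputError("Z must be disjoint from X and Y")
    t = joint_table(m).marginal(set(X) | set(Y) | set(Z))
    pz_table = t.marginal(set(Z))
    out = {}
    for xvals in itertools.product(*(m.domains[v] for v in X)):
        acc = None
        for zvals in itertools.product(*(m.domains[v] for v in Z)):
            pz = float(pz_table.probs[tuple(
                pz_table.domains[v].index(zvals[Z.index(v)]) for v in pz_table.variables
            )]) if Z else 1.0
            if pz == 0.0:
                continue
            event = dict(zip(X, xvals)) | dict(zip(Z, zvals))
            try:
                py = t.condition(event)
            except ZeroProbabilityError:
                raise PositivityError(
                    f"adjustment needs P(Y | X={xvals}, Z={zvals}) but "
                    f"P(X={xvals}, Z={zvals}) = 0"
                ) from None
            py = py.marginal(set(Y))
            acc = pz * py.probs if acc is None else acc + pz * py.probs
        out[xvals] = JointTable(
            tuple(v for v in t.variables if v in set(Y)), m.domains, acc
        )
    return out


def _require_binary_cause(m: DiscreteModel, X) -> str:
    if len(X) != 1:
        raise InputError("this measure requires a single binary cause node")
    (x,) = X
    if set(m.domains[x]) != {0, 1}:
        raise InputError(f"cause {x!r} must have domain {{0, 1}}")
    return x


def _require_numeric_outcome(m: DiscreteModel, Y) -> str:
    if len(Y) != 1:
        raise InputError("expectation-based effects require a single outcome node")
    (y,) = Y
    if y not in m.numeric:
        raise InputError(
            f"outcome {y!r} has no declared numeric coding; mark it numeric "
            f"explicitly (ordinal coercion is never silent)"
        )
    return y


def ace(m: DiscreteModel, X, Y, Z=None) -> float:
    """Average causal effect E[Y|do(X=1)] - E[Y|do(X=0)].

    With ``Z=None`` the two interventional expectations are computed
    exactly.  With an adjustment set Z the observational form
    ``E_{P(Z)}[ E[Y|X=1,Z] - E[Y|X=0,Z] ]`` is used; the two agree whenever
    Z satisfies the back-door criterion.
    """
    X, Y = _ordered(m, X), _ordered(m, Y)
    x = _require_binary_cause(m, X)
    y = _require_numeric_outcome(m, Y)
    if Z is None:
        e1 = intervene(m, {x: 1}).marginal([y]).expectation(y)
        e0 = intervene(m, {x: 0}).marginal([y]).expectation(y)
        return e1 - e0
    Z = _ordered(m, Z)
    strata = adjust(m, X, Y, Z)
    t1, t0 = strata[(1,)], strata[(0,)]
    vals = np.asarray(m.domains[y], dtype=float)
    return float(np.dot(t1.probs - t0.probs, vals))


def sce(m: DiscreteModel, X, Y, z: dict) -> float:
    """Specific (z-stratum) causal effect
    ``E[Y|do(X=1), Z=z] - E[Y|do(X=0), Z=z]`` for a full assignment ``z``
    of a set of non-descendants of X; interventions are applied before
    conditioning."""
    X, Y = _ordered(m, X), _ordered(m, Y)
    x = _require_binary_cause(m, X)
    y = _require_numeric_outcome(m, Y)
    Z = _ordered(m, z.keys())
    bad = set(Z) & m.graph.descendants(X)
    if bad:
        raise InputError(f"SCE requires non-descendants of X; {sorted(bad)} are not")
    out = {}
    for xv in (1, 0):
        t = intervene(m, {x: xv})
        out[xv] = t.condition(z).marginal([y]).expectation(y)
    return out[1] - out[0]


def effect_mi_with_jsd_check(m: DiscreteModel, X, Y, Z=None,
                             tol: float | None = None):
    """Step 2: effect size as (conditional) mutual information, with the
    Jensen-Shannon cross-check.

    Returns ``(mi, report)`` where ``report['aggregate']`` is JSD(r||q)
    (``Z=None``) or ``E_Z[JSD(r_z||q_z)]``, and ``report['per_z']`` carries
    each stratum's JSD, its weight P(z), and the z-stratum KL divergence
    ``D(P(X,Y|z) || P(X|z)P(Y|z))`` that the JSD must equal there.  Raises
    :class:`PipelineOrderError` if step 1 does not hold for (X, Y[, Z]).
    """
    X, Y = _ordered(m, X), _ordered(m, Y)
    x = _require_binary_cause(m, X)
    if Z is None:
        ok, di = check_unconfounded(m, X, Y, tol)
        if not ok:
            raise PipelineOrderError(
                f"(X={X}, Y={Y}) is confounded (I(Y->X) = {di.value:.6g} "
                f"{di.base}); run step 1 and adjust first"
            )
        t = joint_table(m).marginal(set(X) | set(Y))
        px = t.marginal([x])
        q = intervene(m, {x: 1}).marginal(set(Y))
        r = intervene(m, {x: 0}).marginal(set(Y))
        w = JSDWeights(pi_q=float(px.probs[px.domains[x].index(1)]),
                       pi_r=float(px.probs[px.domains[x].index(0)]))
        agg = jsd_weighted(q, r, w)
        mi = mutual_information(t, X, Y)
        return mi, {"aggregate": agg, "per_z": None, "weights": w}
    Z = _ordered(m, Z)
    cdi = conditional_directed_information(m, Y, X, Z)
    if not cdi.is_zero(tol):
        raise PipelineOrderError(
            f"Z={Z} is not an adjustment set for (X={X}, Y={Y}) "
            f"(I(Y->X|Z) = {cdi.value:.6g} {cdi.base})"
        )
    t = joint_table(m).marginal(set(X) | set(Y) | set(Z))
    pz_table = t.marginal(set(Z))
    do1, do0 = intervene(m, {x: 1}), intervene(m, {x: 0})
    per_z, total = {}, 0.0
    for zvals in itertools.product(*(m.domains[v] for v in Z)):
        zev = dict(zip(Z, zvals))
        pz = float(pz_table.probs[tuple(
            pz_table.domains[v].index(zev[v]) for v in pz_table.variables)])
        if pz == 0.0:
            continue
        qz = do1.condition(zev).marginal(set(Y))
        rz = do0.condition(zev).marginal(set(Y))
        px_z = t.condition(zev).marginal([x])
        w = JSDWeights(pi_q=float(px_z.probs[px_z.domains[x].index(1)]),
                       pi_r=float(px_z.probs[px_z.domains[x].index(0)]))
        jz = jsd_weighted(qz, rz, w)
        stratum = t.condition(zev)
        stratum_kl = mutual_information(stratum, X, Y)
        per_z[zvals] = {"jsd": jz, "weight": pz, "stratum_kl": stratum_kl,
                        "weights": w}
        total += pz * jz.value
    agg = InfoValue(total, resolve_base(None))
    cmi = mutual_information(t, X, Y, Z)
    return cmi, {"aggregate": agg, "per_z": per_z, "cdi": cdi}


def quantify_effect(m: DiscreteModel, X, Y, max_size: int = 3,
                    tol: float | None = None) -> EffectReport:
    """Run the full two-step procedure for the ordered pair (X, Y)."""
    X, Y = _ordered(m, X), _ordered(m, Y)
    ok, di = check_unconfounded(m, X, Y, tol)
    report = EffectReport(cause=X, outcome=Y, unconfounded=ok, di_value=di,
                          identified=ok)
    Z = None
    if not ok:
        Z = find_adjustment_set(m, X, Y, max_size, method="both", tol=tol)
        if Z is None:
            report.identified = False
            report.notes.append(
                f"no adjustment set of size <= {max_size}; effect not "
                f"identified by this procedure"
            )
            return report
        report.identified = True
        report.adjustment_set = Z
        report.cdi_value = conditional_directed_information(m, Y, X, Z)
    binary_cause = len(X) == 1 and set(m.domains[X[0]]) == {0, 1}
    if binary_cause:
        mi, jsd_rep = effect_mi_with_jsd_check(m, X, Y, Z, tol)
        report.effect_mi, report.jsd_check = mi, jsd_rep
    else:
        t = joint_table(m).marginal(set(X) | set(Y) | set(Z or ()))
        report.effect_mi = mutual_information(t, X, Y, Z or ())
        report.notes.append("non-binary cause: MI/CMI reported without the "
                            "Jensen-Shannon cross-check")
    numeric_outcome = len(Y) == 1 and Y[0] in m.numeric
    if binary_cause and numeric_outcome:
        report.ace = ace(m, X, Y, Z)
        if Z:
            sces = {}
            for zvals in itertools.product(*(m.domains[v] for v in Z)):
                zev = dict(zip(Z, zvals))
                try:
                    sces[zvals] = sce(m, X, Y, zev)
                except ZeroProbabilityError:
                    continue
            report.sce_by_z = sces
    logger.info("step 2: effect of %s on %s: MI=%s ACE=%s",
                X, Y, report.effect_mi, report.ace)
    return report
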