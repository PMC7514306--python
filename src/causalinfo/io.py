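"""Model serialization (JSON), DOT export, and named fixtures.

The document format declares variables (with ordered domains and an
optional explicit ``numeric`` flag used by expectation-based effect
measures), directed and undirected edges, and one table block per chain
component.  Each table block records its parent order explicitly and its
``entries`` array is indexed parents-then-component, row-major over the
declared orders — removing the classic CPT axis-ambiguity trap.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, ModelValidationError, SchemaError
from .graphs import ChainGraph, to_dot
from .models import ComponentTable, DiscreteModel, random_model
from .timeseries import CanonicalSpec, build_canonical

__all__ = [
    "FORMAT_VERSION",
    "read_model",
    "write_model",
    "model_to_document",
    "document_to_model",
    "fixture",
    "FIXTURES",
]

FORMAT_VERSION = "1.0"


def _expect(cond, pointer, message):
    if not cond:
        raise SchemaError(message, pointer=pointer)


def document_to_model(doc: dict) -> DiscreteModel:
    """Validate a model document and build the DiscreteModel.

    Schema violations raise :class:`SchemaError` with a JSON-pointer path;
    structural problems (cycles, bad row sums) propagate from graph and
    model validation with located messages.
    """
    _expect(isinstance(doc, dict), "", "document must be a JSON object")
    for key in ("variables", "tables"):
        _expect(key in doc, f"/{key}", "required key missing")
    _expect(isinstance(doc["variables"], list) and doc["variables"],
            "/variables", "must be a non-empty array")
    names, domains, numeric = [], {}, set()
    for i, var in enumerate(doc["variables"]):
        ptr = f"/variables/{i}"
        _expect(isinstance(var, dict), ptr, "must be an object")
        _expect(isinstance(var.get("name"), str), f"{ptr}/name", "must be a string")
        dom = var.get("domain")
        _expect(isinstance(dom, list) and dom, f"{ptr}/domain",
                "must be a non-empty array")
        name = var["name"]
        _expect(name not in domains, f"{ptr}/name", f"duplicate variable {name!r}")
        names.append(name)
        domains[name] = tuple(tuple(v) if isinstance(v, list) else v for v in dom)
        if var.get("numeric", False):
            _expect(all(isinstance(v, (int, float)) and not isinstance(v, bool)
                        for v in dom),
                    f"{ptr}/numeric", "numeric flag requires numeric domain values")
            numeric.add(name)
    known = set(names)

    def edges(key):
        lst = doc.get(key, [])
        _expect(isinstance(lst, list), f"/{key}", "must be an array")
        out = []
        for j, e in enumerate(lst):
            _expect(isinstance(e, list) and len(e) == 2, f"/{key}/{j}",
                    "must be a pair")
            _expect(e[0] in known and e[1] in known, f"/{key}/{j}",
                    f"undeclared endpoint in {e}")
            out.append((e[0], e[1]))
        return out

    graph = ChainGraph(names, edges("directed_edges"), edges("undirected_edges"))
    tables = []
    _expect(isinstance(doc["tables"], list), "/tables", "must be an array")
    for i, blk in enumerate(doc["tables"]):
        ptr = f"/tables/{i}"
        _expect(isinstance(blk, dict), ptr, "must be an object")
        comp = blk.get("component")
        parents = blk.get("parents", [])
        _expect(isinstance(comp, list) and comp, f"{ptr}/component",
                "must be a non-empty array")
        _expect(isinstance(parents, list), f"{ptr}/parents", "must be an array")
        for v in list(comp) + list(parents):
            _expect(v in known, ptr, f"undeclared node {v!r}")
        try:
            entries = np.asarray(blk.get("entries"), dtype=float)
        except (TypeError, ValueError):
            raise SchemaError("entries must be a nested numeric array",
                              pointer=f"{ptr}/entries") from None
        shape = tuple(len(domains[p]) for p in parents) + tuple(
            len(domains[c]) for c in comp)
        _expect(entries.shape == shape, f"{ptr}/entries",
                f"shape {entries.shape} does not match declared axes {shape}")
        tables.append(ComponentTable(tuple(comp), tuple(parents), entries))
    return DiscreteModel(graph, domains, tables, numeric=numeric,
                         meta={"format_version": doc.get("format_version",
                                                         FORMAT_VERSION)})


def model_to_document(m: DiscreteModel) -> dict:
    comps = [tuple(c) for c in m.graph.chain_components]
    return {
        "format_version": FORMAT_VERSION,
        "variables": [
            {"name": v, "domain": list(m.domains[v])}
            | ({"numeric": True} if v in m.numeric else {})
            for v in m.graph.nodes
        ],
        "directed_edges": [list(e) for e in sorted(m.graph.directed_edges)],
        "undirected_edges": [sorted(e) for e in
                             sorted(map(sorted, m.graph.undirected_edges))],
        "tables": [
            {
                "component": list(key),
                "parents": list(m.tables[key].parents),
                "entries": m.tables[key].probs.tolist(),
            }
            for key in comps
        ],
    }


def read_model(path) -> DiscreteModel:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise SchemaError(f"not valid JSON: {e}") from None
    return document_to_model(doc)


def write_model(m: DiscreteModel, path) -> None:
    # json emits shortest round-trip float representations, so
    # read(write(m)) reproduces the probabilities bit-for-bit
    Path(path).write_text(json.dumps(model_to_document(m), indent=1) + "\n")


# -- fixtures ---------------------------------------------------------------

def _two_node():
    g = ChainGraph(["X", "Y"], [("X", "Y")])
    return random_model(g, {"X": (0, 1), "Y": (0, 1)}, seed=11,
                        numeric=("X", "Y"))


def _triangle():
    g = ChainGraph(["Z", "X", "Y"], [("Z", "X"), ("Z", "Y"), ("X", "Y")])
    return random_model(g, {v: (0, 1) for v in "ZXY"}, seed=13,
                        numeric=("X", "Y", "Z"))


def _collider():
    g = ChainGraph(["X", "Y", "C"], [("X", "C"), ("Y", "C")])
    return random_model(g, {v: (0, 1) for v in "XYC"}, seed=17,
                        numeric=("X", "Y", "C"))


def _fig2_style():
    # seven-node DAG whose only minimum-size back-door sets for (X, Y) are
    # {Z3, Z4} and {Z4, Z5}, with pa(X) = {Z3, Z4}: Z4 closes X <- Z4 -> Y
    # and either of Z3, Z5 closes X <- Z3 <- Z5 -> Y
    nodes = ["Z1", "Z2", "Z3", "Z4", "Z5", "X", "Y"]
    edges = [("Z1", "Z3"), ("Z2", "Z5"), ("Z5", "Z3"),
             ("Z3", "X"), ("Z4", "X"), ("Z4", "Y"), ("Z5", "Y"), ("X", "Y")]
    g = ChainGraph(nodes, edges)
    return random_model(g, {v: (0, 1) for v in nodes}, seed=19,
                        numeric=("X", "Y"))


FIXTURES = {
    "two_node": _two_node,
    "triangle": _triangle,
    "collider": _collider,
    "fig2_style": _fig2_style,
    # canonical time-series kinds, with embedded sizes and seeds
    "g1": lambda: build_canonical(CanonicalSpec("g1", n=3, seed=3)),
    "g2": lambda: build_canonical(CanonicalSpec("g2", n=3, seed=5)),
    "g2z": lambda: build_canonical(CanonicalSpec("g2z", n=2, seed=5)),
    "h1": lambda: build_canonical(CanonicalSpec("h1", n=2, seed=23)),
    "h1z": lambda: build_canonical(CanonicalSpec("h1z", n=2, seed=23)),
    "bidirectional": lambda: build_canonical(
        CanonicalSpec("bidirectional", n=4, seed=7)),
}


def fixture(name: str) -> DiscreteModel:
    """Deterministic named model; unknown names list what is available."""
    try:
        return FIXTURES[name]()
    except KeyError:
        raise InputError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
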