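"""Exception hierarchy for causalinfo.

All package exceptions derive from :class:`CausalInfoError` so callers can
catch everything with one clause; the CLI maps subclasses to exit codes.
"""


class CausalInfoError(Exception):
    """Base class for all causalinfo errors."""


class InputError(CausalInfoError, ValueError):
    """Invalid user input: unknown nodes, overlapping sets, bad values."""


class GraphStructureError(CausalInfoError, ValueError):
    """Structural violation: directed or semi-directed cycle, conflicting edges."""

    def __init__(self, message, cycle=None):
        super().__init__(message)
        self.cycle = tuple(cycle) if cycle is not None else None


class ModelValidationError(CausalInfoError, ValueError):
    """Conditional table inconsistent with the graph or not row-stochastic."""


class SchemaError(CausalInfoError, ValueError):
    """Model document violates the JSON schema; carries a JSON-pointer path."""

    def __init__(self, message, pointer=""):
        super().__init__(f"{pointer}: {message}" if pointer else message)
        self.pointer = pointer


class ResourceCapError(CausalInfoError, RuntimeError):
    """Exact enumeration would exceed the configured state-space cap."""


class ZeroProbabilityError(CausalInfoError, ArithmeticError):
    """Conditioning on (or stratifying by) an event of probability zero."""


class PositivityError(CausalInfoError, ArithmeticError):
    """An identification formula needs a cell probability that is zero."""


class PipelineOrderError(CausalInfoError, RuntimeError):
    """Effect quantification requested for a pair that failed the
    no-confounding step without an adjustment set."""


class ConsistencyError(CausalInfoError, RuntimeError):
    """Two routes that must agree (information-theoretic vs graphical)
    disagreed; indicates an internal defect, surfaced for the test suite."""
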