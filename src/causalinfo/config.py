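"""Global options and logging for causalinfo.

Information quantities are reported in bits by default; switch to nats with
``options.log_base = "nats"`` or per call via the ``base=`` argument that
every functional accepts.  "Equals zero" decisions (no-confounding checks,
adjustment-set search) use ``options.zero_tol``: all computations here are
exact summations over finite tables, so the tolerance only absorbs float
round-off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger("causalinfo")
logger.addHandler(logging.NullHandler())

#: Recognised logarithm bases.
BASES = ("bits", "nats")


@dataclass
class Options:
    #: default base for every information functional ("bits" or "nats")
    log_base: str = "bits"
    #: absolute tolerance for declaring an information value zero (bits)
    zero_tol: float = 1e-9
    #: absolute tolerance for conditional-table row sums
    row_sum_tol: float = 1e-9
    #: refuse exact joint enumeration beyond this many assignments
    state_space_cap: int = 4_000_000


options = Options()


def resolve_base(base: str | None) -> str:
    b = options.log_base if base is None else base
    if b not in BASES:
        raise ValueError(f"unknown log base {b!r}; expected one of {BASES}")
    return b
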