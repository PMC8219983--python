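"""Functional classification of stable stem-loops.

A stem-loop's role is read from its downstream-window U features:

* terminator (TSL): poly(U) run >= 4 AND U content >= 7 AND a downstream tail
  (the run starts right at the stem);
* stabilizer (SSL): U content <= 5 AND poly(U) run <= 3 (no tail or a short
  one);
* stabilizer-and-terminator (STSL): the middle class — a discontinuous or
  upstream (in-stem) poly(U) tail, or U content > 5.

Rules are evaluated in the order TSL, SSL, STSL; the extreme classes are
conjunctions and STSL is the permissive disjunction. With ``stsl_priority``
(the default) a discontinuous or upstream tail forces STSL even when the SSL
numeric bounds hold, which is what separates a scattered-U tail from a truly
tail-less stabilizer.
"""

from __future__ import annotations

from dataclasses import dataclass

from .features import UFeatures

LABELS = ("SSL", "STSL", "TSL", "unclassified")

TSL_MIN_POLYU = 4
TSL_MIN_U = 7
SSL_MAX_U = 5
SSL_MAX_POLYU = 3
STSL_MIN_U = 6  # "U content > 5"


@dataclass(frozen=True)
class SLClassification:
    label: str
    rule_trace: tuple[tuple[str, bool], ...]

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if not self.rule_trace:
            raise ValueError("rule_trace must be non-empty")


def classify(uf: UFeatures, stsl_priority: bool = True) -> SLClassification:
    """Assign SSL/STSL/TSL from U features; total, with fixed precedence."""
    trace: list[tuple[str, bool]] = []

    tsl = (
        uf.polyU_len >= TSL_MIN_POLYU
        and uf.U_content >= TSL_MIN_U
        and uf.tail_position == "downstream"
    )
    trace.append(
        (
            f"TSL: polyU>={TSL_MIN_POLYU} and U>={TSL_MIN_U} and downstream tail",
            tsl,
        )
    )
    if tsl:
        return SLClassification("TSL", tuple(trace))

    if stsl_priority:
        forced = uf.tail_position in ("discontinuous", "upstream")
        trace.append(("STSL priority: discontinuous or upstream tail", forced))
        if forced:
            return SLClassification("STSL", tuple(trace))

    ssl = uf.U_content <= SSL_MAX_U and uf.polyU_len <= SSL_MAX_POLYU
    trace.append((f"SSL: U<={SSL_MAX_U} and polyU<={SSL_MAX_POLYU}", ssl))
    if ssl:
        return SLClassification("SSL", tuple(trace))

    stsl = (
        uf.tail_position in ("discontinuous", "upstream")
        or uf.U_content >= STSL_MIN_U
    )
    trace.append(
        ("STSL: discontinuous or upstream tail, or U>5", stsl)
    )
    if stsl:
        return SLClassification("STSL", tuple(trace))

    return SLClassification("unclassified", tuple(trace))
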