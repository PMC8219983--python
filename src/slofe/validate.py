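"""Validation of SRPS candidates against expression data.

The normalized read-depth difference across a stem-loop,

    NRD = (Rd5 - Rd3) / max(Rd5, Rd3),

compares the read depth of the genes flanking the SL: values near +1 mean the
upstream transcript segment is selectively stabilized. Predicted ratios are
scored against measured transcript/protein abundances by Pearson correlation
on log10-normalized values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ExpressionTable
from .ratio import RatioPrediction, SRPSOperon, STABILIZER_LABELS

NRD_THRESHOLD = 0.5


@dataclass(frozen=True)
class ValidationRecord:
    sl_id: str
    operon_id: int
    rd5: float | None
    rd3: float | None
    nrd: float | None
    passed: bool | None
    status: str  # ok | no_data | undefined | rescued

    def __post_init__(self):
        if self.nrd is not None and not (-1.0 <= self.nrd <= 1.0):
            raise ValueError("NRD out of [-1, 1]")


@dataclass(frozen=True)
class CorrelationReport:
    operon_id: int
    r: float | None
    n_genes: int
    kind: str
    reason: str = ""  # why r was not computed, when it was not


def nrd(rd5: float, rd3: float) -> float:
    """Normalized read-depth difference (Rd5 - Rd3) / max(Rd5, Rd3)."""
    if rd5 < 0 or rd3 < 0:
        raise ValueError("read depths must be nonnegative")
    m = max(rd5, rd3)
    if m == 0:
        raise ValueError("NRD undefined for rd5 = rd3 = 0")
    return (rd5 - rd3) / m


def _nrd_5prime(rd5: float, rd3: float) -> float:
    """Caption variant: difference divided by the 5' gene's depth."""
    if rd5 <= 0:
        raise ValueError("5'-denominator NRD needs rd5 > 0")
    return (rd5 - rd3) / rd5


def validate_sls(
    operons: list[SRPSOperon],
    depths: ExpressionTable,
    threshold: float = NRD_THRESHOLD,
    dg_rescue: bool = False,
    denominator: str = "max",
) -> list[ValidationRecord]:
    """NRD records for every stabilizer-type control SL with depth data.

    Only SSLs and STSLs are tested (terminators are expected to drop depth for
    a different reason). ``dg_rescue`` applies the secondary check: a failing
    SL is rescued when per-gene depth correlates positively with |dG| of the
    controlling SLs across its operon.
    """
    nrd_fn = nrd if denominator == "max" else _nrd_5prime
    records = []
    for op in operons:
        for c in op.control_sls:
            if c.terminal or c.sl.label not in STABILIZER_LABELS:
                continue
            up = op.genes[c.after_index]
            down = (
                op.genes[c.after_index + 1]
                if c.after_index + 1 < len(op.genes)
                else None
            )
            rd5 = depths.get(up)
            rd3 = depths.get(down) if down is not None else None
            if rd5 is None or rd3 is None:
                records.append(
                    ValidationRecord(c.sl.id, op.operon_id, rd5, rd3, None, None, "no_data")
                )
                continue
            if max(rd5, rd3) == 0:
                records.append(
                    ValidationRecord(c.sl.id, op.operon_id, rd5, rd3, None, None, "undefined")
                )
                continue
            value = nrd_fn(rd5, rd3)
            passed = value > threshold
            status = "ok"
            if not passed and dg_rescue and _dg_depth_correlated(op, depths):
                passed, status = True, "rescued"
            records.append(
                ValidationRecord(c.sl.id, op.operon_id, rd5, rd3, value, passed, status)
            )
    return records


def _dg_depth_correlated(op: SRPSOperon, depths: ExpressionTable) -> bool:
    from .ratio import predict_ratio

    pred = predict_ratio(op)
    xs, ys = [], []
    for g in pred.per_gene:
        d = depths.get(g.gene_id)
        if d is None or g.dG_assigned is None:
            continue
        xs.append(abs(g.dG_assigned))
        ys.append(d)
    if len(xs) < 3 or len(set(xs)) < 2 or len(set(ys)) < 2:
        return False
    r, _ = stats.pearsonr(xs, ys)
    return r > 0


def correlate(
    pred: RatioPrediction,
    expr: ExpressionTable,
    pseudocount: float | None = None,
) -> CorrelationReport:
    """Pearson r between predicted values and log10 abundances.

    Genes with zero abundance are excluded pairwise unless a ``pseudocount``
    is supplied; r is not computed for fewer than three genes or when either
    vector has zero variance.
    """
    xs, ys = [], []
    for g in pred.per_gene:
        a = expr.get(g.gene_id)
        if a is None:
            continue
        if a <= 0:
            if pseudocount is None:
                continue
            a = a + pseudocount
        xs.append(g.value)
        ys.append(math.log10(a))
    n = len(xs)
    if n < 3:
        return CorrelationReport(pred.operon_id, None, n, expr.kind, "fewer than 3 genes")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return CorrelationReport(pred.operon_id, None, n, expr.kind, "zero variance")
    r, _ = stats.pearsonr(xs, ys)
    return CorrelationReport(pred.operon_id, float(r), n, expr.kind)
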