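"""SRPS operon identification and stoichiometry-ratio prediction.

An operon is SRPS when at least one of its intergenic, intra-operonic stable
stem-loops is a stabilizer (SSL or STSL). Within such an operon every gene is
controlled by the nearest stem-loop at-or-downstream of its 3' end (its
upstream control unit, UCU); a gene with no stem-loop left before the operon
end is predicted silent. The per-gene ratio is the controlling SL's dG
divided by the dG of the 5'-most control SL, rounded to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

from .discovery import StemLoop
from .io import GeneAnnotation, OperonMap

STABILIZER_LABELS = ("SSL", "STSL")


@dataclass(frozen=True)
class ControlSL:
    """A control stem-loop positioned after the operon gene at ``after_index``."""

    sl: StemLoop
    after_index: int  # 0-based index into the operon's gene list
    terminal: bool = False  # attached from the inter-operonic 3' end


@dataclass(frozen=True)
class SRPSOperon:
    operon_id: int
    genes: tuple[str, ...]
    strand: str
    control_sls: tuple[ControlSL, ...]  # transcription order

    def __post_init__(self):
        labels = {c.sl.label for c in self.control_sls if not c.terminal}
        if not labels & set(STABILIZER_LABELS):
            raise ValueError(
                f"operon {self.operon_id}: no intra-operonic SSL/STSL control SL"
            )


@dataclass(frozen=True)
class GeneRatio:
    gene_id: str
    controlling_sl: str | None
    dG_assigned: float | None  # None marks the zero-expression case
    value: float


@dataclass(frozen=True)
class RatioPrediction:
    operon_id: int
    per_gene: tuple[GeneRatio, ...]

    @property
    def values(self) -> list[float]:
        return [g.value for g in self.per_gene]


def _gene_index(op: OperonMap) -> dict[str, int]:
    return {g: i for i, g in enumerate(op.genes)}


#: default maximum distance (nt) between an operon's last gene and an
#: attached terminal stem-loop; intrinsic terminators live in the 3' UTR,
#: so distant downstream SLs are not credited to the operon
TERMINAL_MAX_DIST = 300


def identify_srps(
    classified_sls: list[StemLoop],
    operons: list[OperonMap],
    genes: list[GeneAnnotation] | None = None,
    terminal_max_dist: int = TERMINAL_MAX_DIST,
) -> list[SRPSOperon]:
    """Operons harboring >=1 intergenic intra-operonic SSL/STSL.

    Intra-operonic SLs are placed after their upstream flanking gene; an
    inter-operonic SL trailing the operon's last gene is attached as the
    terminal (typically terminator) control SL, provided it lies within
    ``terminal_max_dist`` nt of that gene (checked when ``genes`` is given).
    """
    by_id = {op.operon_id: op for op in operons}
    gene_by_id = {g.gene_id: g for g in genes} if genes is not None else None
    internal: dict[int, list[ControlSL]] = {}
    terminal: dict[int, ControlSL] = {}
    for sl in classified_sls:
        if sl.category != "intergenic" or sl.operon_id is None:
            continue
        op = by_id.get(sl.operon_id)
        if op is None:
            continue
        gi = _gene_index(op)
        if sl.operon_context == "intra_operonic":
            idx = gi[sl.upstream_gene]
            internal.setdefault(op.operon_id, []).append(ControlSL(sl, idx))
        elif (
            sl.operon_context == "inter_operonic"
            and sl.upstream_gene is not None
            and sl.upstream_gene == op.genes[-1]
        ):
            if gene_by_id is not None:
                last = gene_by_id.get(sl.upstream_gene)
                if last is not None:
                    dist = (
                        sl.start - last.end - 1
                        if op.strand == "+"
                        else last.start - sl.end - 1
                    )
                    if not (0 <= dist <= terminal_max_dist):
                        continue
            cand = ControlSL(sl, len(op.genes) - 1, terminal=True)
            cur = terminal.get(op.operon_id)
            # nearest SL downstream of the last gene wins
            if cur is None or _distance_to_operon_end(cand.sl, op) < _distance_to_operon_end(cur.sl, op):
                terminal[op.operon_id] = cand
    out = []
    for oid, controls in sorted(internal.items()):
        labels = {c.sl.label for c in controls}
        if not labels & set(STABILIZER_LABELS):
            continue
        if oid in terminal:
            controls = controls + [terminal[oid]]
        controls.sort(key=lambda c: (c.after_index, c.terminal))
        op = by_id[oid]
        out.append(SRPSOperon(oid, op.genes, op.strand, tuple(controls)))
    return out


def _distance_to_operon_end(sl: StemLoop, op: OperonMap) -> int:
    # transcription-orientation distance proxy: genomic coordinate toward 3'
    return sl.start if op.strand == "+" else -sl.end


def predict_ratio(op: SRPSOperon, tsl_controls: bool = True) -> RatioPrediction:
    """Per-gene normalized stoichiometry values for one SRPS operon."""
    controls = [
        c for c in op.control_sls if tsl_controls or c.sl.label in STABILIZER_LABELS
    ]
    if not controls:
        raise ValueError(f"operon {op.operon_id}: no control SLs")
    dg_first = controls[0].sl.dG
    per_gene = []
    for i, gene in enumerate(op.genes):
        ctrl = next((c for c in controls if c.after_index >= i), None)
        if ctrl is None:
            per_gene.append(GeneRatio(gene, None, None, 0.0))
        else:
            per_gene.append(
                GeneRatio(
                    gene,
                    ctrl.sl.id,
                    ctrl.sl.dG,
                    round(ctrl.sl.dG / dg_first, 2),
                )
            )
    return RatioPrediction(op.operon_id, tuple(per_gene))
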