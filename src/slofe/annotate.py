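"""Mapping stem-loops onto genes and operons.

Each SL gets exactly one of five positional categories relative to the gene
annotation, and each intergenic SL an intra- vs inter-operonic context based
on its flanking genes on the strand it folded on.
"""

from __future__ import annotations

import dataclasses

from intervaltree import IntervalTree

from .discovery import StemLoop
from .errors import CrossReferenceError
from .io import GeneAnnotation, OperonMap

CATEGORIES = (
    "intragenic",
    "intergenic",
    "overlapped_on_3",
    "overlapped_on_5",
    "overlapped_with_two_genes",
)


class GeneIndex:
    """Interval and strand-ordered lookups over one contig's genes."""

    def __init__(self, genes: list[GeneAnnotation], contig: str | None = None):
        self.genes = [g for g in genes if contig is None or g.contig == contig]
        self.tree = IntervalTree()
        for g in self.genes:
            self.tree[g.start : g.end + 1] = g
        self.by_strand = {
            "+": sorted((g for g in self.genes if g.strand == "+"), key=lambda g: g.start),
            "-": sorted((g for g in self.genes if g.strand == "-"), key=lambda g: g.start),
        }

    def overlapping(self, start: int, end: int) -> list[GeneAnnotation]:
        return sorted((iv.data for iv in self.tree.overlap(start, end + 1)),
                      key=lambda g: g.start)

    def flanking(self, sl: StemLoop) -> tuple[GeneAnnotation | None, GeneAnnotation | None]:
        """(upstream, downstream) genes in transcription orientation on the
        SL's strand; genes overlapping the SL do not count as flanking."""
        same = self.by_strand.get(sl.strand, [])
        before = [g for g in same if g.end < sl.start]
        after = [g for g in same if g.start > sl.end]
        left = max(before, key=lambda g: g.end, default=None)
        right = min(after, key=lambda g: g.start, default=None)
        if sl.strand == "+":
            return left, right
        return right, left


def categorize_position(sl: StemLoop, genes: list[GeneAnnotation] | GeneIndex) -> str:
    """One of the five positional categories for this SL."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, sl.contig)
    ov = index.overlapping(sl.start, sl.end)
    if not ov:
        return "intergenic"
    if len(ov) >= 2:
        return "overlapped_with_two_genes"
    g = ov[0]
    inside_left = sl.start >= g.start
    inside_right = sl.end <= g.end
    if inside_left and inside_right:
        return "intragenic"
    # straddling one gene boundary: which gene end is crossed, in the gene's
    # own orientation; an SL engulfing a whole gene counts as crossing its 3'
    crosses_right = not inside_right
    if g.strand == "+":
        return "overlapped_on_3" if crosses_right else "overlapped_on_5"
    return "overlapped_on_3" if not inside_left else "overlapped_on_5"


def operon_context(
    sl: StemLoop,
    operons: list[OperonMap],
    genes: list[GeneAnnotation] | GeneIndex,
) -> tuple[str, int | None, str | None, str | None]:
    """(context, operon_id, upstream_gene, downstream_gene) for one SL.

    Only intergenic SLs get a context; both flanking genes in the same operon
    means intra-operonic, anything else (different operons, or an operon edge)
    is inter-operonic. An SL with no flanking gene on its strand at all is
    not_applicable.
    """
    if sl.category != "intergenic":
        return "not_applicable", None, None, None
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, sl.contig)
    up, down = index.flanking(sl)
    if up is None and down is None:
        return "not_applicable", None, None, None
    op_of = {g: op.operon_id for op in operons for g in op.genes}
    for g in (up, down):
        if g is not None and g.gene_id not in op_of:
            raise CrossReferenceError(
                f"gene {g.gene_id} flanks {sl.id} but is absent from the operon map"
            )
    up_id = up.gene_id if up else None
    down_id = down.gene_id if down else None
    if up and down and op_of[up_id] == op_of[down_id]:
        return "intra_operonic", op_of[up_id], up_id, down_id
    # attribute the SL to its upstream operon when it sits between operons
    oid = op_of[up_id] if up else op_of[down_id]
    return "inter_operonic", oid, up_id, down_id


def annotate_all(
    sls: list[StemLoop],
    genes: list[GeneAnnotation],
    operons: list[OperonMap] | None = None,
) -> list[StemLoop]:
    """Attach positional category (and operon context if operons given)."""
    indexes: dict[str, GeneIndex] = {}
    out = []
    for sl in sls:
        if sl.contig not in indexes:
            indexes[sl.contig] = GeneIndex(genes, sl.contig)
        index = indexes[sl.contig]
        cat = categorize_position(sl, index) if index.genes else "intergenic"
        sl = dataclasses.replace(sl, category=cat)
        if operons is not None and index.genes:
            ctx, oid, upg, downg = operon_context(sl, operons, index)
            sl = dataclasses.replace(
                sl, operon_context=ctx, operon_id=oid,
                upstream_gene=upg, downstream_gene=downg,
            )
        elif operons is not None:
            sl = dataclasses.replace(sl, operon_context="not_applicable")
        out.append(sl)
    return out
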