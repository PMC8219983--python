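"""Readers and writers for the external formats used by the pipeline.

Genomic coordinates are 1-based inclusive throughout (GFF3 convention); the
only place the 0-based half-open convention appears is the BED export at the
write boundary. DNA is stored uppercase over {A,C,G,T,N}; RNA input (U) is
converted to T on read, and stem-loop sequences are reported as RNA.
"""

from __future__ import annotations

import dataclasses
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .errors import CrossReferenceError, FormatError

_DNA_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """A single contig: identifier plus uppercase DNA sequence."""

    id: str
    sequence: str

    def __post_init__(self):
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise FormatError(
                f"illegal characters in genome sequence {self.id!r}: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int, strand: str = "+") -> str:
        """1-based inclusive slice, reverse-complemented on the minus strand."""
        s = self.sequence[start - 1 : end]
        return revcomp(s) if strand == "-" else s

    def reverse_complement(self) -> "GenomeRecord":
        return GenomeRecord(self.id, revcomp(self.sequence))


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    contig: str = ""

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"gene {self.gene_id}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class OperonMap:
    """Ordered genes of one operon, in transcription order."""

    operon_id: int
    genes: tuple[str, ...]
    strand: str


@dataclass
class ExpressionTable:
    """Per-gene nonnegative abundances (read depth, transcript or protein)."""

    values: dict[str, float]
    kind: str = "read_depth"

    def __post_init__(self):
        neg = {g: v for g, v in self.values.items() if v < 0}
        if neg:
            raise FormatError(f"negative abundances: {neg}")

    def get(self, gene_id: str):
        return self.values.get(gene_id)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.values


def read_genome(path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA genome; uppercases and converts U to T."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(GenomeRecord(rec.id, seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def read_annotation(path) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 or GenBank (by file extension)."""
    path = Path(path)
    if path.suffix.lower() in {".gb", ".gbk", ".genbank", ".gbff"}:
        return _read_genbank(path)
    return _read_gff3(path)


def _read_gff3(path) -> list[GeneAnnotation]:
    import gffutils

    with tempfile.NamedTemporaryFile(suffix=".db") as tf:
        db = gffutils.create_db(
            str(path), tf.name, force=True, keep_order=True, merge_strategy="create_unique"
        )
        feats = list(db.features_of_type("gene"))
        if not feats:  # annotations that only carry CDS features
            feats = list(db.features_of_type("CDS"))
        genes = []
        for f in feats:
            gid = f.attributes.get("locus_tag", f.attributes.get("ID", [f.id]))[0]
            genes.append(GeneAnnotation(gid, f.start, f.end, f.strand, f.seqid))
    return genes


def _read_genbank(path) -> list[GeneAnnotation]:
    genes = []
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type != "gene":
                continue
            gid = feat.qualifiers.get("locus_tag", feat.qualifiers.get("gene", ["?"]))[0]
            strand = "-" if feat.location.strand == -1 else "+"
            genes.append(
                GeneAnnotation(
                    gid, int(feat.location.start) + 1, int(feat.location.end), strand, rec.id
                )
            )
    if not genes:
        raise FormatError(f"no gene features in {path}")
    return genes


def write_gff3(genes: Iterable[GeneAnnotation], path, source: str = "slofe") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig, g.start)):
            attrs = f"ID={g.gene_id};locus_tag={g.gene_id}"
            fh.write(
                f"{g.contig}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_operon_map(path, genes: list[GeneAnnotation] | None = None) -> list[OperonMap]:
    """Read the operon map TSV (operon_id, gene_id, order, strand).

    If ``genes`` is given, every referenced gene must exist in the annotation
    and the gene order must be monotone in genomic coordinate (increasing on
    ``+``, decreasing on ``-``).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    required = {"operon_id", "gene_id", "order", "strand"}
    if not required.issubset(df.columns):
        raise FormatError(f"operon map must have columns {sorted(required)}")
    by_gene = {g.gene_id: g for g in genes} if genes is not None else None
    operons = []
    for oid, grp in df.groupby("operon_id", sort=True):
        strands = set(grp["strand"])
        if len(strands) != 1:
            raise FormatError(f"operon {oid}: mixed strands {sorted(strands)}")
        strand = strands.pop()
        ordered = tuple(grp.sort_values("order")["gene_id"])
        if by_gene is not None:
            missing = [g for g in ordered if g not in by_gene]
            if missing:
                raise CrossReferenceError(
                    f"operon {oid}: genes absent from annotation: {missing}"
                )
            starts = [by_gene[g].start for g in ordered]
            if strand == "-":
                starts = starts[::-1]
            if starts != sorted(starts):
                raise FormatError(f"operon {oid}: gene order not monotone on {strand}")
        operons.append(OperonMap(int(oid), ordered, strand))
    return operons


def write_operon_map(operons: Iterable[OperonMap], path) -> None:
    rows = [
        {"operon_id": op.operon_id, "gene_id": g, "order": i + 1, "strand": op.strand}
        for op in operons
        for i, g in enumerate(op.genes)
    ]
    pd.DataFrame(rows, columns=["operon_id", "gene_id", "order", "strand"]).to_csv(
        path, sep="\t", index=False
    )


def read_expression(path, kind: str = "read_depth") -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str},
                 float_precision="round_trip")
    if not {"gene_id", "value"}.issubset(df.columns):
        raise FormatError("expression table must have columns gene_id, value")
    return ExpressionTable(dict(zip(df["gene_id"], df["value"].astype(float))), kind)


def write_expression(table: ExpressionTable, path) -> None:
    pd.DataFrame(
        {"gene_id": list(table.values), "value": list(table.values.values())}
    ).to_csv(path, sep="\t", index=False)


# --- stem-loop tables ------------------------------------------------------

#: columns of the stem-loop TSV, in order; None-valued fields serialize empty
SL_COLUMNS = [
    "id", "contig", "start", "end", "strand", "sequence", "structure", "dG",
    "stem_len", "loop_len", "polyU_len", "U_content", "tail_position",
    "category", "operon_context", "operon_id", "upstream_gene",
    "downstream_gene", "label", "S1", "S2", "S3", "S4", "S4_norm",
]


def write_sl_table(sls, path, header_comment: str | None = None) -> None:
    """Write stem-loops as TSV; round-trips losslessly through read_sl_table."""
    from .discovery import StemLoop  # local import to avoid a cycle

    rows = []
    for sl in sls:
        d = dataclasses.asdict(sl)
        d["stem_len"] = sl.stem_len
        d["loop_len"] = sl.loop_len
        rows.append({c: d.get(c) for c in SL_COLUMNS})
    df = pd.DataFrame(rows, columns=SL_COLUMNS)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_sl_table(path):
    from .discovery import StemLoop

    df = pd.read_csv(path, sep="\t", comment="#", dtype={"contig": str},
                 float_precision="round_trip")
    sls = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        kwargs = {}
        for f in dataclasses.fields(StemLoop):
            if f.name in ("stem_len", "loop_len"):
                continue
            v = d.get(f.name)
            if pd.isna(v):
                v = None
            kwargs[f.name] = v
        for key in ("start", "end"):
            kwargs[key] = int(kwargs[key])
        if kwargs.get("operon_id") is not None:
            kwargs["operon_id"] = int(kwargs["operon_id"])
        for key in ("polyU_len", "U_content"):
            if kwargs.get(key) is not None:
                kwargs[key] = int(kwargs[key])
        sls.append(StemLoop(**kwargs))
    return sls


def write_sl_bed(sls, path) -> None:
    """BED6 export (0-based half-open) of stem-loop spans."""
    with open(path, "w") as fh:
        for sl in sls:
            fh.write(
                f"{sl.contig}\t{sl.start - 1}\t{sl.end}\t{sl.id}\t0\t{sl.strand}\n"
            )


def extract_cds(genome: GenomeRecord, genes: Iterable[GeneAnnotation]) -> dict[str, str]:
    """Coding sequences (sense strand, DNA) for genes on one contig."""
    out = {}
    for g in genes:
        if g.contig and g.contig != genome.id:
            continue
        out[g.gene_id] = genome.subseq(g.start, g.end, g.strand)
    return out
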