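"""Genome-wide discovery of candidate stem-loops.

The scanner finds, on both strands, every maximal hairpin candidate under a
descriptor of stem/loop bounds: for each possible loop window the stem is
grown outward from the obligatory innermost pair, preferring pairs and
spending at most ``max_mismatch`` mispairs, until the stem bound or an
unextendable position is reached (trailing mispairs are trimmed so candidates
end on a pair). Bulges are not enumerated at scan time; they emerge at the
folding step, where each candidate span is refolded to its minimum-free-energy
single hairpin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .energy import fold_hairpin, pairable
from .io import GenomeRecord, revcomp


@dataclass(frozen=True)
class Descriptor:
    """Scan constraints for hairpin candidates (lengths in nt)."""

    stem_min: int = 6
    stem_max: int = 40
    loop_min: int = 3
    loop_max: int = 30
    allow_GU: bool = True
    max_mismatch: int = 2
    max_bulge: int = 2

    def __post_init__(self):
        if not (1 <= self.stem_min <= self.stem_max):
            raise ValueError("need 1 <= stem_min <= stem_max")
        if not (3 <= self.loop_min <= self.loop_max):
            raise ValueError("need 3 <= loop_min <= loop_max")


@dataclass
class StemLoop:
    """A folded stem-loop anchored on the genome.

    ``start``/``end`` are 1-based inclusive genomic coordinates of the folded
    span; ``sequence`` is the RNA read 5'->3' on ``strand`` (i.e. the reverse
    complement of the genomic slice for minus-strand SLs). Downstream
    annotations (U-features, positional category, operon context,
    classification label, stability scores) are attached as optional fields.
    """

    id: str
    contig: str
    start: int
    end: int
    strand: str
    sequence: str
    structure: str
    dG: float
    # --- annotations attached by later pipeline stages ---
    polyU_len: int | None = None
    U_content: int | None = None
    tail_position: str | None = None
    category: str | None = None
    operon_context: str | None = None
    operon_id: int | None = None
    upstream_gene: str | None = None
    downstream_gene: str | None = None
    label: str | None = None
    S1: float | None = None
    S2: float | None = None
    S3: float | None = None
    S4: float | None = None
    S4_norm: float | None = None

    def __post_init__(self):
        if len(self.sequence) != len(self.structure):
            raise ValueError(f"{self.id}: |structure| != |sequence|")
        if self.structure.count("(") != self.structure.count(")"):
            raise ValueError(f"{self.id}: unbalanced brackets")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(f"{self.id}: span does not match sequence length")

    @property
    def stem_len(self) -> int:
        """Paired positions on one side of the stem (sl)."""
        return self.structure.count("(")

    @property
    def loop_len(self) -> int:
        op = self.structure.rfind("(")
        cl = self.structure.find(")")
        if op < 0:
            return 0
        return cl - op - 1

    @property
    def total_len(self) -> int:
        """Stem-loop length L."""
        return self.end - self.start + 1


def _scan_strand(seq: str, d: Descriptor) -> set[tuple[int, int]]:
    """Maximal candidate spans (0-based inclusive) on one strand."""
    n = len(seq)
    spans: set[tuple[int, int]] = set()
    for loop_len in range(d.loop_min, d.loop_max + 1):
        for a in range(0, n - loop_len - 1):
            b = a + loop_len + 1
            if b >= n:
                break
            if not pairable(seq[a], seq[b], d.allow_GU):
                continue
            p, q = a, b
            op, oq = a, b  # outermost *paired* positions
            npairs, mm = 1, 0
            while npairs < d.stem_max and p > 0 and q < n - 1:
                if pairable(seq[p - 1], seq[q + 1], d.allow_GU):
                    p, q = p - 1, q + 1
                    op, oq = p, q
                    npairs += 1
                elif mm < d.max_mismatch:
                    p, q = p - 1, q + 1
                    mm += 1
                else:
                    break
            if npairs >= d.stem_min and "N" not in seq[op : oq + 1]:
                spans.add((op, oq))
    return spans


def scan_motifs(genome: GenomeRecord, d: Descriptor | None = None) -> list[tuple[int, int, str]]:
    """Candidate spans ``(start, end, strand)`` in 1-based genomic coordinates."""
    d = d or Descriptor()
    n = genome.length
    out = []
    for s0, e0 in _scan_strand(genome.sequence, d):
        out.append((s0 + 1, e0 + 1, "+"))
    rc = revcomp(genome.sequence)
    for s0, e0 in _scan_strand(rc, d):
        out.append((n - e0, n - s0, "-"))
    out.sort()
    return out


def fold_candidate(seq: str, backend: str = "internal") -> tuple[str, float]:
    """Secondary structure and dG (kcal/mol) of one candidate sequence."""
    return fold_hairpin(seq, backend=backend)


def discover(
    genome: GenomeRecord,
    d: Descriptor | None = None,
    backend: str = "internal",
) -> list[StemLoop]:
    """Scan both strands and fold every candidate; drop foldless candidates."""
    d = d or Descriptor()
    sls = []
    for start, end, strand in scan_motifs(genome, d):
        dna = genome.subseq(start, end, strand)
        structure, dg = fold_candidate(dna, backend=backend)
        if "(" not in structure:
            continue
        rna = dna.replace("T", "U")
        sls.append(
            StemLoop(
                id=f"SL_{genome.id}_{start}_{end}_{strand}",
                contig=genome.id,
                start=start,
                end=end,
                strand=strand,
                sequence=rna,
                structure=structure,
                dG=dg,
            )
        )
    return sls
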