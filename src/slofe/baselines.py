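"""Sequence-based expression predictors used as comparison baselines.

Five per-gene predictors, each turned into an operon ratio by dividing by the
first gene's score:

* CAI  — codon adaptation index (Sharp & Li 1987): geometric mean of the
  relative adaptiveness w_c = f_c / max(f over synonymous codons), estimated
  from a reference gene set; single-codon families (Met, Trp) and stops are
  excluded.
* RCBS — relative codon usage bias (Roymondal et al. 2009): self-referential;
  d_xyz = (f_xyz - f1(x) f2(y) f3(z)) / (f1(x) f2(y) f3(z)) with positional
  base frequencies from the gene itself, RCBS = prod(1 + d)^(1/L) - 1.
* RCA  — relative codon adaptation (Fox & Erill 2010): geometric mean of
  RCA_xyz = f_xyz / (f1(x) f2(y) f3(z)), all frequencies from the reference.
* MELP — MILC-based expression level predictor (Supek & Vlahovicek 2005):
  MELP = MILC(gene | whole reference) / MILC(gene | highly-expressed set),
  where MILC sums per-amino-acid goodness-of-fit terms
  M_a = 2 * sum_c n_c ln(f_c^gene / f_c^ref) over codons, normalized by gene
  length with the correction C = sum_a (k_a - 1) / L.
* gene order — strictly decreasing values n, n-1, ..., 1 scaled by n.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

from .io import OperonMap

METHODS = ("CAI", "RCBS", "RCA", "MELP", "order")

_STOPS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_FAMILIES: dict[str, list[str]] = {}
for _c, _a in _CODON_TABLE.items():
    _FAMILIES.setdefault(_a, []).append(_c)

_MIN_W = 0.01  # floor for unobserved codons, avoids zero geometric means


def split_codons(seq: str, gene_id: str = "?") -> list[str]:
    """Codons of a CDS; internal stops are skipped with a warning."""
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3:
        raise ValueError(f"{gene_id}: CDS length not divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in _STOPS:
        codons = codons[:-1]
    bad = [c for c in codons if c in _STOPS]
    if bad:
        warnings.warn(f"{gene_id}: internal stop codon(s) skipped")
        codons = [c for c in codons if c not in _STOPS]
    unknown = [c for c in codons if c not in _CODON_TABLE]
    if unknown:
        raise ValueError(f"{gene_id}: invalid codons {unknown[:3]}")
    return codons


def _positional_freqs(codons: list[str]) -> list[dict[str, float]]:
    out = []
    for pos in range(3):
        cnt = Counter(c[pos] for c in codons)
        tot = sum(cnt.values())
        out.append({b: cnt.get(b, 0) / tot for b in "ACGT"})
    return out


@dataclass
class CodonUsageModel:
    """Codon statistics of a reference gene set for one scoring method."""

    method: str
    weights: dict[str, float] = field(default_factory=dict)
    codon_freq: dict[str, float] = field(default_factory=dict)
    family_freq: dict[str, float] = field(default_factory=dict)
    positional: list[dict[str, float]] = field(default_factory=list)

    @classmethod
    def from_reference(cls, cds_seqs: dict[str, str], method: str) -> "CodonUsageModel":
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; use one of {METHODS}")
        counts: Counter[str] = Counter()
        for gid, seq in cds_seqs.items():
            counts.update(split_codons(seq, gid))
        total = sum(counts.values())
        codon_freq = {c: counts.get(c, 0) / total for c in _CODON_TABLE}
        # within-family relative frequencies
        family_freq = {}
        weights = {}
        for aa, fam in _FAMILIES.items():
            fam_tot = sum(counts.get(c, 0) for c in fam)
            fmax = max((counts.get(c, 0) for c in fam), default=0)
            for c in fam:
                family_freq[c] = counts.get(c, 0) / fam_tot if fam_tot else 1 / len(fam)
                if fmax == 0:
                    weights[c] = 1.0
                else:
                    weights[c] = max(counts.get(c, 0) / fmax, _MIN_W)
        model = cls(method, weights, codon_freq, family_freq)
        model.positional = _positional_freqs(list(counts.elements()))
        return model


def score_gene(seq: str, model: CodonUsageModel, gene_id: str = "?") -> float:
    """Per-gene expression proxy under the model's method."""
    codons = split_codons(seq, gene_id)
    if not codons:
        raise ValueError(f"{gene_id}: empty CDS")
    if model.method == "CAI":
        vals = [
            math.log(model.weights[c])
            for c in codons
            if len(_FAMILIES[_CODON_TABLE[c]]) > 1  # skip Met/Trp
        ]
        return math.exp(sum(vals) / len(vals)) if vals else 1.0
    if model.method == "RCBS":
        pos = _positional_freqs(codons)
        cnt = Counter(codons)
        L = len(codons)
        log_prod = 0.0
        for c, n in cnt.items():
            expected = pos[0][c[0]] * pos[1][c[1]] * pos[2][c[2]]
            f = n / L
            d = (f - expected) / expected
            log_prod += n * math.log1p(d)
        return math.exp(log_prod / L) - 1.0
    if model.method == "RCA":
        vals = []
        for c in codons:
            expected = (
                model.positional[0][c[0]]
                * model.positional[1][c[1]]
                * model.positional[2][c[2]]
            )
            # floors keep unobserved codons/bases finite without dominating
            w = max(model.codon_freq.get(c, 0.0), _MIN_W * 1e-2) / max(expected, 1e-9)
            vals.append(math.log(w))
        return math.exp(sum(vals) / len(vals))
    raise ValueError(f"score_gene does not apply to method {model.method!r}")


def milc(seq: str, ref_family_freq: dict[str, float], gene_id: str = "?") -> float:
    """MILC distance of one gene's codon usage from a reference usage."""
    codons = split_codons(seq, gene_id)
    cnt = Counter(codons)
    fam_counts: dict[str, Counter] = {}
    for c, n in cnt.items():
        fam_counts.setdefault(_CODON_TABLE[c], Counter())[c] = n
    L = sum(cnt.values())
    total = 0.0
    dof = 0
    for aa, fc in fam_counts.items():
        fam = _FAMILIES[aa]
        if len(fam) == 1:
            continue
        na = sum(fc.values())
        for c in fam:
            n = fc.get(c, 0)
            if n == 0:
                continue
            fg = n / na
            fr = max(ref_family_freq.get(c, 0.0), 1e-4)
            total += 2.0 * n * math.log(fg / fr)
        dof += len(fam) - 1
    correction = dof / L
    return total / L - correction


def melp_score(
    seq: str,
    genome_model: CodonUsageModel,
    he_model: CodonUsageModel,
    gene_id: str = "?",
) -> float:
    denom = milc(seq, he_model.family_freq, gene_id)
    num = milc(seq, genome_model.family_freq, gene_id)
    if abs(denom) < 1e-9:
        return float("nan")
    return num / denom


def highly_expressed_reference(
    cds_seqs: dict[str, str], fraction: float = 0.10
) -> dict[str, str]:
    """Default highly-expressed set for MELP: the top fraction of genes by CAI."""
    cai_model = CodonUsageModel.from_reference(cds_seqs, "CAI")
    ranked = sorted(
        cds_seqs, key=lambda g: score_gene(cds_seqs[g], cai_model, g), reverse=True
    )
    k = max(2, int(round(fraction * len(ranked))))
    return {g: cds_seqs[g] for g in ranked[:k]}


def baseline_ratio(
    op: OperonMap,
    method: str,
    cds_seqs: dict[str, str],
    reference: dict[str, str] | None = None,
) -> list[tuple[str, float]]:
    """Per-gene operon ratio under one baseline, normalized by the first gene.

    ``reference`` defaults to all supplied CDS; genes without a CDS are
    dropped with a warning.
    """
    genes = [g for g in op.genes if g in cds_seqs]
    for g in op.genes:
        if g not in cds_seqs:
            warnings.warn(f"operon {op.operon_id}: no CDS for {g}; dropped")
    if not genes:
        return []
    if method == "order":
        n = len(genes)
        return [(g, (n - i) / n) for i, g in enumerate(genes)]
    reference = reference or cds_seqs
    if method == "MELP":
        genome_model = CodonUsageModel.from_reference(reference, "MELP")
        he_model = CodonUsageModel.from_reference(
            highly_expressed_reference(reference), "MELP"
        )
        scores = [melp_score(cds_seqs[g], genome_model, he_model, g) for g in genes]
    else:
        model = CodonUsageModel.from_reference(reference, method)
        scores = [score_gene(cds_seqs[g], model, g) for g in genes]
    first = scores[0]
    if first == 0 or math.isnan(first):
        return [(g, float("nan")) for g in genes]
    return [(g, s / first) for g, s in zip(genes, scores)]
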