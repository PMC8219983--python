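"""Synthetic genomes with planted stem-loops of known class and dG.

The generator emulates the regulatory architecture the pipeline is built to
recover: operons of protein-coding genes whose intergenic regions carry
hairpins of designed free energy, each followed by a 10-nt window written to
satisfy exactly one classification rule set (SSL/STSL/TSL), plus read-depth
and protein tables in which each gene's abundance is a monotone function of
the |dG| of its controlling stem-loop with multiplicative log-normal noise.

Three hairpin tiers keep the design consistent with the pipeline's own
selection rules: descending |dG| along the operon makes every stabilizer SL a
sharp (>2x) depth step (so its NRD exceeds 0.5 at the default noise), while
stem/loop geometries are co-chosen so all tiers' S4 stability scores stay
within 60% of the cohort minimum and survive stable-SL selection.

Every planted hairpin is verified end-to-end at generation time: the local
region is rescanned and refolded with the default descriptor, and the planted
span must come back as the lowest-dG stem-loop with its intended structure
and class; pads and windows are resampled until it does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features
from .classify import classify
from .discovery import Descriptor, StemLoop, discover
from .energy import fold_hairpin, pairable
from .errors import GenerationError
from .io import (
    ExpressionTable,
    GeneAnnotation,
    GenomeRecord,
    OperonMap,
    revcomp,
    write_expression,
    write_gff3,
    write_operon_map,
)

DG_REF = 40.0  # |dG| scale for the depth model


@dataclass(frozen=True)
class Tier:
    """Geometry and free-energy band of one planted-hairpin tier."""

    dg_band: tuple[float, float]  # (low, high), kcal/mol
    stem_len: int
    loop_len: tuple[int, int]


TIERS: dict[str, Tier] = {
    "strong": Tier((-42.0, -36.0), 16, (26, 30)),
    "mid": Tier((-29.5, -26.5), 12, (10, 12)),
    "weak": Tier((-20.5, -18.0), 14, (3, 4)),
}


@dataclass(frozen=True)
class PlantedSL:
    after_index: int  # SL sits after this gene (0-based, transcription order)
    uclass: str  # SSL | STSL | TSL
    tier: str  # key into TIERS
    terminal: bool = False  # placed after the operon's last gene


@dataclass(frozen=True)
class OperonPlan:
    n_genes: int
    strand: str
    sls: tuple[PlantedSL, ...]

    @property
    def is_srps(self) -> bool:
        return any(s.uclass in ("SSL", "STSL") and not s.terminal for s in self.sls)


def default_plans() -> tuple[OperonPlan, ...]:
    """Ten operons: five SRPS layouts, five negatives (incl. an operon whose
    only internal SL is a terminator, which must not be called SRPS)."""
    return (
        OperonPlan(4, "+", (PlantedSL(0, "SSL", "strong"), PlantedSL(1, "STSL", "mid"),
                            PlantedSL(3, "TSL", "weak", terminal=True))),
        OperonPlan(4, "-", (PlantedSL(0, "SSL", "strong"), PlantedSL(2, "STSL", "mid"),
                            PlantedSL(3, "TSL", "weak", terminal=True))),
        OperonPlan(4, "+", (PlantedSL(0, "SSL", "strong"), PlantedSL(1, "STSL", "mid"))),
        OperonPlan(3, "-", (PlantedSL(0, "SSL", "strong"),)),
        OperonPlan(3, "+", (PlantedSL(0, "SSL", "strong"), PlantedSL(1, "STSL", "mid"),
                            PlantedSL(2, "TSL", "weak", terminal=True))),
        OperonPlan(3, "-", (PlantedSL(1, "TSL", "mid"),)),  # internal TSL only
        OperonPlan(4, "+", (PlantedSL(3, "TSL", "weak", terminal=True),)),
        OperonPlan(3, "-", ()),
        OperonPlan(1, "+", ()),
        OperonPlan(2, "-", ()),
    )


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    plans: tuple[OperonPlan, ...] = field(default_factory=default_plans)
    noise_sigma: float = 0.1  # log10-scale expression noise
    gc: float = 0.37  # background GC content (Clostridium-like)
    gene_codons: tuple[int, int] = (60, 110)
    intergenic_len: tuple[int, int] = (60, 120)
    pad_len: tuple[int, int] = (12, 20)
    spacer_len: tuple[int, int] = (150, 220)
    depth_gamma: float = 6.0  # depth ~ (|dG|/DG_REF) ** gamma
    depth_scale: float = 1000.0
    contig_id: str = "synthchr1"


@dataclass
class Fixture:
    spec: FixtureSpec
    genome: GenomeRecord
    genes: list[GeneAnnotation]
    operons: list[OperonMap]
    depths: ExpressionTable
    proteins: ExpressionTable
    truth_sls: pd.DataFrame
    truth_ratios: pd.DataFrame
    srps_operon_ids: set[int]
    paths: dict[str, Path] = field(default_factory=dict)


_SENSE_CODONS = sorted(set(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
) - {"TAA", "TAG", "TGA"})


def _random_background(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p)) if n else ""


def _random_gene(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    return "ATG" + "".join(body) + "TAA"


_WINDOW_TEMPLATES = {
    # 10-nt windows; 'N' slots are filled with non-T background
    "SSL": ["NNTNNNTNNN", "NNNNTNNNNN", "NNNNNNNNNN"],
    "STSL": ["TTNTTTNNNN", "TTTNTTNNNN", "NTTNTTNNTN"],
    "TSL": ["TTTTTTTNNN", "TTTTTTNTNN", "TTTTTNTTNN"],
}


def _make_window(rng: np.random.Generator, uclass: str) -> str:
    tpl = _WINDOW_TEMPLATES[uclass][rng.integers(len(_WINDOW_TEMPLATES[uclass]))]
    return "".join(
        c if c == "T" else "ACG"[rng.integers(3)] for c in tpl
    )


def make_hairpin(
    dg_band: tuple[float, float],
    uclass: str,
    rng: np.random.Generator,
    stem_len: int | None = None,
    loop_len: int | None = None,
    max_tries: int = 400,
) -> tuple[str, str, float, str]:
    """A planted hairpin plus its 10-nt class window.

    Returns ``(hairpin_dna, window_dna, dG, structure)`` where the internal
    fold of ``hairpin_dna`` is the designed perfect stem with dG inside
    ``dg_band`` and the window satisfies exactly the requested class's rules.
    """
    lo, hi = dg_band
    if lo > hi:
        raise GenerationError("dg_band must be (low, high)")
    tier = None
    if stem_len is None or loop_len is None:
        tier = _nearest_tier(dg_band)
        stem_len = stem_len or tier.stem_len
        loop_len = loop_len or int(rng.integers(tier.loop_len[0], tier.loop_len[1] + 1))
    # initial stem: GC-rich, then swap pair strengths toward the band
    pair_pool_strong = [("G", "C"), ("C", "G")]
    pair_pool_weak = [("A", "T"), ("T", "A")]
    pairs = [pair_pool_strong[rng.integers(2)] for _ in range(stem_len)]
    for _ in range(max_tries):
        loop = "".join("AC"[rng.integers(2)] for _ in range(loop_len))
        stem5 = "".join(p[0] for p in pairs)
        stem3 = "".join(p[1] for p in reversed(pairs))
        seq = stem5 + loop + stem3
        structure, dg = fold_hairpin(seq)
        expected = "(" * stem_len + "." * loop_len + ")" * stem_len
        if structure != expected:
            # misfold: reshuffle a random pair and loop
            i = int(rng.integers(stem_len))
            pairs[i] = (pair_pool_strong + pair_pool_weak)[rng.integers(4)]
            continue
        if dg < lo:  # too stable: weaken an interior GC pair
            cand = [i for i in range(1, stem_len) if pairs[i][0] in "GC"]
            if not cand:
                raise GenerationError("cannot weaken stem further")
            pairs[int(cand[rng.integers(len(cand))])] = pair_pool_weak[rng.integers(2)]
        elif dg > hi:  # too weak: strengthen an AU pair
            cand = [i for i in range(stem_len) if pairs[i][0] in "AT"]
            if not cand:
                raise GenerationError("cannot strengthen stem further")
            pairs[int(cand[rng.integers(len(cand))])] = pair_pool_strong[rng.integers(2)]
        else:
            window = _make_window(rng, uclass)
            return seq, window, dg, structure
    raise GenerationError(f"no hairpin found in band {dg_band} after {max_tries} tries")


def _nearest_tier(dg_band: tuple[float, float]) -> Tier:
    mid = sum(dg_band) / 2
    return min(TIERS.values(), key=lambda t: abs(sum(t.dg_band) / 2 - mid))


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _pairs_either_strand(x: str, y: str) -> bool:
    # a genomic juxtaposition pairs on the antisense too (GU is asymmetric:
    # sense A.C becomes antisense G.U), so guard both orientations
    return pairable(x, y) or pairable(_COMP[y], _COMP[x])


def _safe_pad(rng: np.random.Generator, n: int, gc: float, next_bases: str) -> str:
    """Background pad whose last bases cannot pair - on either strand - with
    the following bases (blocks outward stem extension across the junction)."""
    pad = list(_random_background(rng, n, gc))
    guard = min(3, len(pad), len(next_bases))
    bad = set(next_bases[:guard])
    for k in range(guard):
        i = len(pad) - 1 - k
        choices = [c for c in "ACGT" if all(not _pairs_either_strand(c, b) for b in bad)]
        if not choices:
            choices = ["C" if "G" not in bad else "A"]
        pad[i] = choices[int(rng.integers(len(choices)))]
    return "".join(pad)


def _verify_planted(
    region: str, hp_start: int, hp_end: int, dg: float, structure: str, uclass: str
) -> bool:
    """Re-scan a local sense region and demand the planted hairpin wins.

    The lowest-dG trimmed SL overlapping the planted span must be exactly the
    planted span with its designed structure, and its window must classify to
    the intended class.
    """
    g = GenomeRecord("region", region)
    sls = [s for s in discover(g, Descriptor()) if s.strand == "+"]
    trimmed = []
    for sl in sls:
        t = features.trim_flanks(sl)
        if t.end >= hp_start + 1 and t.start <= hp_end + 1:
            trimmed.append(t)
    if not trimmed:
        return False
    best = min(trimmed, key=lambda s: (s.dG, s.start))
    if (best.start, best.end) != (hp_start + 1, hp_end + 1):
        return False
    if best.structure != structure or abs(best.dG - dg) > 0.01:
        return False
    uf = features.u_features(best, g)
    return classify(uf).label == uclass


@dataclass
class _PlacedSL:
    plan: PlantedSL
    local_start: int  # 0-based inclusive, sense segment coords
    local_end: int
    dg: float
    sequence: str
    structure: str
    window: str


def _build_segment(
    plan: OperonPlan, rng: np.random.Generator, spec: FixtureSpec
) -> tuple[str, list[tuple[int, int]], list[_PlacedSL]]:
    """Sense-strand operon segment: genes, intergenic SLs, terminal SL."""
    sl_after = {s.after_index: s for s in plan.sls}
    parts: list[str] = []
    pos = 0
    gene_spans: list[tuple[int, int]] = []
    placed: list[_PlacedSL] = []
    for i in range(plan.n_genes):
        gene = _random_gene(rng, int(rng.integers(*spec.gene_codons)))
        gene_spans.append((pos, pos + len(gene) - 1))
        parts.append(gene)
        pos += len(gene)
        s = sl_after.get(i)
        if s is not None:
            ig, sl = _intergenic_with_sl(s, rng, spec, pos)
            placed.append(sl)
        elif i < plan.n_genes - 1:
            ig = _random_background(rng, int(rng.integers(*spec.intergenic_len)), spec.gc)
        else:
            ig = ""
        parts.append(ig)
        pos += len(ig)
    return "".join(parts), gene_spans, placed


def _intergenic_with_sl(
    s: PlantedSL, rng: np.random.Generator, spec: FixtureSpec, offset: int,
    max_tries: int = 40,
) -> tuple[str, _PlacedSL]:
    tier = TIERS[s.tier]
    for _ in range(max_tries):
        hp, window, dg, structure = make_hairpin(tier.dg_band, s.uclass, rng,
                                                 tier.stem_len)
        pad_l = _safe_pad(rng, int(rng.integers(*spec.pad_len)), spec.gc, window)
        pad_r = _random_background(rng, int(rng.integers(*spec.pad_len)), spec.gc)
        region = pad_l + hp + window + pad_r
        hp_start, hp_end = len(pad_l), len(pad_l) + len(hp) - 1
        if _verify_planted(region, hp_start, hp_end, dg, structure, s.uclass):
            return region, _PlacedSL(
                s, offset + hp_start, offset + hp_end, dg,
                hp.replace("T", "U"), structure, window,
            )
    raise GenerationError(
        f"could not plant a verifiable {s.uclass} hairpin in tier {s.tier}"
    )


def make_fixture(spec: FixtureSpec, outdir: str | Path | None = None) -> Fixture:
    """Assemble the full synthetic dataset (optionally writing all files)."""
    rng = np.random.default_rng(spec.seed)
    segments: list[tuple[OperonPlan, str, list[tuple[int, int]], list[_PlacedSL]]] = []
    for plan in spec.plans:
        seg, gene_spans, placed = _build_segment(plan, rng, spec)
        segments.append((plan, seg, gene_spans, placed))

    parts = [_random_background(rng, int(rng.integers(*spec.spacer_len)), spec.gc)]
    genome_pos = len(parts[0])  # 0-based offset of next segment
    genes: list[GeneAnnotation] = []
    operons: list[OperonMap] = []
    truth_rows = []
    ratio_rows = []
    depth_vals: dict[str, float] = {}
    prot_vals: dict[str, float] = {}
    srps_ids: set[int] = set()

    for oid0, (plan, seg, gene_spans, placed) in enumerate(segments):
        oid = oid0 + 1
        m = len(seg)
        strand = plan.strand
        emitted = seg if strand == "+" else revcomp(seg)
        parts.append(emitted)

        def to_genome(a: int, b: int) -> tuple[int, int]:
            if strand == "+":
                return genome_pos + a + 1, genome_pos + b + 1
            return genome_pos + (m - 1 - b) + 1, genome_pos + (m - 1 - a) + 1

        gene_ids = [f"op{oid:02d}_g{i + 1}" for i in range(plan.n_genes)]
        for gid, (a, b) in zip(gene_ids, gene_spans):
            gs, ge = to_genome(a, b)
            genes.append(GeneAnnotation(gid, gs, ge, strand, spec.contig_id))
        operons.append(OperonMap(oid, tuple(gene_ids), strand))
        if plan.is_srps:
            srps_ids.add(oid)

        for p in placed:
            gs, ge = to_genome(p.local_start, p.local_end)
            truth_rows.append(
                {
                    "operon_id": oid,
                    "after_gene": gene_ids[p.plan.after_index],
                    "after_index": p.plan.after_index,
                    "uclass": p.plan.uclass,
                    "terminal": p.plan.terminal,
                    "dG": p.dg,
                    "start": gs,
                    "end": ge,
                    "strand": strand,
                    "sequence": p.sequence,
                    "structure": p.structure,
                    "window": p.window.replace("T", "U"),
                }
            )

        # expression truth: nearest planted SL at-or-downstream controls a gene
        placed_sorted = sorted(placed, key=lambda p: p.plan.after_index)
        dg_first = placed_sorted[0].dg if placed_sorted else None
        for i, gid in enumerate(gene_ids):
            ctrl = next((p for p in placed_sorted if p.plan.after_index >= i), None)
            if ctrl is None:
                true_val, depth_mu = 0.0, 0.0
            else:
                true_val = round(ctrl.dg / dg_first, 2)
                depth_mu = spec.depth_scale * (abs(ctrl.dg) / DG_REF) ** spec.depth_gamma
            if placed_sorted:
                ratio_rows.append(
                    {"operon_id": oid, "gene_id": gid, "true_value": true_val}
                )
            for table, store in ((depth_vals, 0), (prot_vals, 1)):
                if depth_mu == 0.0:
                    table[gid] = 0.0
                else:
                    noise = 10.0 ** rng.normal(0.0, spec.noise_sigma)
                    table[gid] = round(depth_mu * noise, 2)

        genome_pos += m
        spacer = _random_background(rng, int(rng.integers(*spec.spacer_len)), spec.gc)
        parts.append(spacer)
        genome_pos += len(spacer)

    genome = GenomeRecord(spec.contig_id, "".join(parts))
    fixture = Fixture(
        spec=spec,
        genome=genome,
        genes=genes,
        operons=operons,
        depths=ExpressionTable(depth_vals, "read_depth"),
        proteins=ExpressionTable(prot_vals, "protein"),
        truth_sls=pd.DataFrame(truth_rows),
        truth_ratios=pd.DataFrame(ratio_rows),
        srps_operon_ids=srps_ids,
    )
    if outdir is not None:
        fixture.paths = _write_fixture(fixture, Path(outdir))
    return fixture


def _write_fixture(fx: Fixture, outdir: Path) -> dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "gff": outdir / "genes.gff3",
        "operons": outdir / "operons.tsv",
        "depths": outdir / "depths.tsv",
        "proteins": outdir / "proteins.tsv",
        "truth_sls": outdir / "truth_sls.tsv",
        "truth_ratios": outdir / "truth_ratios.tsv",
    }
    with open(paths["genome"], "w") as fh:
        fh.write(f">{fx.genome.id}\n")
        for i in range(0, fx.genome.length, 70):
            fh.write(fx.genome.sequence[i : i + 70] + "\n")
    write_gff3(fx.genes, paths["gff"])
    write_operon_map(fx.operons, paths["operons"])
    write_expression(fx.depths, paths["depths"])
    write_expression(fx.proteins, paths["proteins"])
    fx.truth_sls.to_csv(paths["truth_sls"], sep="\t", index=False)
    fx.truth_ratios.to_csv(paths["truth_ratios"], sep="\t", index=False)
    return paths
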