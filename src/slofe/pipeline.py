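"""End-to-end orchestration: scan -> fold -> trim -> dedup -> map ->
classify -> identify SRPS -> predict ratios -> validate.

Every stage is a pure function of (inputs, config), so reruns are
byte-stable; all stage outputs are written as TSV with the configuration
echoed in the header, plus a summary.json of the per-stage tallies.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import features, io
from .annotate import annotate_all
from .classify import classify
from .discovery import Descriptor, StemLoop, discover
from .errors import SlofeError
from .ratio import RatioPrediction, SRPSOperon, identify_srps, predict_ratio
from .validate import correlate, validate_sls

log = logging.getLogger("slofe")


@dataclass(frozen=True)
class PipelineConfig:
    descriptor: Descriptor = field(default_factory=Descriptor)
    backend: str = "internal"
    dg_max: float = features.DG_FLOOR
    overlap_frac: float = 0.75
    mismatch_nt: int = 3
    score: str = "S4"
    stable_threshold: float = features.STABLE_THRESHOLD
    stsl_priority: bool = True
    tsl_controls: bool = True
    nrd_threshold: float = 0.5
    dg_rescue: bool = False

    def to_header(self) -> str:
        d = dataclasses.asdict(self)
        desc = d.pop("descriptor")
        items = [f"{k}={v}" for k, v in {**desc, **d}.items()]
        return "slofe config: " + " ".join(items)


@dataclass
class PipelineResult:
    config: PipelineConfig
    sls: list[StemLoop]
    stable: list[StemLoop]
    classified: list[StemLoop]
    srps: list[SRPSOperon]
    ratios: list[RatioPrediction]
    validations: list
    correlations: list
    summary: dict


def run_stages(
    genomes: list[io.GenomeRecord],
    genes: list[io.GeneAnnotation],
    operons: list[io.OperonMap],
    config: PipelineConfig | None = None,
    depths: io.ExpressionTable | None = None,
    expression: io.ExpressionTable | None = None,
) -> PipelineResult:
    """Run the full pipeline in memory."""
    config = config or PipelineConfig()
    genome_by_id = {g.id: g for g in genomes}

    log.info("scanning %d contig(s)", len(genomes))
    raw: list[StemLoop] = []
    for g in genomes:
        raw.extend(discover(g, config.descriptor, backend=config.backend))
    log.info("folded stem-loops: %d", len(raw))

    trimmed = [features.trim_flanks(sl) for sl in raw]
    deduped = features.deduplicate(
        trimmed, config.dg_max, config.overlap_frac, config.mismatch_nt
    )
    log.info("after dG floor + redundancy removal: %d", len(deduped))

    scored = features.attach_scores(deduped)
    stable = features.select_stable(scored, config.score, config.stable_threshold)
    log.info("stable stem-loops (%s >= %.0f%% of min): %d",
             config.score, 100 * config.stable_threshold, len(stable))

    mapped = annotate_all(stable, genes, operons)
    classified = []
    for sl in mapped:
        uf = features.u_features(sl, genome_by_id[sl.contig])
        cls = classify(uf, stsl_priority=config.stsl_priority)
        classified.append(
            dataclasses.replace(
                sl,
                polyU_len=uf.polyU_len,
                U_content=uf.U_content,
                tail_position=uf.tail_position,
                label=cls.label,
            )
        )

    srps = identify_srps(classified, operons, genes)
    ratios = [predict_ratio(op, tsl_controls=config.tsl_controls) for op in srps]
    log.info("SRPS operons: %d", len(srps))

    validations = []
    if depths is not None:
        validations = validate_sls(
            srps, depths, config.nrd_threshold, config.dg_rescue
        )
    correlations = []
    for table in (depths, expression):
        if table is None:
            continue
        for pred in ratios:
            if len(pred.per_gene) < 3:  # bicistronic: correlation not reported
                continue
            correlations.append(correlate(pred, table))

    cat_counts = pd.Series([sl.category for sl in mapped]).value_counts().to_dict()
    label_counts = pd.Series(
        [sl.label for sl in classified
         if sl.category == "intergenic" and sl.operon_context == "intra_operonic"]
    ).value_counts().to_dict()
    summary = {
        "n_folded": len(raw),
        "n_after_dedup": len(deduped),
        "n_stable": len(stable),
        "categories": cat_counts,
        "intra_operonic_labels": label_counts,
        "n_srps_operons": len(srps),
        "srps_operon_ids": sorted(op.operon_id for op in srps),
        "n_validated": sum(1 for v in validations if v.passed),
        "n_validation_records": len(validations),
    }
    return PipelineResult(
        config, raw, stable, classified, srps, ratios, validations, correlations, summary
    )


def run_all(
    genome_path,
    gff_path,
    operons_path,
    outdir,
    config: PipelineConfig | None = None,
    depths_path=None,
    expression_path=None,
) -> PipelineResult:
    """File-level entry point; writes all stage outputs under ``outdir``."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        genomes = io.read_genome(genome_path)
        genes = io.read_annotation(gff_path)
        operons = io.read_operon_map(operons_path, genes)
        depths = io.read_expression(depths_path) if depths_path else None
        if depths is None:
            log.info("no read-depth table supplied: validation stage skipped")
        expression = (
            io.read_expression(expression_path, "transcript")
            if expression_path
            else None
        )
        res = run_stages(genomes, genes, operons, config, depths, expression)
        hdr = config.to_header()
        io.write_sl_table(
            [features.trim_flanks(sl) for sl in res.sls], outdir / "sls.tsv", hdr
        )
        io.write_sl_table(res.stable, outdir / "stable.tsv", hdr)
        io.write_sl_table(res.classified, outdir / "mapped.tsv", hdr)
        io.write_sl_table(res.classified, outdir / "classified.tsv", hdr)
        _write_srps(res.srps, outdir / "srps_operons.tsv", hdr)
        _write_ratios(res.ratios, outdir / "ratios.tsv", hdr)
        _write_validation(res.validations, outdir / "validation.tsv", hdr)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(res.summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return res
    except SlofeError:
        log.exception("pipeline stage failed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def _write_srps(srps, path, hdr):
    rows = [
        {
            "operon_id": op.operon_id,
            "strand": op.strand,
            "n_genes": len(op.genes),
            "genes": ",".join(op.genes),
            "control_sls": ",".join(
                f"{c.sl.id}:{c.sl.label}:{'T' if c.terminal else 'I'}@{c.after_index}"
                for c in op.control_sls
            ),
        }
        for op in srps
    ]
    _write_tsv(rows, ["operon_id", "strand", "n_genes", "genes", "control_sls"], path, hdr)


def _write_ratios(ratios, path, hdr):
    rows = [
        {
            "operon_id": p.operon_id,
            "gene_id": g.gene_id,
            "control_sl": g.controlling_sl or "",
            "dG": "" if g.dG_assigned is None else g.dG_assigned,
            "ratio": g.value,
        }
        for p in ratios
        for g in p.per_gene
    ]
    _write_tsv(rows, ["operon_id", "gene_id", "control_sl", "dG", "ratio"], path, hdr)


def _write_validation(records, path, hdr):
    rows = [
        {
            "sl_id": v.sl_id,
            "operon_id": v.operon_id,
            "rd5": "" if v.rd5 is None else v.rd5,
            "rd3": "" if v.rd3 is None else v.rd3,
            "nrd": "" if v.nrd is None else round(v.nrd, 4),
            "passed": "" if v.passed is None else v.passed,
            "status": v.status,
        }
        for v in records
    ]
    _write_tsv(rows, ["sl_id", "operon_id", "rd5", "rd3", "nrd", "passed", "status"], path, hdr)


def _write_tsv(rows, columns, path, hdr):
    with open(path, "w") as fh:
        fh.write(f"# {hdr}\n")
        pd.DataFrame(rows, columns=columns).to_csv(fh, sep="\t", index=False)
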