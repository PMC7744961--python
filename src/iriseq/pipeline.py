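"""End-to-end orchestration: annotation -> quantify -> classify -> associate.

The pipeline is a thin composition of the library stages with file IO and a
JSON run report. All outputs are plain TSV/JSON so runs can be diffed; a
rerun on identical inputs and config reproduces identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import pyfaidx

from . import __version__
from .annotation import (
    annotate_features,
    build_intron_records,
    compute_shared_regions,
    parse_annotation,
    records_to_bed,
)
from .association import (
    class_expression_contrast,
    expression_change,
    gene_level_classes,
    iri_fc_binning,
)
from .classify import ClassifierConfig, classify_all, label_counts
from .coverage import group_order, read_bedgraph, read_design
from .quantify import (
    apply_iri_filters,
    build_iri_matrix,
    expression_table,
    filter_expressed,
    iri_matrix_to_tsv,
)
from .rbp import binding_density, load_binding_sites

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    annotation: str
    coverage_dir: str
    design: str
    out_dir: str
    genome: str | None = None
    binding_bed: str | None = None
    annotation_dialect: str = "gtf"
    mode: str = "timeseries"
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    read_length: int = 100
    expression_threshold: float = 1.0
    expression_pseudocount: float = 0.1
    iri_pseudocount: float = 0.01
    n_bins: int = 8
    fc_groups: tuple[str, str] | None = None  # default: first vs last group
    log_level: str = "INFO"

    def validate_paths(self) -> None:
        for name in ("annotation", "coverage_dir", "design"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        for name in ("genome", "binding_bed"):
            v = getattr(self, name)
            if v is not None and not Path(v).exists():
                raise FileNotFoundError(f"{name} path does not exist: {v}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; write stage TSVs and a JSON run report.

    Raises :class:`PipelineError` naming the failing stage; partial outputs
    are retained next to a ``FAILED`` marker file.
    """
    logging.basicConfig(level=config.log_level)
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": _jsonable(config)}
    stage = "setup"
    try:
        stage = "annotation"
        genes = parse_annotation(config.annotation, dialect=config.annotation_dialect)
        records = []
        shared_by_gene = {}
        for gene in genes:
            shared = compute_shared_regions(gene)
            shared_by_gene[gene.gene_id] = (gene.chrom, shared.shared_exonic)
            records.extend(build_intron_records(shared))
        if config.genome:
            genome = pyfaidx.Fasta(config.genome)
            records = annotate_features(records, genome)
        (out / "introns.bed").write_text(records_to_bed(records))
        report["annotation"] = {"genes": len(genes), "introns": len(records)}

        stage = "coverage"
        design = read_design(config.design)
        tracks = {}
        for row in design.itertuples():
            path = Path(config.coverage_dir) / f"{row.sample_id}.bedgraph"
            if not path.exists():
                raise FileNotFoundError(f"coverage file missing: {path}")
            tracks[row.sample_id] = read_bedgraph(
                path, row.sample_id, total_mapped=row.total_mapped
            )

        stage = "quantify"
        matrix = build_iri_matrix(tracks, records)
        matrix, filter_report = apply_iri_filters(matrix)
        iri_matrix_to_tsv(matrix).to_csv(out / "iri_matrix.tsv", sep="\t",
                                         index=False)
        report["quantify"] = filter_report

        stage = "classify"
        table = classify_all(matrix, design, config.classifier, mode=config.mode)
        table.to_csv(out / "classification.tsv", sep="\t")
        counts = label_counts(table)
        report["classify"] = counts

        stage = "association"
        expr = expression_table(tracks, shared_by_gene, design,
                                read_length=config.read_length)
        expr.to_csv(out / "expression_fpkm.tsv", sep="\t")
        expressed = filter_expressed(expr, design, config.expression_threshold)
        order = group_order(design)
        ga, gb = config.fc_groups or (order[0], order[-1])
        fc = expression_change(expr, design, ga, gb,
                               pseudocount=config.expression_pseudocount,
                               genes=expressed)
        fc.to_csv(out / "expression_log2fc.tsv", sep="\t")
        classes = gene_level_classes(table)
        contrast = class_expression_contrast(classes, fc)
        contrast.to_csv(out / "class_expression_contrast.tsv", sep="\t")
        trend = iri_fc_binning(matrix, fc, design, ga, gb,
                               n_bins=config.n_bins, delta=config.iri_pseudocount,
                               min_abs_delta=config.classifier.change_cutoff)
        trend.table.to_csv(out / "iri_fc_bins.tsv", sep="\t")
        report["association"] = {
            "expressed_genes": len(expressed),
            "fc_groups": [ga, gb],
            "bin_trend_rho": trend.rho,
            "bin_trend_p": trend.p_value,
            "class_medians": contrast["median_log2fc"].to_dict(),
        }

        if config.binding_bed:
            stage = "rbp"
            index = load_binding_sites(config.binding_bed)
            kept_records = [r for r in records if r.intron_id in matrix.intron_ids]
            dens = binding_density(index, kept_records, rbp="all")
            dens = dens.merge(
                table[["label"]].reset_index(), on="intron_id", how="left"
            )
            dens.to_csv(out / "binding_density.tsv", sep="\t", index=False)
            report["rbp"] = {
                "n_sites": int(len(index.sites)),
                "n_rbps": len(index.rbp_names),
            }
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        raise PipelineError(stage, exc) from exc

    # internal consistency of counts
    q = report["quantify"]
    assert q["quantified"] == q["kept"] + q["iri_gt1"] + q["missing"]
    labels = report["classify"]
    assert labels["classified"] == sum(
        labels[k] for k in ("no_IR", "stable_IR", "up_IR", "down_IR", "discarded")
    )
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True)
                                     + "\n")
    return report


def analyze_simulation(result, config: ClassifierConfig | None = None,
                       mode: str = "timeseries", n_bins: int = 8) -> dict:
    """Run quantify -> classify -> association on an in-memory simulation.

    Convenience for simulation studies: returns the filtered IRI matrix,
    classification table, expression table, per-gene log2 fold change
    (last vs first group), and the binned IRI-FC/expression trend.
    """
    matrix = build_iri_matrix(result.tracks, result.genome.introns)
    matrix, filter_report = apply_iri_filters(matrix)
    table = classify_all(matrix, result.design, config or ClassifierConfig(),
                         mode=mode)
    shared = {
        g.gene_id: (g.chrom, result.genome.shared_exonic[g.gene_id])
        for g in result.genome.genes
    }
    expr = expression_table(result.tracks, shared, result.design,
                            read_length=result.config.read_length)
    expressed = filter_expressed(expr, result.design)
    order = group_order(result.design)
    fc = expression_change(expr, result.design, order[0], order[-1],
                           genes=expressed)
    trend = iri_fc_binning(matrix, fc, result.design, order[0], order[-1],
                           n_bins=n_bins,
                           min_abs_delta=(config or ClassifierConfig()).change_cutoff)
    return {
        "matrix": matrix,
        "filter_report": filter_report,
        "classification": table,
        "expression": expr,
        "fold_change": fc,
        "trend": trend,
    }


def _jsonable(config: RunConfig) -> dict:
    d = asdict(config)
    if isinstance(d.get("fc_groups"), tuple):
        d["fc_groups"] = list(d["fc_groups"])
    return d
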