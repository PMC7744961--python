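"""Intron retention index (IRI) quantification and gene expression.

The IRI of an intron in a sample is the ratio of read density (mean per-base
depth) over the intron to the pooled read density over its two flanking
shared exonic segments: 0 means fully spliced, 1 means retained at exon
level. Two quality filters apply, both at the intron-row level after
quantification:

* an intron cell is *missing* when fewer than half its bases are covered
  (``low_coverage``) or the flank density is zero (``zero_flank``);
* any intron with IRI > 1 in any sample, or a missing IRI in any sample,
  is discarded entirely — values above 1 indicate missing annotation rather
  than retention, and the downstream classifiers need complete vectors.

Gene expression is a simple exonic-density FPKM over the gene's shared
exonic bases with a configured read length, sufficient for the expression
filter (FPKM > 1 in at least one group) and fold-change contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack, covered_fraction, region_density
from .intervals import GenomicInterval, IntronRecord

MIN_COVERED_FRACTION = 0.5


@dataclass
class IRIRecord:
    """IRI of one intron in one sample with its QC quantities."""

    intron_id: str
    sample_id: str
    intron_density: float
    flank_density: float
    covered_fraction: float
    iri: float | None
    qc_flags: frozenset[str] = frozenset()


@dataclass
class IRIMatrix:
    """Introns x samples IRI grid with per-cell QC, as aligned DataFrames."""

    iri: pd.DataFrame
    intron_density: pd.DataFrame
    flank_density: pd.DataFrame
    covered_fraction: pd.DataFrame
    flags: pd.DataFrame  # comma-joined flag strings, "" when clean
    intron_meta: pd.DataFrame  # index intron_id; gene_id, length, gc_content
    retention_cutoff: float = 0.1
    change_cutoff: float = 0.1
    filter_report: dict = field(default_factory=dict)

    @property
    def intron_ids(self) -> pd.Index:
        return self.iri.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.iri.columns


def compute_iri(track: CoverageTrack, record: IntronRecord) -> IRIRecord:
    """IRI of one intron in one sample.

    Flank density pools both flanking segments length-weighted (one
    denominator). The IRI is left missing with the matching flag when the
    intron's covered fraction is below 0.5 or the flank density is zero;
    IRI > 1 is computed but flagged (row-level discard happens in
    :func:`apply_iri_filters`).
    """
    intron_density = region_density(track, record.interval)
    flank_sum = track.interval_sum(record.flank_up) + track.interval_sum(
        record.flank_down
    )
    flank_len = record.flank_up.length + record.flank_down.length
    flank_density = flank_sum / flank_len
    cov = covered_fraction(track, record.interval)

    flags: set[str] = set()
    iri: float | None
    if cov < MIN_COVERED_FRACTION:
        flags.add("low_coverage")
    if flank_density == 0:
        flags.add("zero_flank")
    if flags:
        iri = None
    else:
        iri = intron_density / flank_density
        if iri > 1:
            flags.add("iri_gt1")
    return IRIRecord(
        intron_id=record.intron_id,
        sample_id=track.sample_id,
        intron_density=intron_density,
        flank_density=flank_density,
        covered_fraction=cov,
        iri=iri,
        qc_flags=frozenset(flags),
    )


def build_iri_matrix(
    tracks: Mapping[str, CoverageTrack],
    records: Sequence[IntronRecord],
    retention_cutoff: float = 0.1,
    change_cutoff: float = 0.1,
) -> IRIMatrix:
    """Quantify every intron in every sample into an :class:`IRIMatrix`."""
    sample_ids = list(tracks)
    intron_ids = [r.intron_id for r in records]
    shape = (len(records), len(sample_ids))
    iri = np.full(shape, np.nan)
    dens = np.zeros(shape)
    flank = np.zeros(shape)
    cov = np.zeros(shape)
    flags = np.empty(shape, dtype=object)
    for j, sid in enumerate(sample_ids):
        track = tracks[sid]
        for i, rec in enumerate(records):
            cell = compute_iri(track, rec)
            if cell.iri is not None:
                iri[i, j] = cell.iri
            dens[i, j] = cell.intron_density
            flank[i, j] = cell.flank_density
            cov[i, j] = cell.covered_fraction
            flags[i, j] = ",".join(sorted(cell.qc_flags))
    idx = pd.Index(intron_ids, name="intron_id")
    cols = pd.Index(sample_ids, name="sample_id")
    meta = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "chrom": [r.interval.chrom for r in records],
            "start": [r.interval.start for r in records],
            "end": [r.interval.end for r in records],
            "strand": [r.interval.strand for r in records],
            "length": [r.length for r in records],
            "gc_content": [r.gc_content for r in records],
        },
        index=idx,
    )
    return IRIMatrix(
        iri=pd.DataFrame(iri, index=idx, columns=cols),
        intron_density=pd.DataFrame(dens, index=idx, columns=cols),
        flank_density=pd.DataFrame(flank, index=idx, columns=cols),
        covered_fraction=pd.DataFrame(cov, index=idx, columns=cols),
        flags=pd.DataFrame(flags, index=idx, columns=cols),
        intron_meta=meta,
        retention_cutoff=retention_cutoff,
        change_cutoff=change_cutoff,
    )


def apply_iri_filters(matrix: IRIMatrix) -> tuple[IRIMatrix, dict[str, int]]:
    """Drop intron rows with IRI > 1 or a missing IRI in any sample.

    Returns the filtered matrix and a report counting removed rows per
    reason (``iri_gt1`` takes precedence over ``missing``) plus ``kept``.
    Surviving values are all in [0, 1].
    """
    gt1 = (matrix.iri > 1).any(axis=1)
    missing = matrix.iri.isna().any(axis=1) & ~gt1
    keep = ~gt1 & ~missing
    report = {
        "quantified": int(len(matrix.iri)),
        "kept": int(keep.sum()),
        "iri_gt1": int(gt1.sum()),
        "missing": int(missing.sum()),
    }
    filtered = IRIMatrix(
        iri=matrix.iri.loc[keep],
        intron_density=matrix.intron_density.loc[keep],
        flank_density=matrix.flank_density.loc[keep],
        covered_fraction=matrix.covered_fraction.loc[keep],
        flags=matrix.flags.loc[keep],
        intron_meta=matrix.intron_meta.loc[keep],
        retention_cutoff=matrix.retention_cutoff,
        change_cutoff=matrix.change_cutoff,
        filter_report=report,
    )
    return filtered, report


def gene_fpkm(
    track: CoverageTrack,
    shared_exonic: Sequence[tuple[int, int]],
    chrom: str,
    total_mapped: float | None = None,
    read_length: int = 100,
) -> float:
    """Exonic-density FPKM over a gene's shared exonic bases.

    The fragment count is approximated from coverage as
    (summed base coverage) / read_length; FPKM then scales per kilobase of
    shared-exon length per million mapped reads.
    """
    exon_len = sum(e - s for s, e in shared_exonic)
    if exon_len <= 0:
        raise ValueError("zero shared-exon length")
    if total_mapped is None:
        total_mapped = track.total_mapped
    base_cov = sum(
        track.interval_sum(GenomicInterval(chrom, s, e)) for s, e in shared_exonic
    )
    fragments = base_cov / read_length
    return fragments * 1e9 / (exon_len * total_mapped)


def expression_table(
    tracks: Mapping[str, CoverageTrack],
    shared_exonic_by_gene: Mapping[str, tuple[str, Sequence[tuple[int, int]]]],
    design: pd.DataFrame,
    read_length: int = 100,
) -> pd.DataFrame:
    """Gene x sample FPKM table.

    ``shared_exonic_by_gene`` maps gene_id -> (chrom, shared exon list).
    ``total_mapped`` comes from the design table.
    """
    tm = dict(zip(design["sample_id"], design["total_mapped"]))
    data = {}
    for sid, track in tracks.items():
        col = {}
        for gene_id, (chrom, exons) in shared_exonic_by_gene.items():
            col[gene_id] = gene_fpkm(
                track, exons, chrom, total_mapped=tm.get(sid), read_length=read_length
            )
        data[sid] = col
    df = pd.DataFrame(data)
    df.index.name = "gene_id"
    df.columns.name = "sample_id"
    return df


def filter_expressed(
    expr: pd.DataFrame, design: pd.DataFrame, threshold: float = 1.0
) -> list[str]:
    """Genes whose group-mean FPKM strictly exceeds ``threshold`` in >= 1 group."""
    groups = design.groupby("group", sort=False)["sample_id"].apply(list)
    keep = pd.Series(False, index=expr.index)
    for _, samples in groups.items():
        keep |= expr[samples].mean(axis=1) > threshold
    return list(expr.index[keep])


def iri_matrix_to_tsv(matrix: IRIMatrix) -> pd.DataFrame:
    """Long-format export of the IRI matrix (one row per intron x sample)."""
    long = (
        matrix.iri.stack(future_stack=True)
        .rename("iri")
        .reset_index()
        .merge(
            matrix.covered_fraction.stack(future_stack=True)
            .rename("covered_fraction")
            .reset_index()
        )
        .merge(matrix.flags.stack(future_stack=True).rename("qc_flags").reset_index())
    )
    return long.merge(
        matrix.intron_meta[["gene_id"]].reset_index(), on="intron_id", how="left"
    )
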