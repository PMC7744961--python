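"""Gene-annotation parsing and shared-region reduction.

Multi-isoform genes make per-intron retention ambiguous: a base that is
intronic in one isoform may be exonic in another. To avoid that interference
the whole pipeline works on *shared* regions — bases exonic in every annotated
isoform (shared exonic) or intronic in every isoform (shared intronic). One
:class:`~iriseq.intervals.IntronRecord` is built per shared intronic segment
that has a shared exonic segment on both sides; those flanks provide the
denominator of the intron retention index.

Coordinates are converted at the boundary: GTF is 1-based inclusive, refFlat
is already 0-based half-open; everything internal is 0-based half-open.
"""

from __future__ import annotations

import bisect
import logging
from pathlib import Path
from typing import Iterable, Mapping

from gffutils.feature import feature_from_line

from .intervals import (
    GeneModel,
    GenomicInterval,
    IntronRecord,
    SharedRegions,
    intersect_many,
    merge_intervals,
    subtract_intervals,
)

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    pass


def _finalize_genes(
    raw: dict[str, dict], rejected: list[str]
) -> list[GeneModel]:
    genes = []
    for gene_id, info in raw.items():
        if len(info["chrom"]) > 1 or len(info["strand"]) > 1:
            logger.warning(
                "gene %s spans multiple chromosomes/strands; rejected", gene_id
            )
            rejected.append(gene_id)
            continue
        transcripts = {
            tx: merge_intervals(exons) for tx, exons in info["transcripts"].items()
        }
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=next(iter(info["chrom"])),
                strand=next(iter(info["strand"])),
                transcripts=transcripts,
            )
        )
    return genes


def _parse_gtf(path: Path) -> list[GeneModel]:
    raw: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                raise AnnotationError(
                    f"{path}: malformed GTF line {lineno}: expected 9 fields"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # noqa: BLE001 - reported with line number
                raise AnnotationError(f"{path}: malformed GTF line {lineno}: {exc}")
            if feat.featuretype != "exon":
                continue
            try:
                gene_id = feat.attributes["gene_id"][0]
                tx_id = feat.attributes["transcript_id"][0]
            except KeyError as exc:
                raise AnnotationError(
                    f"{path}: line {lineno}: exon record lacks {exc} attribute"
                )
            info = raw.setdefault(
                gene_id, {"chrom": set(), "strand": set(), "transcripts": {}}
            )
            info["chrom"].add(feat.seqid)
            info["strand"].add(feat.strand)
            # GTF is 1-based inclusive; convert to 0-based half-open.
            info["transcripts"].setdefault(tx_id, []).append(
                (feat.start - 1, feat.end)
            )
    rejected: list[str] = []
    return _finalize_genes(raw, rejected)


def _parse_refflat(path: Path) -> list[GeneModel]:
    raw: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                raise AnnotationError(
                    f"{path}: malformed refFlat line {lineno}: "
                    f"expected 11 columns, got {len(fields)}"
                )
            gene_id, tx_id, chrom, strand = fields[0], fields[1], fields[2], fields[3]
            try:
                starts = [int(x) for x in fields[9].rstrip(",").split(",")]
                ends = [int(x) for x in fields[10].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: malformed refFlat line {lineno}: {exc}"
                )
            info = raw.setdefault(
                gene_id, {"chrom": set(), "strand": set(), "transcripts": {}}
            )
            info["chrom"].add(chrom)
            info["strand"].add(strand)
            # refFlat exon coordinates are already 0-based half-open.
            info["transcripts"].setdefault(tx_id, []).extend(zip(starts, ends))
    rejected: list[str] = []
    return _finalize_genes(raw, rejected)


def parse_annotation(path: str | Path, dialect: str = "gtf") -> list[GeneModel]:
    """Parse a GTF or refFlat annotation into :class:`GeneModel` objects.

    Exons are grouped by gene and transcript identifier, sorted, and merged
    (duplicate exon lines collapse to one). Genes whose records span more
    than one chromosome or strand are rejected with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "gtf":
        return _parse_gtf(path)
    if dialect == "refflat":
        return _parse_refflat(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def compute_shared_regions(gene: GeneModel) -> SharedRegions:
    """Reduce a gene model to regions exonic/intronic in *every* isoform.

    A base is shared exonic iff it is exonic in every transcript of the gene.
    A base is shared intronic iff, for every transcript, it lies strictly
    between that transcript's first and last exon and is not exonic in it
    (hence not exonic in any). Bases outside any transcript span belong to
    neither set.
    """
    exon_lists = list(gene.transcripts.values())
    shared_exonic = intersect_many(exon_lists)
    intronic_lists = []
    for exons in exon_lists:
        span = [(exons[0][0], exons[-1][1])]
        intronic_lists.append(subtract_intervals(span, exons))
    shared_intronic = intersect_many(intronic_lists)
    return SharedRegions(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        shared_exonic=shared_exonic,
        shared_intronic=shared_intronic,
    )


def build_intron_records(shared: SharedRegions) -> list[IntronRecord]:
    """One record per shared intronic segment flanked by shared exons.

    Segments lacking a shared exonic segment on either side are dropped (and
    counted in a debug log). Intron indices follow transcription order, so on
    the minus strand the leftmost segment receives the highest index.
    """
    exon_starts = [s for s, _ in shared.shared_exonic]
    exon_ends = [e for _, e in shared.shared_exonic]
    kept: list[tuple] = []
    dropped = 0
    for s, e in shared.shared_intronic:
        # nearest shared exonic segment entirely to the left / right
        i_up = bisect.bisect_right(exon_ends, s) - 1
        i_down = bisect.bisect_left(exon_starts, e)
        if i_up < 0 or i_down >= len(shared.shared_exonic):
            dropped += 1
            continue
        kept.append((s, e, shared.shared_exonic[i_up], shared.shared_exonic[i_down]))
    if dropped:
        logger.debug(
            "gene %s: dropped %d shared intronic segment(s) lacking a flank",
            shared.gene_id,
            dropped,
        )
    n = len(kept)
    records = []
    for pos, (s, e, fu, fd) in enumerate(kept):
        index = pos + 1 if shared.strand != "-" else n - pos
        records.append(
            IntronRecord(
                intron_id=f"{shared.gene_id}_intron{index}",
                gene_id=shared.gene_id,
                interval=GenomicInterval(shared.chrom, s, e, shared.strand),
                flank_up=GenomicInterval(shared.chrom, fu[0], fu[1], shared.strand),
                flank_down=GenomicInterval(shared.chrom, fd[0], fd[1], shared.strand),
                index=index,
                length=e - s,
            )
        )
    return records


def gc_fraction(seq: str) -> float | None:
    """GC fraction over non-N bases; None if no informative base."""
    seq = seq.upper()
    informative = sum(1 for b in seq if b != "N")
    if informative == 0:
        return None
    gc = seq.count("G") + seq.count("C")
    return gc / informative


def annotate_features(
    records: Iterable[IntronRecord], genome: Mapping[str, object]
) -> list[IntronRecord]:
    """Fill gc_content from a genome sequence source.

    ``genome`` may be a plain dict of chromosome -> sequence string or a
    ``pyfaidx.Fasta`` object (anything whose ``[chrom][start:end]`` slice
    stringifies to sequence). Missing chromosomes leave the feature unset
    with a warning.
    """
    out = []
    for rec in records:
        try:
            chrom_seq = genome[rec.interval.chrom]
        except KeyError:
            logger.warning(
                "chromosome %s absent from genome; gc left missing for %s",
                rec.interval.chrom,
                rec.intron_id,
            )
            out.append(rec)
            continue
        seq = str(chrom_seq[rec.interval.start : rec.interval.end])
        rec.gc_content = gc_fraction(seq)
        out.append(rec)
    return out


def records_to_bed(records: Iterable[IntronRecord]) -> str:
    """Export intron records as BED6+ text (extra columns: length, gc)."""
    lines = []
    for r in records:
        gc = f"{r.gc_content:.4f}" if r.gc_content is not None else "NA"
        lines.append(
            "\t".join(
                [
                    r.interval.chrom,
                    str(r.interval.start),
                    str(r.interval.end),
                    r.intron_id,
                    "0",
                    r.interval.strand,
                    str(r.length),
                    gc,
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
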