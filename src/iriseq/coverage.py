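"""Per-base read-coverage tracks and interval summaries.

A :class:`CoverageTrack` holds dense per-chromosome depth arrays (synthetic
genomes and test fixtures are small; real chromosomes can be supplied region
by region). bedGraph input/output uses the 4-column 0-based half-open
convention. Interval sums use cached cumulative sums so that quantifying
thousands of introns per sample costs O(1) each.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import GenomicInterval


class CoverageError(KeyError):
    pass


@dataclass
class CoverageTrack:
    """Per-chromosome read depth for one sample."""

    sample_id: str
    depths: dict[str, np.ndarray]
    total_mapped: float
    _cumsum: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.total_mapped <= 0:
            raise ValueError("total_mapped must be > 0")
        for chrom, arr in self.depths.items():
            if np.any(arr < 0):
                raise ValueError(f"negative depth on {chrom}")

    def chrom_depths(self, chrom: str) -> np.ndarray:
        try:
            return self.depths[chrom]
        except KeyError:
            raise CoverageError(
                f"chromosome {chrom!r} absent from coverage track "
                f"{self.sample_id!r}"
            )

    def _chrom_cumsum(self, chrom: str) -> np.ndarray:
        if chrom not in self._cumsum:
            arr = self.chrom_depths(chrom)
            cs = np.zeros(len(arr) + 1, dtype=np.float64)
            np.cumsum(arr, out=cs[1:])
            self._cumsum[chrom] = cs
        return self._cumsum[chrom]

    def interval_sum(self, interval: GenomicInterval) -> float:
        cs = self._chrom_cumsum(interval.chrom)
        n = len(cs) - 1
        s = min(interval.start, n)
        e = min(interval.end, n)
        return float(cs[e] - cs[s])

    def covered_bases(self, interval: GenomicInterval) -> int:
        arr = self.chrom_depths(interval.chrom)
        seg = arr[interval.start : interval.end]
        return int(np.count_nonzero(seg))

    def scaled(self, k: float) -> "CoverageTrack":
        """Uniformly scale all depths by k > 0 (IRI must be invariant)."""
        if k <= 0:
            raise ValueError("scale factor must be > 0")
        return CoverageTrack(
            sample_id=self.sample_id,
            depths={c: a * k for c, a in self.depths.items()},
            total_mapped=self.total_mapped * k,
        )


def region_density(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Mean per-base depth ("read density") over an interval."""
    if interval.length <= 0:
        raise ValueError("empty interval")
    return track.interval_sum(interval) / interval.length


def covered_fraction(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Fraction of interval bases with depth >= 1."""
    if interval.length <= 0:
        raise ValueError("empty interval")
    return track.covered_bases(interval) / interval.length


def read_bedgraph(
    path: str | Path,
    sample_id: str,
    total_mapped: float,
    chrom_sizes: Mapping[str, int] | None = None,
) -> CoverageTrack:
    """Load a 4-column bedGraph (chrom, start, end, depth; 0-based half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "depth"],
        comment="#",
        dtype={"chrom": str},
    )
    sizes: dict[str, int] = dict(chrom_sizes or {})
    for chrom, sub in df.groupby("chrom", sort=False):
        sizes[chrom] = max(sizes.get(chrom, 0), int(sub["end"].max()))
    depths = {c: np.zeros(n, dtype=np.float64) for c, n in sizes.items()}
    for chrom, sub in df.groupby("chrom", sort=False):
        arr = depths[chrom]
        for s, e, d in zip(sub["start"], sub["end"], sub["depth"]):
            arr[int(s) : int(e)] = d
    return CoverageTrack(sample_id=sample_id, depths=depths, total_mapped=total_mapped)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write run-length-encoded bedGraph; zero-depth runs are omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(track.depths):
            arr = track.depths[chrom]
            if len(arr) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [len(arr)]))
            for s, e in zip(starts, ends):
                d = arr[s]
                if d == 0:
                    continue
                if d == int(d):
                    fh.write(f"{chrom}\t{s}\t{e}\t{int(d)}\n")
                else:
                    fh.write(f"{chrom}\t{s}\t{e}\t{d}\n")


def read_design(path: str | Path) -> pd.DataFrame:
    """Sample design TSV: sample_id, group, replicate, total_mapped.

    Group order (time-point order for the time-series classifier) is the
    order of first appearance in the file.
    """
    design = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    required = {"sample_id", "group", "replicate", "total_mapped"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table lacks columns: {sorted(missing)}")
    dup = design.duplicated(subset=["group", "replicate"])
    if dup.any():
        raise ValueError("design table has duplicate (group, replicate) pairs")
    return design


def group_order(design: pd.DataFrame) -> list[str]:
    return list(dict.fromkeys(design["group"]))
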