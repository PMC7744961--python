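"""Shared fixtures and independent brute-force oracles.

The oracles here recompute quantities by per-base enumeration or direct
formulas, independently of the library's interval algebra and cumulative-sum
paths, so tests compare two genuinely different routes to the same answer.
"""

from __future__ import annotations

import numpy as np
import pytest

from iriseq.intervals import GeneModel, GenomicInterval


def brute_force_shared(gene: GeneModel) -> tuple[set[int], set[int]]:
    """Per-base labeling oracle for the shared-region reduction.

    A base is shared exonic iff exonic in every transcript; shared intronic
    iff, for every transcript, it lies strictly between that transcript's
    first and last exon and is not exonic in it.
    """
    lo = min(ex[0][0] for ex in gene.transcripts.values())
    hi = max(ex[-1][1] for ex in gene.transcripts.values())
    shared_ex, shared_in = set(), set()
    per_tx = []
    for exons in gene.transcripts.values():
        bases = set()
        for s, e in exons:
            bases.update(range(s, e))
        per_tx.append((bases, exons[0][0], exons[-1][1]))
    for pos in range(lo, hi):
        if all(pos in bases for bases, _, _ in per_tx):
            shared_ex.add(pos)
        elif all(
            span_lo <= pos < span_hi and pos not in bases
            for bases, span_lo, span_hi in per_tx
        ):
            shared_in.add(pos)
    return shared_ex, shared_in


def intervals_to_bases(intervals) -> set[int]:
    out: set[int] = set()
    for s, e in intervals:
        out.update(range(s, e))
    return out


def random_gene_model(rng: np.random.Generator, gene_id: str = "g",
                      max_isoforms: int = 3, span: int = 2000) -> GeneModel:
    """A random small gene model (<= `max_isoforms` isoforms, span <= `span`)."""
    n_tx = int(rng.integers(1, max_isoforms + 1))
    transcripts = {}
    for t in range(n_tx):
        n_ex = int(rng.integers(1, 6))
        cuts = np.sort(rng.choice(span, size=2 * n_ex, replace=False))
        exons = [(int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(n_ex)]
        transcripts[f"{gene_id}.t{t}"] = exons
    return GeneModel(gene_id=gene_id, chrom="chr1",
                     strand="+" if rng.random() < 0.5 else "-",
                     transcripts=transcripts)


def naive_iri(depths: np.ndarray, intron: tuple[int, int],
              flank_up: tuple[int, int], flank_down: tuple[int, int]):
    """Naive per-base recount of the retention index (the oracle route)."""
    i_sum = sum(depths[p] for p in range(*intron))
    i_len = intron[1] - intron[0]
    f_sum = sum(depths[p] for p in range(*flank_up)) + sum(
        depths[p] for p in range(*flank_down)
    )
    f_len = (flank_up[1] - flank_up[0]) + (flank_down[1] - flank_down[0])
    intron_density = i_sum / i_len
    flank_density = f_sum / f_len
    covered = sum(1 for p in range(*intron) if depths[p] >= 1) / i_len
    if covered < 0.5 or flank_density == 0:
        return intron_density, flank_density, covered, None
    return intron_density, flank_density, covered, intron_density / flank_density


@pytest.fixture
def simple_intron_record():
    from iriseq.intervals import IntronRecord

    return IntronRecord(
        intron_id="g1_intron1",
        gene_id="g1",
        interval=GenomicInterval("chr1", 100, 200, "+"),
        flank_up=GenomicInterval("chr1", 0, 100, "+"),
        flank_down=GenomicInterval("chr1", 200, 300, "+"),
        index=1,
        length=100,
    )


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small written fixture bundle shared by file-based tests."""
    from iriseq import SimConfig, simulate_bundle, write_fixture_bundle

    out = tmp_path_factory.mktemp("bundle") / "sim"
    config = SimConfig(n_genes=30)
    result = simulate_bundle(config, seed=11)
    manifest = write_fixture_bundle(result, out)
    return {"dir": out, "result": result, "manifest": manifest}
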