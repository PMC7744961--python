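"""Synthetic RNA-seq fixture generator with known intron-retention truth.

The generator embodies the degradation-coupling model the analysis is meant
to detect. Per gene, transcription produces ``T`` transcripts per unit time;
a fraction ``rho_t`` of them retain the gene's focal intron at time point
``t`` and decay ``gamma``-fold faster than spliced transcripts. Steady-state
abundances are therefore

* spliced      ``S_t = T (1 - rho_t)``
* retained     ``R_t = T rho_t / gamma``

so the gene's exonic signal ``S_t + R_t = T (1 - rho_t (1 - 1/gamma))``
falls as retention rises whenever ``gamma > 1`` — the mechanism that couples
retention to expression. The expected intron retention index is

``IRI_t = (rho_t / gamma + beta) / (1 - rho_t (1 - 1/gamma))``

where ``beta`` is a small nascent pre-mRNA background (intronic signal
present regardless of retention, proportional to transcription); with
``beta = 0`` this reduces to ``R_t / (S_t + R_t)``.

Retention trajectories follow one of five classes: ``none`` (IRI below the
retention cutoff at every time point), ``stable`` (retained but flat),
``up``/``down`` (strictly monotone), ``irregular`` (alternating between the
amplitude extremes, so its correlation with a monotone reference is ~0 and
the classifier must discard it). Each gene carries exactly one focal intron
with the gene's class; its remaining introns are ``none`` background, which
matches the observation that most retention-containing genes harbor a single
event and keeps the closed form above exact.

Coverage is simulated directly as independent per-base Poisson depth (the
retention index consumes depth, so read placement would add machinery
without exercising anything downstream). All randomness flows through
per-component streams derived from one master seed, so adding an RBP cannot
perturb coverage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import annotate_features, build_intron_records, compute_shared_regions
from .coverage import CoverageTrack, write_bedgraph
from .intervals import (
    GeneModel,
    IntronRecord,
    merge_intervals,
    subtract_intervals,
)

CLASSES = ("none", "stable", "up", "down", "irregular")

_STREAMS = {"genome": 0, "trajectories": 1, "coverage": 2, "sites": 3,
            "rbp_expression": 4}


def _rng(seed: int, component: str) -> np.random.Generator:
    """Independent, reproducible stream per simulation component."""
    return np.random.default_rng([int(seed), _STREAMS[component]])


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 100
    introns_per_gene: tuple[int, int] = (2, 4)
    exon_length: tuple[int, int] = (140, 220)
    intron_length: tuple[int, int] = (280, 600)
    change_intron_length: tuple[int, int] = (250, 450)  # change classes shorter
    gc_exon: float = 0.50
    gc_by_class: dict = field(
        default_factory=lambda: {
            "up": (0.55, 0.65),
            "down": (0.55, 0.65),
            "stable": (0.45, 0.55),
            "none": (0.35, 0.45),
            "irregular": (0.45, 0.55),
        }
    )
    skipping_fraction: float = 0.3
    gene_gap: int = 400
    n_timepoints: int = 5
    replicates: int = 3
    depth: float = 30.0
    read_length: int = 100
    gamma: float = 5.0
    intronic_background: float = 0.04  # beta: nascent pre-mRNA fraction
    class_mixture: dict = field(
        default_factory=lambda: {
            "none": 0.20, "stable": 0.20, "up": 0.25, "down": 0.25,
            "irregular": 0.10,
        }
    )
    rho_low: tuple[float, float] = (0.02, 0.08)
    rho_high: tuple[float, float] = (0.45, 0.60)
    rho_stable: tuple[float, float] = (0.30, 0.50)
    rho_none: tuple[float, float] = (0.0, 0.05)
    t_rate: tuple[float, float] = (1.0, 2.0)
    retention_cutoff: float = 0.1
    # RBP roster
    n_decoy_rbps: int = 20
    planted_rbp: str = "RBP_REG"
    rbp_base_rate: float = 2.0  # sites per kb
    rbp_enrichment: float = 5.0
    rbp_site_length: int = 30
    rbp_models: tuple[str, ...] = ("HFF", "MRC5", "DF", "BJ", "IMR90", "WI38")
    rbp_drop_models: int = 3  # planted regulator drops 2-fold in this many
    rbp_drop_fold: float = 2.0
    rbp_planted_expression: float = 30.0
    rbp_expression_reps: int = 3
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if abs(sum(self.class_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("class mixture proportions must sum to 1")
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        for lo, hi in (self.rho_low, self.rho_high, self.rho_stable, self.rho_none):
            if not (0 <= lo <= hi < 1):
                raise ValueError("rho ranges must satisfy 0 <= lo <= hi < 1")
        if self.introns_per_gene[0] < 1:
            raise ValueError("need >= 1 intron per gene")
        if self.intron_length[0] < 2 or self.exon_length[0] < 2:
            raise ValueError("infeasible length ranges")


def expected_iri(rho: np.ndarray | float, gamma: float, beta: float = 0.0):
    """Closed-form expected IRI under the degradation-coupling model."""
    rho = np.asarray(rho, dtype=float)
    return (rho / gamma + beta) / (1.0 - rho * (1.0 - 1.0 / gamma))


def exonic_signal_factor(rho, gamma: float):
    """Relative steady-state exonic signal (S + R) / T = 1 - rho (1 - 1/gamma)."""
    rho = np.asarray(rho, dtype=float)
    return 1.0 - rho * (1.0 - 1.0 / gamma)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    is_gc = rng.random(length) < gc
    pick = rng.integers(0, 2, size=length)
    bases = np.where(is_gc, np.where(pick == 0, "G", "C"),
                     np.where(pick == 0, "A", "T"))
    return "".join(bases)


@dataclass
class SimGenome:
    genes: list[GeneModel]
    sequences: dict[str, str]
    introns: list[IntronRecord]
    intron_class: dict[str, str]           # intron_id -> class
    gene_class: dict[str, str]             # gene_id -> class
    focal_intron: dict[str, str]           # gene_id -> intron_id
    shared_exonic: dict[str, list]         # gene_id -> interval list
    semi_exonic: dict[str, list]           # exonic in some but not all isoforms
    chrom: str = "chrS"

    @property
    def chrom_length(self) -> int:
        return len(self.sequences[self.chrom])

    def introns_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "intron_id": [r.intron_id for r in self.introns],
                "gene_id": [r.gene_id for r in self.introns],
                "chrom": [r.interval.chrom for r in self.introns],
                "start": [r.interval.start for r in self.introns],
                "end": [r.interval.end for r in self.introns],
                "strand": [r.interval.strand for r in self.introns],
                "length": [r.length for r in self.introns],
                "gc_content": [r.gc_content for r in self.introns],
                "true_class": [self.intron_class[r.intron_id] for r in self.introns],
            }
        ).set_index("intron_id")


def simulate_genome(config: SimConfig, seed: int) -> SimGenome:
    """Generate gene models (with exon-skipping isoform pairs) and sequence.

    Deterministic given (config, seed): two runs produce byte-identical
    annotation and genome text.
    """
    rng = _rng(seed, "genome")
    classes = sorted(config.class_mixture)
    probs = np.array([config.class_mixture[c] for c in classes])
    pos = config.gene_gap
    seq_parts = [_random_seq(rng, config.gene_gap, 0.40)]
    genes: list[GeneModel] = []
    gene_class: dict[str, str] = {}
    intron_class_by_pos: dict[str, list[str]] = {}  # gene -> classes left-to-right
    skipped: dict[str, tuple[int, int] | None] = {}

    for gi in range(config.n_genes):
        gene_id = f"g{gi + 1:04d}"
        g_class = classes[rng.choice(len(classes), p=probs)]
        gene_class[gene_id] = g_class
        n_introns = int(rng.integers(config.introns_per_gene[0],
                                     config.introns_per_gene[1] + 1))
        focal_pos = int(rng.integers(0, n_introns))
        per_intron = ["none"] * n_introns
        per_intron[focal_pos] = g_class
        intron_class_by_pos[gene_id] = per_intron
        strand = "+" if gi % 2 == 0 else "-"

        exons: list[tuple[int, int]] = []
        cur = pos
        for k in range(n_introns + 1):
            elen = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            exons.append((cur, cur + elen))
            seq_parts.append(_random_seq(rng, elen, config.gc_exon))
            cur += elen
            if k < n_introns:
                cls = per_intron[k]
                lo, hi = (
                    config.change_intron_length
                    if cls in ("up", "down")
                    else config.intron_length
                )
                ilen = int(rng.integers(lo, hi + 1))
                gclo, gchi = config.gc_by_class[cls]
                seq_parts.append(
                    _random_seq(rng, ilen, float(rng.uniform(gclo, gchi)))
                )
                cur += ilen
        transcripts = {f"{gene_id}.t1": list(exons)}
        skipped[gene_id] = None
        if len(exons) >= 3 and rng.random() < config.skipping_fraction:
            j = int(rng.integers(1, len(exons) - 1))
            transcripts[f"{gene_id}.t2"] = [e for i, e in enumerate(exons) if i != j]
            skipped[gene_id] = exons[j]
        genes.append(
            GeneModel(gene_id=gene_id, chrom=config.chrom, strand=strand,
                      transcripts=transcripts)
        )
        seq_parts.append(_random_seq(rng, config.gene_gap, 0.40))
        pos = cur + config.gene_gap

    sequences = {config.chrom: "".join(seq_parts)}
    introns: list[IntronRecord] = []
    intron_class: dict[str, str] = {}
    focal_intron: dict[str, str] = {}
    shared_exonic: dict[str, list] = {}
    semi_exonic: dict[str, list] = {}
    for gene in genes:
        shared = compute_shared_regions(gene)
        records = build_intron_records(shared)
        records = annotate_features(records, sequences)
        records_lr = sorted(records, key=lambda r: r.interval.start)
        per_intron = intron_class_by_pos[gene.gene_id]
        assert len(records_lr) == len(per_intron), (
            f"{gene.gene_id}: shared-region reduction changed intron count"
        )
        for k, rec in enumerate(records_lr):
            intron_class[rec.intron_id] = per_intron[k]
            if per_intron[k] == gene_class[gene.gene_id]:
                focal_intron.setdefault(gene.gene_id, rec.intron_id)
        # a 'none' gene's focal intron is just its designated none intron
        if gene.gene_id not in focal_intron:
            focal_intron[gene.gene_id] = records_lr[0].intron_id
        introns.extend(records_lr)
        shared_exonic[gene.gene_id] = shared.shared_exonic
        all_exonic = merge_intervals(
            [iv for ex in gene.transcripts.values() for iv in ex]
        )
        semi_exonic[gene.gene_id] = subtract_intervals(
            all_exonic, shared.shared_exonic
        )
    return SimGenome(
        genes=genes,
        sequences=sequences,
        introns=introns,
        intron_class=intron_class,
        gene_class=gene_class,
        focal_intron=focal_intron,
        shared_exonic=shared_exonic,
        semi_exonic=semi_exonic,
        chrom=config.chrom,
    )


@dataclass
class GroundTruth:
    """True per-intron retention trajectories and per-gene abundances."""

    n_timepoints: int
    gamma: float
    beta: float
    intron_class: dict[str, str]
    rho: dict[str, np.ndarray]             # intron_id -> rho_t
    expected_iri: dict[str, np.ndarray]    # intron_id -> IRI_t closed form
    gene_class: dict[str, str]
    focal_intron: dict[str, str]
    T: dict[str, np.ndarray]               # gene_id -> transcription rate per t
    S: dict[str, np.ndarray]               # spliced abundance
    R: dict[str, np.ndarray]               # retained abundance

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for intron_id, cls in self.intron_class.items():
            row = {"intron_id": intron_id, "true_class": cls}
            for t in range(self.n_timepoints):
                row[f"rho_t{t + 1}"] = self.rho[intron_id][t]
                row[f"expected_iri_t{t + 1}"] = self.expected_iri[intron_id][t]
            rows.append(row)
        return pd.DataFrame(rows).set_index("intron_id")


def simulate_ir_trajectories(
    config: SimConfig, genome: SimGenome, seed: int
) -> GroundTruth:
    """Assign retention trajectories rho_t per intron and rates T per gene."""
    n = config.n_timepoints
    gamma, beta = config.gamma, config.intronic_background
    cut = config.retention_cutoff

    # feasibility of the configured amplitudes under gamma
    rho_needed = gamma * (cut - beta) / (1 + cut * (gamma - 1) - gamma * beta)
    for name, rng_hi in (("rho_high", config.rho_high),
                         ("rho_stable", config.rho_stable)):
        if float(expected_iri(rng_hi[1], gamma, beta)) < cut:
            raise ValueError(
                f"{name} amplitude incompatible with gamma={gamma}: expected "
                f"IRI cannot reach {cut}; need rho >= {rho_needed:.3f}"
            )

    rng = _rng(seed, "trajectories")
    rho: dict[str, np.ndarray] = {}
    eiri: dict[str, np.ndarray] = {}
    for rec in genome.introns:
        cls = genome.intron_class[rec.intron_id]
        if cls == "none":
            r = np.full(n, rng.uniform(*config.rho_none))
        elif cls == "stable":
            r = np.full(n, rng.uniform(*config.rho_stable))
        elif cls in ("up", "down"):
            lo = rng.uniform(*config.rho_low)
            hi = rng.uniform(*config.rho_high)
            r = np.linspace(lo, hi, n)
            if cls == "down":
                r = r[::-1].copy()
        elif cls == "irregular":
            hi = rng.uniform(*config.rho_high)
            lo = rng.uniform(*config.rho_low)
            r = np.array([hi if t % 2 == 0 else lo for t in range(n)])
        else:  # pragma: no cover
            raise ValueError(f"unknown class {cls!r}")
        rho[rec.intron_id] = r
        eiri[rec.intron_id] = expected_iri(r, gamma, beta)

    T: dict[str, np.ndarray] = {}
    S: dict[str, np.ndarray] = {}
    R: dict[str, np.ndarray] = {}
    for gene in genome.genes:
        t_rate = float(rng.uniform(*config.t_rate))
        T[gene.gene_id] = np.full(n, t_rate)
        focal_rho = rho[genome.focal_intron[gene.gene_id]]
        S[gene.gene_id] = T[gene.gene_id] * (1.0 - focal_rho)
        R[gene.gene_id] = T[gene.gene_id] * focal_rho / gamma
    return GroundTruth(
        n_timepoints=n,
        gamma=gamma,
        beta=beta,
        intron_class=dict(genome.intron_class),
        rho=rho,
        expected_iri=eiri,
        gene_class=dict(genome.gene_class),
        focal_intron=dict(genome.focal_intron),
        T=T,
        S=S,
        R=R,
    )


def simulate_coverage(
    config: SimConfig, genome: SimGenome, truth: GroundTruth, seed: int
) -> tuple[dict[str, CoverageTrack], pd.DataFrame]:
    """Per-sample Poisson coverage tracks plus the sample design table.

    Exonic bases of a gene receive mean ``depth * (S_t + R_t)``; each
    intron's bases receive ``depth * T_t * (rho_t / gamma + beta)``; exon
    bases present in only some isoforms receive half the exonic mean.
    """
    rng = _rng(seed, "coverage")
    n = config.n_timepoints
    L = genome.chrom_length
    means = [np.zeros(L) for _ in range(n)]
    for gene in genome.genes:
        gid = gene.gene_id
        exonic = config.depth * (truth.S[gid] + truth.R[gid])  # per time point
        for t in range(n):
            for s, e in genome.shared_exonic[gid]:
                means[t][s:e] = exonic[t]
            for s, e in genome.semi_exonic[gid]:
                means[t][s:e] = 0.5 * exonic[t]
    for rec in genome.introns:
        gid = rec.gene_id
        mu = config.depth * truth.T[gid] * (
            truth.rho[rec.intron_id] / config.gamma + config.intronic_background
        )
        for t in range(n):
            means[t][rec.interval.start : rec.interval.end] = mu[t]

    tracks: dict[str, CoverageTrack] = {}
    design_rows = []
    for t in range(n):
        group = f"T{t + 1}"
        for rep in range(1, config.replicates + 1):
            sid = f"{group}_rep{rep}"
            depths = rng.poisson(means[t]).astype(np.float64)
            total_mapped = max(float(depths.sum()) / config.read_length, 1.0)
            tracks[sid] = CoverageTrack(
                sample_id=sid,
                depths={genome.chrom: depths},
                total_mapped=total_mapped,
            )
            design_rows.append(
                {"sample_id": sid, "group": group, "replicate": rep,
                 "total_mapped": total_mapped}
            )
    design = pd.DataFrame(design_rows)
    return tracks, design


def simulate_rbp_sites(
    config: SimConfig, genome: SimGenome, truth: GroundTruth, seed: int
) -> tuple[pd.DataFrame, dict]:
    """Place RBP binding sites; the planted regulator is enriched in
    change-class (up/down) introns by ``rbp_enrichment``x.

    Returns a BED-like DataFrame (chrom, start, end, rbp, score, strand)
    and a manifest of true placement rates.
    """
    rng = _rng(seed, "sites")
    roster = [config.planted_rbp] + [
        f"RBP_D{i + 1:02d}" for i in range(config.n_decoy_rbps)
    ]
    rows = []
    manifest = {}
    for rbp in roster:
        enrich = config.rbp_enrichment if rbp == config.planted_rbp else 1.0
        manifest[rbp] = {"base_rate_per_kb": config.rbp_base_rate,
                         "change_intron_enrichment": enrich}
        for rec in genome.introns:
            cls = truth.intron_class[rec.intron_id]
            rate = config.rbp_base_rate * (
                enrich if cls in ("up", "down") else 1.0
            )
            n_sites = int(rng.poisson(rate * rec.length / 1000.0))
            if n_sites == 0:
                continue
            max_start = max(rec.interval.end - config.rbp_site_length,
                            rec.interval.start + 1)
            starts = rng.integers(rec.interval.start, max_start, size=n_sites)
            for s in sorted(int(x) for x in starts):
                rows.append(
                    {
                        "chrom": rec.interval.chrom,
                        "start": s,
                        "end": min(s + config.rbp_site_length, rec.interval.end),
                        "rbp": rbp,
                        "score": 0,
                        "strand": rec.interval.strand,
                    }
                )
    sites = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "rbp", "score", "strand"]
    )
    return sites, manifest


def simulate_rbp_expression(config: SimConfig, seed: int) -> dict[str, pd.DataFrame]:
    """Per-model RBP expression tables (RPKM) for the candidate screen.

    The planted regulator drops ``rbp_drop_fold``-fold from the early to the
    late group in the first ``rbp_drop_models`` models and stays flat
    elsewhere; decoys are flat everywhere. Multiplicative log-normal noise.
    """
    rng = _rng(seed, "rbp_expression")
    roster = [config.planted_rbp] + [
        f"RBP_D{i + 1:02d}" for i in range(config.n_decoy_rbps)
    ]
    base = {config.planted_rbp: config.rbp_planted_expression}
    for rbp in roster[1:]:
        base[rbp] = float(rng.uniform(12.0, 60.0))
    tables = {}
    for mi, model in enumerate(config.rbp_models):
        rows = []
        for rbp in roster:
            drop = (
                config.rbp_drop_fold
                if rbp == config.planted_rbp and mi < config.rbp_drop_models
                else 1.0
            )
            for group, mean in (("early", base[rbp]), ("late", base[rbp] / drop)):
                for rep in range(1, config.rbp_expression_reps + 1):
                    noise = float(rng.lognormal(0.0, 0.05))
                    rows.append(
                        {"rbp": rbp, "group": group, "replicate": rep,
                         "value": mean * noise}
                    )
        tables[model] = pd.DataFrame(rows)
    return tables


@dataclass
class SimulationResult:
    config: SimConfig
    seed: int
    genome: SimGenome
    truth: GroundTruth
    tracks: dict[str, CoverageTrack]
    design: pd.DataFrame
    rbp_sites: pd.DataFrame
    rbp_manifest: dict
    rbp_expression: dict[str, pd.DataFrame]


def simulate_bundle(config: SimConfig, seed: int,
                    with_rbp: bool = True) -> SimulationResult:
    """Run every simulation stage; all stages derive from one master seed."""
    genome = simulate_genome(config, seed)
    truth = simulate_ir_trajectories(config, genome, seed)
    tracks, design = simulate_coverage(config, genome, truth, seed)
    if with_rbp:
        sites, manifest = simulate_rbp_sites(config, genome, truth, seed)
        expression = simulate_rbp_expression(config, seed)
    else:
        sites = pd.DataFrame(
            columns=["chrom", "start", "end", "rbp", "score", "strand"]
        )
        manifest, expression = {}, {}
    return SimulationResult(
        config=config, seed=seed, genome=genome, truth=truth, tracks=tracks,
        design=design, rbp_sites=sites, rbp_manifest=manifest,
        rbp_expression=expression,
    )


def genome_to_gtf(genome: SimGenome) -> str:
    """Annotation as GTF text (1-based inclusive exon records)."""
    lines = []
    for gene in genome.genes:
        for tx_id in sorted(gene.transcripts):
            for s, e in gene.transcripts[tx_id]:
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx_id}";'
                lines.append(
                    "\t".join(
                        [gene.chrom, "iriseq_sim", "exon", str(s + 1), str(e),
                         ".", gene.strand, ".", attrs]
                    )
                )
    return "\n".join(lines) + "\n"


def genome_to_fasta(genome: SimGenome, width: int = 60) -> str:
    parts = []
    for chrom in sorted(genome.sequences):
        seq = genome.sequences[chrom]
        parts.append(f">{chrom}")
        parts.extend(seq[i : i + width] for i in range(0, len(seq), width))
    return "\n".join(parts) + "\n"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(result: SimulationResult, out_dir: str | Path) -> dict:
    """Write the simulated dataset as the standard formats the pipeline reads.

    GTF, FASTA, per-sample bedGraph, design TSV, binding-site BED, ground
    truth TSV, per-model RBP expression TSVs, and a JSON manifest recording
    the config, master seed, and a sha256 checksum per file. Regenerating
    with the same config and seed reproduces every file byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "coverage").mkdir(exist_ok=True)
    files: dict[str, str] = {}

    (out / "annotation.gtf").write_text(genome_to_gtf(result.genome))
    (out / "genome.fa").write_text(genome_to_fasta(result.genome))
    for sid in sorted(result.tracks):
        write_bedgraph(result.tracks[sid], out / "coverage" / f"{sid}.bedgraph")
    result.design.to_csv(out / "design.tsv", sep="\t", index=False)
    result.rbp_sites.to_csv(out / "rbp_sites.bed", sep="\t", index=False,
                            header=False)
    truth_df = result.truth.to_frame()
    meta = result.genome.introns_frame()
    truth_df.join(meta[["gene_id", "length", "gc_content"]]).to_csv(
        out / "ground_truth.tsv", sep="\t"
    )
    if result.rbp_expression:
        (out / "rbp_expression").mkdir(exist_ok=True)
        for model in sorted(result.rbp_expression):
            result.rbp_expression[model].to_csv(
                out / "rbp_expression" / f"{model}.tsv", sep="\t", index=False
            )

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            files[str(p.relative_to(out))] = _sha256(p)
    manifest = {
        "seed": result.seed,
        "config": _config_to_jsonable(result.config),
        "rbp_truth": result.rbp_manifest,
        "files": files,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _config_to_jsonable(config: SimConfig) -> dict:
    d = asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
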