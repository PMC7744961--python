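# Methods

## Scope and model

`iriseq` quantifies intron retention (IR) from per-base RNA-seq coverage and
follows its dynamics. The quantity of interest is the intron retention index

IRI(i, s) = d_intron(i, s) / d_flank(i, s),

the ratio of mean per-base depth over intron *i* to the pooled mean depth
over its two flanking exonic segments in sample *s*. The ratio is a
read-length-free density contrast: 0 for a fully spliced intron, 1 for an
intron retained at the level of its flanks. Depth ratios are invariant under
uniform scaling of a sample's coverage, so no library-size normalization
enters the IRI itself (the test suite asserts this to 1e-12).

### Shared-region reduction

Multi-isoform annotation makes "intronic" ambiguous. All region math
therefore runs on the gene's shared regions: a base is **shared exonic** iff
it is exonic in every annotated isoform, and **shared intronic** iff, for
every isoform, it lies strictly between that isoform's first and last exon
and is not exonic in it. Bases outside any isoform's span belong to neither
set — a deliberate conservative choice that avoids calling UTR-adjacent gaps
introns when isoforms have different spans. An intron record is built for
each shared intronic segment that has a shared exonic segment on **both**
sides (the whole nearest segment serves as the flank; no fixed window);
edge segments without both flanks are dropped. Intron ordinals follow
transcription order, so minus-strand genes number right to left. The
reduction is implemented as sorted-interval algebra and is checked against a
brute-force per-base labeling oracle on hundreds of random gene models.

### Quantification filters

Per cell (intron × sample): the IRI is left missing when fewer than 50% of
intron bases have depth ≥ 1 (`low_coverage`) or the flank density is zero
(`zero_flank`). Per row (intron): any IRI > 1 in any sample discards the
intron (values above 1 indicate missing annotation, not retention), and any
missing cell discards it too, because both classifiers need complete
vectors. Both flanking segments are pooled length-weighted into a single
denominator rather than averaged per flank. Surviving values lie in [0, 1];
retention calls use IRI ≥ 0.1.

### Gene expression

Expression is an exonic-density FPKM: summed depth over the gene's shared
exonic bases divided by a configured read length (default 100 bp)
approximates the fragment count, scaled per kilobase of shared-exon length
per million mapped reads. This is intentionally simple — it feeds only the
expressed-gene filter (group-mean FPKM > 1 in ≥ 1 group, strict) and log2
fold changes with a pseudocount (default 0.1 FPKM); isoform-resolved
quantification and dispersion modeling are out of scope.

## Classification

Time-series mode labels each intron's vector X of per-time-point IRI means
by five **sequential** rules (each applies only after the previous failed):
`no_IR` if max(X) < 0.1; `stable_IR` if max(X) − min(X) < 0.1; `up_IR` if
Pearson Cor(X, L) > 0.7 against the monotone reference L = (0, …, 1) in
equal steps; `down_IR` if Cor(X, L) < −0.7; else `discarded`. The sequential
order means `stable_IR` implicitly requires max(X) ≥ 0.1, and the
correlation is never evaluated on a constant vector (max − min ≥ 0.1 there);
a zero-variance guard discards degenerate input anyway. Replicates are
averaged per time point before classification.

Two-condition mode uses ΔIRI = mean(B) − mean(A) on replicate IRIs:
`no_IR` when both condition means < 0.1; `stable_IR` when |ΔIRI| < 0.1;
`up_IR`/`down_IR` when ΔIRI ≥ 0.1 (≤ −0.1) with a two-sided pooled-variance
Student t-test p < 0.05; else `discarded`. Welch's test would also be
defensible at n = 2–3 replicates; the pooled choice is recorded in the
output metadata so it can be swapped. No multiple-testing correction is
applied to these per-intron tests.

## Expression coupling read-outs

Gene-level class sets lift intron labels to genes (a gene is `up_IR` if any
intron is; `no_IR` only if all are; `change_IR` = up ∪ down). Two read-outs
detect degradation coupling:

* **Per-class contrasts** — one-sided Wilcoxon rank-sum of expression log2
  fold changes: up_IR genes shifted below no_IR genes, down_IR above.
* **Binned trend** — each gene is represented by its intron with the
  largest |ΔIRI|; genes are octiled (equal-count bins, ties broken by a
  stable sort on gene id, hence bit-reproducible) by IRI fold change
  (mean IRI_B + 0.01)/(mean IRI_A + 0.01), and the Spearman ρ of bin index
  vs per-bin median expression log2FC is the trend statistic.

**Estimator-artifact guard.** By default only genes whose representative
intron changes retention by ≥ 0.1 (the change cutoff) enter the binned
trend. The flanking-exon coverage appears in both the IRI denominator and
the gene's FPKM, so for genes with no true retention change the IRI "fold
change" is shared measurement noise that is anti-correlated with the
expression fold change — a spurious ratio correlation that tilts the trend
negative even when no coupling exists (we measured mean ρ ≈ −0.2 to −0.4 on
decoupled data without the guard, ≈ −0.07 with it). Set `min_abs_delta=0`
to bin every quantified gene.

## RBP screens

Binding sites (BED; name column = RBP) are indexed per chromosome with
interval trees; a site counts toward an intron when it overlaps by ≥ 1 bp,
and density is sites per kb of intron. The candidate screen requires
(1) one-sided Wilcoxon rank-sum p < 0.05 for higher density in retained
(up/down/stable) vs spliced (no_IR) introns in **every** supplied dataset —
configurable to change-class-only; (2) a two-sided Student t-test on
replicate expression between the first and last passage group significant
in ≥ 2 of the supplied senescence models; (3) group-mean expression > 10
RPKM in ≥ 1 passage of a designated model. The target screen requires a
changed label in both classifications, sign(expression log2FC) opposite to
sign(ΔIRI), and ≥ 1 peak in the intron or either flanking exon; output is
ranked by |ΔIRI|. Rank-based tests use exact enumeration for small untied
samples and the tie-corrected normal approximation otherwise (scipy's
default policy).

## Synthetic data generator

The generator emulates a passage-series RNA-seq study with known truth. Per
gene: transcription rate T (relative, uniform on [1, 2]); one focal intron
carrying the gene's trajectory class from the mixture {none 0.20,
stable 0.20, up 0.25, down 0.25, irregular 0.10}; remaining introns are
'none' background — mirroring the observation that most IR-containing genes
harbor a single event, and keeping the abundance closed form exact:
S_t = T(1 − ρ_t) spliced and R_t = Tρ_t/γ retained transcripts, with decay
factor γ (default 5) the fold-increase in decay rate of intron-retained
transcripts. The expected retention index is

IRI_t = (ρ_t/γ + β) / (1 − ρ_t(1 − 1/γ)),

where β (default 0.04 of the gene's exonic signal) is a nascent pre-mRNA
background on intronic bases: intronic coverage in real polyA+ data never
falls to zero for expressed genes, and without it low-retention introns
(ρ ≈ 0.02–0.08 at γ = 5 means ~0.1 reads/base at 30×) would fail the 50%
coverage filter and no rising trajectory could survive to be classified.
With β = 0 the expression reduces to R/(S + R).

Trajectories over n = 5 time points: 'up' rises linearly from ρ ∈
U(0.02, 0.08) to U(0.45, 0.60) (expected IRI ≈ 0.05 → 0.2–0.3); 'down' is
the mirror; 'stable' is constant ρ ∈ U(0.30, 0.50) (IRI ≥ 0.1 by the
feasibility check, which errors with the required ρ bound if the amplitude
cannot reach the retention cutoff under γ); 'none' is constant
ρ ∈ U(0, 0.05) (IRI < 0.1 at all t); 'irregular' alternates between the
amplitude extremes, guaranteeing |Cor(X, L)| far below 0.7 at n = 5 and
exercising the discard rule. Coverage is drawn per base as independent
Poisson (the IRI consumes depth, so simulating read placement would add
machinery without exercising anything downstream; no positional
autocorrelation is modeled): shared exonic bases at depth·(S_t + R_t) with
target exon depth 30×, intron bases at depth·T·(ρ_t/γ + β), and
partially-shared exon bases (the planted exon-skipping isoforms, 30% of
genes) at half the exonic mean. Defaults give ~300 introns over 100 genes,
5 × 3 samples. RBP sites are Poisson-placed at 2 sites/kb in introns; a
planted regulator is 5× enriched in change-class introns, and its
expression drops 2-fold from early to late groups in 3 of 6 simulated
senescence models (log-normal noise, σ = 0.05); 20 decoy RBPs are flat.
Each component (genome, trajectories, coverage, sites, RBP expression) has
its own RNG stream derived from the master seed, so adding an RBP cannot
perturb coverage; identical seeds reproduce byte-identical fixture bundles.

### What passing tests do and do not show

The generator validates the pipeline's statistical machinery — estimator
accuracy (mean |measured − expected| IRI < 0.02 at 30×), label recovery
(≥ 95% of up/down, < 5% of none mislabeled, pooled over 10 seeds), coupling
detection (mean 8-bin ρ ≤ −0.8 at γ = 5, |mean ρ| ≤ 0.3 at γ = 1), and
screen specificity (planted regulator in ≥ 18/20 runs, decoys ≤ 5%). It does
not emulate positional coverage bias (GC, fragment-length, 3′ bias),
overlapping genes, antisense signal, annotation errors, or partial/nested
retention, so passing tests certify the method's correctness under its own
model, not performance on any particular real dataset.

## Numerical choices and degenerate inputs

Thresholds: retention cutoff 0.1, change cutoff 0.1, correlation cutoff 0.7,
alpha 0.05 — all configurable, all validated to (0, 1). Pseudocounts: 0.01
on IRI ratios, 0.1 FPKM on expression ratios, both small relative to the
0.1 cutoffs and recorded in outputs. Coordinates are 0-based half-open
internally; GTF converts from 1-based inclusive at the boundary; refFlat is
native 0-based. GC content excludes N bases from numerator and denominator.
Constant IRI vectors cannot reach the correlation rules by construction;
NaN t-test p-values (zero variance in both groups) yield `discarded`.
Empty inputs produce empty outputs rather than errors wherever a downstream
count can still be reported. Overlapping genes are processed independently;
introns shared between genes are not deduplicated.

## Known limitations

Strand-unaware coverage (the IRI definition is strand-agnostic; stranded
bedGraph pairs can be quantified per strand by running twice); no
isoform-resolved expression; no multiple-testing correction in the
per-intron two-condition tests; the two-condition ΔIRI uses replicate means
rather than a per-replicate statistic; splice-site strength scoring and
coordinate liftover are out of scope (inputs must share one genome build).
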