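# iriseq

Intron-retention dynamics from RNA-seq coverage: quantify per-intron
retention, classify how it changes across a time course or between two
conditions, relate retention changes to gene-expression changes, and screen
RNA-binding proteins (RBPs) and their candidate target introns.

## Who this is for

Transcriptomics analysts studying intron retention (IR) in longitudinal bulk
RNA-seq designs — e.g. replicative-senescence passage series, knockdown vs
control contrasts — who need a tested, self-contained pipeline from per-base
coverage to intron trajectory labels, expression coupling, and RBP screens.
Everything runs on plain-text standard formats (GTF/refFlat, FASTA, bedGraph,
BED, TSV) and a bundled synthetic-data generator makes every stage verifiable
against known ground truth without any downloads.

## The method

**Intron retention index (IRI).** For each intron *i* in sample *s*,

```
IRI(i, s) = read density over the intron / pooled read density over its two
            flanking exonic segments
```

where read density is mean per-base depth. To avoid interference from
alternative isoforms, both numerator and denominator are computed over
*shared* regions only: bases intronic (exonic) in **every** annotated isoform
of the gene. Filters: an intron cell is missing when < 50% of intron bases
are covered or the flank density is zero; any intron with IRI > 1 in any
sample (a signature of missing annotation), or a missing cell, is discarded,
so surviving IRI values lie in [0, 1]. An intron counts as retained when
IRI ≥ 0.1.

**Trajectory classification.** With IRI vector *X* = (X₁ … Xₙ) over *n*
ordered time points (replicate means) and the monotone reference
*L* = (0, 1/(n−1), …, 1), five sequential rules label each intron:

1. `no_IR`     if max(X) < 0.1
2. `stable_IR` if max(X) − min(X) < 0.1
3. `up_IR`     if Cor(X, L) > 0.7   (Pearson)
4. `down_IR`   if Cor(X, L) < −0.7
5. `discarded` otherwise (irregular pattern)

For two-condition designs (e.g. knockdown vs control): ΔIRI = mean(B) −
mean(A); `no_IR` if both condition means < 0.1, `stable_IR` if |ΔIRI| < 0.1,
`up_IR`/`down_IR` if |ΔIRI| ≥ 0.1 with two-sided Student *t* p < 0.05, else
`discarded`.

**Expression coupling.** Intron-retained transcripts decay γ-fold faster
than spliced ones, so steady-state abundances are S = T(1−ρ) (spliced) and
R = Tρ/γ (retained) for transcription rate T and retention fraction ρ; the
exonic signal S + R = T(1 − ρ(1 − 1/γ)) falls as ρ rises whenever γ > 1.
The package detects this with per-class expression fold-change contrasts
(one-sided Wilcoxon rank-sum vs `no_IR` genes) and an 8-bin trend: genes
with a real retention change are octiled by IRI fold change and the Spearman
ρ of bin index vs median expression log2FC is reported.

**RBP screens.** Binding-site density (sites/kb, ≥ 1 bp overlap) feeds two
screens: candidate regulators must show (1) higher density in retained than
spliced introns in every dataset, (2) expression change between early and
late passages in ≥ 2 of 6 models, (3) expression > 10 RPKM; candidate target
introns of one RBP must change retention in both the replicative and the
knockdown comparison, anti-correlate with their gene's expression, and carry
a binding peak in the intron or a flanking exon.

## Worked example

```bash
python examples/classify_trajectories.py
```

simulates a 5-time-point × 3-replicate series (100 genes, ~300 shared
introns, 30× exon depth, decay factor γ = 5), quantifies IRI, classifies,
and prints:

```
label counts: {'no_IR': 219, 'stable_IR': 26, 'up_IR': 22, 'down_IR': 27,
               'discarded': 14, 'change_IR': 49, 'classified': 308}
truth -> label:
  down      -> down_IR    27
  irregular -> discarded  14
  none      -> no_IR      219
  stable    -> stable_IR  26
  up        -> up_IR      22
```

Every generative class maps to its intended label: monotone retention
trajectories to `up_IR`/`down_IR`, flat retained introns to `stable_IR`,
sub-cutoff introns to `no_IR`, alternating patterns to `discarded`.
`python examples/expression_coupling.py` then shows the degradation
coupling: with γ = 5 the up_IR gene class has median expression log2FC
−0.70 and down_IR +0.76 with an 8-bin trend of Spearman ρ = −1.0, while
γ = 1 data give class medians ≈ −0.01 and no trend. The other examples
(`simulate_and_quantify.py`, `rbp_screens.py`) demonstrate estimator
accuracy (mean |measured − expected| IRI ≈ 0.01 at 30×) and both screens
(the planted regulator is recovered; decoy false positives occur at the
nominal ~1% rate and the script flags them).

The same stages are available from the shell:

```bash
iriseq simulate --seed 3 --out demo/
iriseq quantify --annotation demo/annotation.gtf --coverage-dir demo/coverage \
                --design demo/design.tsv --genome demo/genome.fa --out iri.tsv
iriseq classify --iri iri.tsv --design demo/design.tsv --out labels.tsv
iriseq run --config run.yaml        # all stages + JSON run report
```

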