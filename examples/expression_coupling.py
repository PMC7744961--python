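"""Show how intron retention couples to steady-state gene expression.

Intron-retained transcripts decay gamma-fold faster than spliced ones, so a
gene's exonic signal S + R = T (1 - rho (1 - 1/gamma)) falls as its
retention rho rises whenever gamma > 1. Two read-outs detect this:
per-class expression fold-change contrasts (up_IR genes shift down, down_IR
genes shift up, vs no_IR) and the 8-bin trend (genes with a real retention
change octiled by IRI fold change; Spearman rho of bin index vs median
expression log2FC). With gamma = 1 the coupling disappears.
"""

from iriseq import (
    SimConfig,
    analyze_simulation,
    class_expression_contrast,
    gene_level_classes,
    simulate_bundle,
)

for gamma in (5.0, 1.0):
    result = simulate_bundle(SimConfig(gamma=gamma), seed=3, with_rbp=False)
    out = analyze_simulation(result)
    classes = gene_level_classes(out["classification"])
    contrast = class_expression_contrast(classes, out["fold_change"])
    trend = out["trend"]
    print(f"gamma = {gamma}")
    print(contrast[["n_genes", "median_log2fc", "p_value"]].round(4))
    print(f"  8-bin trend Spearman rho = {trend.rho:+.3f} "
          f"(p = {trend.p_value:.3g})")
print("-> with fast decay of retained transcripts (gamma=5) rising retention "
      "drives expression down (negative rho, up_IR median < 0 < down_IR "
      "median); with gamma=1 the trend vanishes.")
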