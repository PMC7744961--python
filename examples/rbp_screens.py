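"""Run both RBP screens on simulated data with a planted regulator.

The candidate screen flags an RBP when (1) its binding density is higher in
retained than in spliced introns, (2) its expression changes between early
and late passages in >= 2 of 6 senescence models, and (3) it is expressed
above 10 RPKM. The target screen then asks which individual introns a given
RBP regulates directly: changed retention in both the replicative and the
knockdown comparison, expression moving opposite to retention, and a
binding peak in the intron or a flanking exon.
"""

from dataclasses import replace

from iriseq import (
    SimConfig,
    analyze_simulation,
    rbp_candidate_screen,
    simulate_bundle,
    simulate_genome,
    simulate_ir_trajectories,
    simulate_rbp_expression,
    simulate_rbp_sites,
    target_gene_screen,
)
from iriseq.rbp import BindingSiteIndex

SEED = 4
cfg = SimConfig()

# --- candidate screen on the time-course dataset -------------------------
result = simulate_bundle(cfg, SEED)
out = analyze_simulation(result)
introns = result.genome.introns_frame().reset_index()
introns = introns.merge(
    out["classification"][["label"]].reset_index(), on="intron_id", how="inner"
)
index = BindingSiteIndex(sites=result.rbp_sites)
screen = rbp_candidate_screen({"timecourse": (index, introns)},
                              result.rbp_expression)
hits = screen[screen["candidate"]]
false_hits = [r for r in hits.index if r != cfg.planted_rbp]
print(f"candidate RBPs: {list(hits.index)} "
      f"(planted regulator: {cfg.planted_rbp}; "
      f"{len(screen) - len(hits)} decoys rejected)")
if false_hits:
    print(f"   note: {false_hits} are decoy false positives -- the three "
          "criteria test at nominal alpha=0.05 and do not eliminate chance "
          "hits; across seeds the decoy hit rate is ~1%.")

# --- target screen: same genes, a two-condition knockdown-style contrast --
kd_cfg = replace(cfg, n_timepoints=2)
kd = simulate_bundle(kd_cfg, SEED, with_rbp=False)  # same genome (same seed)
kd_out = analyze_simulation(kd, mode="two-condition")
shared = out["classification"].index.intersection(kd_out["classification"].index)
targets = target_gene_screen(
    out["classification"].loc[shared],
    kd_out["classification"].loc[shared],
    kd_out["fold_change"],
    index,
    result.genome.introns,
    rbp=cfg.planted_rbp,
)
candidates = targets[targets["candidate"]]
print(f"candidate target introns: {len(candidates)} of "
      f"{len(targets)} retention-changed introns, e.g.")
print(candidates.head(5)[["gene_id", "kd_label", "delta_iri",
                          "expression_log2fc"]].round(3))
print("-> introns that change in both comparisons, anti-correlate with "
      "their gene's expression, and carry a binding peak are direct-target "
      "candidates, ranked by |delta IRI|.")
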