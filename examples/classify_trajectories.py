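"""Classify intron-retention trajectories and compare with the known truth.

Each intron's per-time-point IRI vector X is labeled by five sequential
rules: no_IR (max(X) below the 0.1 retention cutoff), stable_IR (max - min
below the 0.1 change cutoff), up_IR / down_IR (Pearson correlation with the
monotone reference L = (0, 0.25, 0.5, 0.75, 1) beyond +/-0.7), else
discarded as irregular.
"""

import collections

from iriseq import (
    SimConfig,
    apply_iri_filters,
    build_iri_matrix,
    classify_all,
    label_counts,
    simulate_bundle,
)

result = simulate_bundle(SimConfig(), seed=2, with_rbp=False)
matrix = build_iri_matrix(result.tracks, result.genome.introns)
matrix, _ = apply_iri_filters(matrix)
table = classify_all(matrix, result.design, mode="timeseries")

print("label counts:", label_counts(table))

confusion = collections.Counter()
for intron_id, true_class in result.truth.intron_class.items():
    got = table.loc[intron_id, "label"] if intron_id in table.index else "filtered"
    confusion[(true_class, got)] += 1
print("truth -> label:")
for (truth, got), n in sorted(confusion.items()):
    print(f"  {truth:9s} -> {got:10s} {n}")
print("-> monotone trajectories land in up_IR/down_IR, flat retained introns "
      "in stable_IR, sub-cutoff introns in no_IR, and alternating patterns "
      "are discarded: the classifier recovers the generative classes.")
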