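"""Relating intron-retention dynamics to gene expression and sequence features.

Intron-retained transcripts decay faster than spliced ones, so a gene whose
intron retention rises should lose steady-state expression and vice versa.
This module implements the gene-level read-outs of that coupling:

* per-class expression fold-change contrasts (one-sided Wilcoxon rank-sum of
  up_IR vs no_IR and down_IR vs no_IR gene fold changes);
* the binned trend — genes octiled by their IRI fold change, per-bin median
  expression log2 fold change, Spearman rho of bin index vs median;
* sequence/binding feature contrasts between intron classes (GC, length,
  binding density);
* set-overlap arithmetic between gene sets from different comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GeneClassSets:
    """Gene membership per intron class; change_IR = up union down."""

    up_IR: set[str] = field(default_factory=set)
    down_IR: set[str] = field(default_factory=set)
    stable_IR: set[str] = field(default_factory=set)
    no_IR: set[str] = field(default_factory=set)

    @property
    def change_IR(self) -> set[str]:
        return self.up_IR | self.down_IR

    def get(self, name: str) -> set[str]:
        if name == "change_IR":
            return self.change_IR
        return getattr(self, name)


@dataclass
class BinTrend:
    table: pd.DataFrame  # per-bin: n_genes, iri_fc_min, iri_fc_max, median_log2fc
    rho: float
    p_value: float
    n_bins: int
    delta: float
    min_abs_delta: float


def gene_level_classes(classification: pd.DataFrame) -> GeneClassSets:
    """Lift intron labels to gene sets.

    A gene is in up_IR if any of its introns is up_IR (likewise down/stable);
    it is in no_IR only if *all* of its classified introns are no_IR.
    """
    if "gene_id" not in classification.columns:
        raise ValueError("classification table needs a gene_id column")
    sets = GeneClassSets()
    for label in ("up_IR", "down_IR", "stable_IR"):
        sets_attr = getattr(sets, label)
        sets_attr.update(
            classification.loc[classification["label"] == label, "gene_id"]
        )
    all_no = classification.groupby("gene_id")["label"].apply(
        lambda s: (s == "no_IR").all()
    )
    sets.no_IR.update(all_no.index[all_no])
    return sets


def expression_change(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    group_a: str,
    group_b: str,
    pseudocount: float = 0.1,
    genes: list[str] | None = None,
) -> pd.Series:
    """Per-gene log2((mean_B + pc) / (mean_A + pc)) between two groups."""
    for g in (group_a, group_b):
        if g not in set(design["group"]):
            raise ValueError(f"unknown group {g!r}")
    sa = list(design.loc[design["group"] == group_a, "sample_id"])
    sb = list(design.loc[design["group"] == group_b, "sample_id"])
    sub = expr if genes is None else expr.loc[genes]
    fc = np.log2((sub[sb].mean(axis=1) + pseudocount) / (sub[sa].mean(axis=1) + pseudocount))
    fc.name = "log2fc"
    return fc


def class_expression_contrast(
    classes: GeneClassSets, fc: pd.Series, min_genes: int = 3
) -> pd.DataFrame:
    """Per-class fold-change summaries and one-sided rank-sum tests vs no_IR.

    Tests: up_IR fold changes shifted *below* no_IR ('less'), down_IR shifted
    *above* no_IR ('greater'). Classes with fewer than ``min_genes`` genes
    are summarized but their test is skipped (p = NaN, note recorded).
    """
    rows = []
    no_fc = fc.loc[fc.index.intersection(list(classes.no_IR))]
    for label, alternative in (("up_IR", "less"), ("down_IR", "greater"),
                               ("stable_IR", None), ("no_IR", None)):
        vals = fc.loc[fc.index.intersection(list(classes.get(label)))]
        row = {
            "class": label,
            "n_genes": len(vals),
            "median_log2fc": float(vals.median()) if len(vals) else np.nan,
            "p_value": np.nan,
            "note": "",
        }
        if alternative is not None:
            if len(vals) < min_genes or len(no_fc) < min_genes:
                row["note"] = f"test skipped: <{min_genes} genes"
            else:
                row["p_value"] = float(
                    stats.mannwhitneyu(vals, no_fc, alternative=alternative).pvalue
                )
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")


def gene_iri_fold_change(
    matrix,
    design: pd.DataFrame,
    group_a: str,
    group_b: str,
    delta: float = 0.01,
) -> pd.DataFrame:
    """Per-gene IRI fold change (mean IRI_B + delta) / (mean IRI_A + delta).

    A gene with several quantified introns is represented by the intron with
    the largest |dIRI| between the two groups. Returns columns ``iri_fc``
    and ``abs_delta`` indexed by gene_id.
    """
    iri = matrix.iri
    meta = matrix.intron_meta
    sa = list(design.loc[design["group"] == group_a, "sample_id"])
    sb = list(design.loc[design["group"] == group_b, "sample_id"])
    mean_a = iri[sa].mean(axis=1)
    mean_b = iri[sb].mean(axis=1)
    df = pd.DataFrame(
        {
            "gene_id": meta["gene_id"],
            "abs_delta": (mean_b - mean_a).abs(),
            "iri_fc": (mean_b + delta) / (mean_a + delta),
        }
    )
    top = df.sort_values(["gene_id", "abs_delta"], kind="stable").groupby(
        "gene_id", sort=True
    ).tail(1)
    return top.set_index("gene_id")[["iri_fc", "abs_delta"]]


def iri_fc_binning(
    matrix,
    fc: pd.Series,
    design: pd.DataFrame,
    group_a: str,
    group_b: str,
    n_bins: int = 8,
    delta: float = 0.01,
    min_abs_delta: float = 0.1,
) -> BinTrend:
    """Octile genes by IRI fold change; per-bin median expression log2FC.

    Only genes whose representative intron changes retention by at least
    ``min_abs_delta`` (default: the standard change cutoff) are binned: for
    a gene with no real retention change the IRI "fold change" is pure
    measurement noise, and because the flanking-exon coverage enters both
    the IRI denominator and the gene's FPKM, that noise is anti-correlated
    with the expression fold change (spurious ratio correlation) and would
    tilt the trend even when no coupling exists. Set ``min_abs_delta=0`` to
    bin every quantified gene.

    Bins are equal-count, ordered by IRI fold change with ties broken by a
    stable sort on gene_id (bit-reproducible). The trend statistic is the
    Spearman rho of bin index vs per-bin median expression fold change.
    """
    gene_fc = gene_iri_fold_change(matrix, design, group_a, group_b, delta=delta)
    gene_fc = gene_fc[gene_fc["abs_delta"] >= min_abs_delta]
    genes = gene_fc.index.intersection(fc.index)
    if len(genes) < n_bins:
        raise ValueError(
            f"only {len(genes)} genes with both an IRI change >= "
            f"{min_abs_delta} and an expression fold change; need >= "
            f"n_bins={n_bins} (use fewer bins)"
        )
    df = pd.DataFrame({"iri_fc": gene_fc.loc[genes, "iri_fc"],
                       "log2fc": fc.loc[genes]})
    df = df.sort_index(kind="stable").sort_values("iri_fc", kind="stable")
    bounds = np.linspace(0, len(df), n_bins + 1).round().astype(int)
    chunks = [df.iloc[bounds[i] : bounds[i + 1]] for i in range(n_bins)]
    rows = []
    for i, chunk in enumerate(chunks, 1):
        rows.append(
            {
                "bin": i,
                "n_genes": len(chunk),
                "iri_fc_min": float(chunk["iri_fc"].min()),
                "iri_fc_max": float(chunk["iri_fc"].max()),
                "median_log2fc": float(chunk["log2fc"].median()),
            }
        )
    table = pd.DataFrame(rows).set_index("bin")
    rho, p = stats.spearmanr(table.index, table["median_log2fc"])
    return BinTrend(table=table, rho=float(rho), p_value=float(p),
                    n_bins=n_bins, delta=delta, min_abs_delta=min_abs_delta)


def feature_contrast(
    features: pd.DataFrame,
    feature: str,
    class_a: str,
    class_b: str,
    alternative: str = "greater",
    min_n: int = 3,
) -> dict:
    """Wilcoxon rank-sum contrast of one feature between two intron classes.

    ``features`` must carry a 'label' column (change_IR matches up or down)
    and the named feature column. ``alternative`` tests class_a vs class_b.
    Exact p for small untied samples, normal approximation with tie
    correction otherwise (scipy's 'auto' policy).
    """
    if feature not in features.columns:
        raise ValueError(f"unknown feature {feature!r}")

    def _select(label: str) -> pd.Series:
        if label == "change_IR":
            mask = features["label"].isin(["up_IR", "down_IR"])
        else:
            mask = features["label"] == label
        return features.loc[mask, feature].dropna()

    a, b = _select(class_a), _select(class_b)
    if len(a) < min_n or len(b) < min_n:
        raise ValueError(
            f"need >= {min_n} introns per class, got {len(a)} vs {len(b)}"
        )
    res = stats.mannwhitneyu(a, b, alternative=alternative)
    return {
        "feature": feature,
        "class_a": class_a,
        "class_b": class_b,
        "n_a": len(a),
        "n_b": len(b),
        "alternative": alternative,
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
    }


def overlap_fraction(set_a: set, set_b: set) -> dict:
    """Overlap of gene set B with reference set A, as a percentage of |A|."""
    if not set_a:
        raise ValueError("reference set A is empty")
    n_overlap = len(set_a & set_b)
    n_a_only = len(set_a - set_b)
    return {
        "n_overlap": n_overlap,
        "n_A_only": n_a_only,
        "percentage": 100.0 * n_overlap / (n_overlap + n_a_only),
    }
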