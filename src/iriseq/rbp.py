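"""RBP binding-site density over intron classes and the two candidate screens.

Binding evidence (CLIP-derived intervals in BED) is reduced to a per-intron
site density (sites per kb, >= 1 bp overlap counts). Two screens follow:

* :func:`rbp_candidate_screen` — an RBP is a candidate regulator when (1) its
  binding density is significantly higher in retained introns than in spliced
  (no_IR) introns in *every* supplied dataset; (2) its expression differs
  significantly between earlier and later passages in at least ``min_models``
  of the supplied senescence models; and (3) its expression exceeds a floor
  (default 10 RPKM) in at least one passage of a designated model.

* :func:`target_gene_screen` — an intron is a candidate direct target of a
  given RBP when it changes class in both the knockdown and the replicative
  comparison, its gene's expression moves opposite to its retention change,
  and the RBP has >= 1 binding peak in the intron or either flanking exon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .intervals import GenomicInterval, IntronRecord

logger = logging.getLogger(__name__)

RETAINED_CLASSES = ("up_IR", "down_IR", "stable_IR")


@dataclass
class BindingSiteIndex:
    """RBP binding sites indexed per (rbp, chrom) for interval queries."""

    sites: pd.DataFrame  # chrom, start, end, rbp, source
    trees: dict[str, dict[str, IntervalTree]] = field(default_factory=dict)

    @property
    def rbp_names(self) -> list[str]:
        return sorted(self.sites["rbp"].unique()) if len(self.sites) else []

    def tree_for(self, rbp: str) -> dict[str, IntervalTree]:
        """Chrom -> IntervalTree for one RBP, or pooled over all ('all')."""
        if rbp not in self.trees:
            sub = (
                self.sites
                if rbp == "all"
                else self.sites[self.sites["rbp"] == rbp]
            )
            trees: dict[str, IntervalTree] = {}
            for chrom, grp in sub.groupby("chrom", sort=False):
                trees[chrom] = IntervalTree.from_tuples(
                    zip(grp["start"], grp["end"])
                )
            self.trees[rbp] = trees
        return self.trees[rbp]

    def count_overlapping(self, rbp: str, interval: GenomicInterval) -> int:
        trees = self.tree_for(rbp)
        tree = trees.get(interval.chrom)
        if tree is None:
            return 0
        return len(tree.overlap(interval.start, interval.end))


def load_binding_sites(path: str | Path) -> BindingSiteIndex:
    """Load a BED file of binding sites (>= 4 columns; name = RBP).

    Records with start >= end are rejected and logged. Coordinates are taken
    as 0-based half-open (BED convention).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: BED record needs >= 4 columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}")
            if start >= end:
                logger.warning(
                    "%s: line %d: start >= end, record rejected", path, lineno
                )
                continue
            rows.append(
                {
                    "chrom": fields[0],
                    "start": start,
                    "end": end,
                    "rbp": fields[3],
                    "source": fields[6] if len(fields) > 6 else "",
                }
            )
    sites = pd.DataFrame(rows, columns=["chrom", "start", "end", "rbp", "source"])
    return BindingSiteIndex(sites=sites)


def binding_density(
    index: BindingSiteIndex,
    introns: Sequence[IntronRecord] | pd.DataFrame,
    rbp: str = "all",
) -> pd.DataFrame:
    """Per-intron overlapping site count and density (sites per kb).

    ``introns`` may be IntronRecords or a DataFrame with intron_id, chrom,
    start, end, length columns. A site counts if it overlaps >= 1 bp.
    """
    if isinstance(introns, pd.DataFrame):
        it = [
            (row.intron_id, GenomicInterval(row.chrom, int(row.start), int(row.end)),
             int(row.length))
            for row in introns.reset_index().itertuples()
        ]
    else:
        it = [(r.intron_id, r.interval, r.length) for r in introns]
    rows = []
    for intron_id, interval, length in it:
        n = index.count_overlapping(rbp, interval)
        rows.append(
            {
                "rbp": rbp,
                "intron_id": intron_id,
                "n_sites": n,
                "density": n / (length / 1000.0),
            }
        )
    return pd.DataFrame(rows, columns=["rbp", "intron_id", "n_sites", "density"])


@dataclass(frozen=True)
class ScreenConfig:
    density_alternative: str = "greater"
    density_alpha: float = 0.05
    expression_alpha: float = 0.05
    min_models: int = 2
    expression_floor: float = 10.0
    floor_model: str | None = None  # default: first supplied model
    retained_classes: tuple[str, ...] = RETAINED_CLASSES

    def __post_init__(self) -> None:
        for name in ("density_alpha", "expression_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


def _density_test(
    index: BindingSiteIndex,
    introns: pd.DataFrame,
    rbp: str,
    config: ScreenConfig,
) -> float:
    dens = binding_density(index, introns, rbp=rbp).set_index("intron_id")["density"]
    labels = introns.set_index("intron_id")["label"]
    retained = dens[labels.isin(config.retained_classes)]
    spliced = dens[labels == "no_IR"]
    if len(retained) < 3 or len(spliced) < 3:
        return np.nan
    return float(
        stats.mannwhitneyu(
            retained, spliced, alternative=config.density_alternative
        ).pvalue
    )


def rbp_candidate_screen(
    datasets: Mapping[str, tuple[BindingSiteIndex, pd.DataFrame]],
    expression: Mapping[str, pd.DataFrame],
    config: ScreenConfig = ScreenConfig(),
    rbps: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Screen RBPs by binding density, expression change, and expression floor.

    Parameters
    ----------
    datasets
        dataset name -> (binding-site index, intron table with intron_id,
        chrom, start, end, length, label columns). Criterion 1 must hold in
        every dataset.
    expression
        model name -> long DataFrame with columns rbp, group ('early'/'late'
        or the model's first/last passages), replicate, value. Criterion 2
        uses a two-sided Student t-test on the replicate values; criterion 3
        checks group-mean expression > floor in >= 1 group of the designated
        model (default: the first supplied model).

    Returns one row per RBP with per-criterion flags and statistics.
    """
    if not datasets:
        raise ValueError("need >= 1 dataset with class-labeled introns")
    model_names = list(expression)
    if len(model_names) < config.min_models:
        raise ValueError(
            f"need >= {config.min_models} model expression tables, "
            f"got {len(model_names)}"
        )
    floor_model = config.floor_model or model_names[0]
    if floor_model not in expression:
        raise ValueError(f"missing expression table for model {floor_model!r}")

    if rbps is None:
        names: set[str] = set()
        for index, _ in datasets.values():
            names.update(index.rbp_names)
        rbps = sorted(names)

    rows = []
    for rbp in rbps:
        dens_p = {
            ds: _density_test(index, introns, rbp, config)
            for ds, (index, introns) in datasets.items()
        }
        crit1 = all(
            (not np.isnan(p)) and p < config.density_alpha for p in dens_p.values()
        )
        n_sig = 0
        for model in model_names:
            tab = expression[model]
            sub = tab[tab["rbp"] == rbp]
            groups = list(dict.fromkeys(sub["group"]))
            if len(groups) < 2:
                continue
            early = sub.loc[sub["group"] == groups[0], "value"].to_numpy()
            late = sub.loc[sub["group"] == groups[-1], "value"].to_numpy()
            if len(early) < 2 or len(late) < 2:
                continue
            p = stats.ttest_ind(early, late, equal_var=True).pvalue
            if not np.isnan(p) and p < config.expression_alpha:
                n_sig += 1
        crit2 = n_sig >= config.min_models
        ftab = expression[floor_model]
        fsub = ftab[ftab["rbp"] == rbp]
        gmeans = fsub.groupby("group", sort=False)["value"].mean()
        max_expr = float(gmeans.max()) if len(gmeans) else 0.0
        crit3 = max_expr > config.expression_floor
        rows.append(
            {
                "rbp": rbp,
                "crit1_density": crit1,
                "crit2_expression_change": crit2,
                "crit3_expression_floor": crit3,
                "candidate": crit1 and crit2 and crit3,
                "max_density_p": float(np.nanmax(list(dens_p.values())))
                if dens_p else np.nan,
                "n_models_significant": n_sig,
                "max_expression": max_expr,
            }
        )
    out = pd.DataFrame(rows).set_index("rbp")
    out.attrs["expression_test"] = "student_t_pooled_two_sided"
    out.attrs["config"] = config
    return out


def target_gene_screen(
    class_replicative: pd.DataFrame,
    class_kd: pd.DataFrame,
    fc_kd: pd.Series,
    peaks: BindingSiteIndex,
    introns: Sequence[IntronRecord],
    rbp: str = "all",
) -> pd.DataFrame:
    """Screen introns for direct regulation by one RBP.

    An intron passes when (1) it is up_IR or down_IR in both the replicative
    and the knockdown classification; (2) its gene's expression log2FC in the
    knockdown comparison has the opposite sign to its dIRI; and (3) >= 1 peak
    of the RBP overlaps the intron or either flanking exon. Output is sorted
    by |dIRI| descending.
    """
    changed = {"up_IR", "down_IR"}
    missing = set(class_kd.index) ^ set(class_replicative.index)
    if missing:
        raise ValueError(
            "classification tables cover different introns: "
            + ", ".join(sorted(missing)[:10])
        )
    if "delta_iri" not in class_kd.columns:
        raise ValueError("knockdown classification lacks delta_iri (two-condition)")
    by_id = {r.intron_id: r for r in introns}
    rows = []
    for intron_id in class_kd.index:
        kd = class_kd.loc[intron_id]
        if kd["label"] not in changed:
            continue
        rep_label = class_replicative.loc[intron_id, "label"]
        crit1 = rep_label in changed
        gene = kd.get("gene_id")
        delta = float(kd["delta_iri"])
        fc = float(fc_kd.get(gene, np.nan))
        crit2 = bool(np.isfinite(fc) and fc * delta < 0)
        rec = by_id.get(intron_id)
        crit3 = False
        if rec is not None:
            crit3 = any(
                peaks.count_overlapping(rbp, iv) > 0
                for iv in (rec.interval, rec.flank_up, rec.flank_down)
            )
        rows.append(
            {
                "intron_id": intron_id,
                "gene_id": gene,
                "kd_label": kd["label"],
                "replicative_label": rep_label,
                "delta_iri": delta,
                "expression_log2fc": fc,
                "crit1_both_changed": crit1,
                "crit2_anticorrelated": crit2,
                "crit3_peak": crit3,
                "candidate": crit1 and crit2 and crit3,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "intron_id", "gene_id", "kd_label", "replicative_label", "delta_iri",
            "expression_log2fc", "crit1_both_changed", "crit2_anticorrelated",
            "crit3_peak", "candidate",
        ],
    )
    if len(out):
        out = out.reindex(
            out["delta_iri"].abs().sort_values(ascending=False, kind="stable").index
        ).set_index("intron_id")
    else:
        out = out.set_index("intron_id")
    return out
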