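"""Trajectory classification of intron-retention dynamics.

Two schemes, matching the two study designs:

* **Time series** (>= 2 ordered time points): the per-intron IRI vector
  ``X`` (replicate means per time point) is labeled by five sequential
  rules — ``no_IR`` if max(X) < retention cutoff; else ``stable_IR`` if
  max(X) - min(X) < change cutoff; else ``up_IR``/``down_IR`` by the
  Pearson correlation of X with the monotone reference sequence L
  (0 ... 1 in equal steps) exceeding +/-0.7; anything left is ``discarded``
  as an irregular pattern. Rules apply strictly in this order, so the
  correlation is only ever evaluated on vectors with real change.

* **Two conditions** (e.g. knockdown vs control, >= 2 replicates each):
  dIRI = mean(B) - mean(A); ``no_IR`` if both condition means are below the
  retention cutoff, ``stable_IR`` if |dIRI| is below the change cutoff,
  ``up_IR``/``down_IR`` when |dIRI| >= cutoff with a two-sided Student
  (pooled-variance) t-test p below alpha, otherwise ``discarded``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

LABELS = ("no_IR", "stable_IR", "up_IR", "down_IR", "discarded")


@dataclass(frozen=True)
class ClassifierConfig:
    retention_cutoff: float = 0.1
    change_cutoff: float = 0.1
    corr_cutoff: float = 0.7
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("retention_cutoff", "change_cutoff", "corr_cutoff", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass
class TrajectoryResult:
    intron_id: str
    label: str
    X: np.ndarray | None = None
    max_minus_min: float | None = None
    cor_with_L: float | None = None
    delta_iri: float | None = None
    p_value: float | None = None


def monotone_reference(n: int) -> np.ndarray:
    """The monotone reference sequence L: 0 ... 1 in n equal steps."""
    if n < 2:
        raise ValueError("monotone reference needs n >= 2 time points")
    return np.linspace(0.0, 1.0, n)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0:
        return np.nan
    return float((xd * yd).sum() / denom)


def classify_timeseries(
    x: Sequence[float],
    config: ClassifierConfig = ClassifierConfig(),
    intron_id: str = "",
) -> TrajectoryResult:
    """Label one intron's time-course IRI vector by the five sequential rules."""
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        raise ValueError("IRI vector contains missing values; filter upstream")
    if len(x) < 2:
        raise ValueError("need >= 2 time points")
    mmm = float(x.max() - x.min())
    res = TrajectoryResult(intron_id=intron_id, label="discarded", X=x,
                           max_minus_min=mmm)
    if x.max() < config.retention_cutoff:
        res.label = "no_IR"
        return res
    if mmm < config.change_cutoff:
        res.label = "stable_IR"
        return res
    r = pearson(x, monotone_reference(len(x)))
    res.cor_with_L = r
    if np.isnan(r):  # constant vector cannot reach here, but guard anyway
        res.label = "discarded"
    elif r > config.corr_cutoff:
        res.label = "up_IR"
    elif r < -config.corr_cutoff:
        res.label = "down_IR"
    else:
        res.label = "discarded"
    return res


def classify_two_condition(
    reps_a: Sequence[float],
    reps_b: Sequence[float],
    config: ClassifierConfig = ClassifierConfig(),
    intron_id: str = "",
) -> TrajectoryResult:
    """Label one intron from replicate IRIs in two conditions (B vs A)."""
    a = np.asarray(reps_a, dtype=float)
    b = np.asarray(reps_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per condition for the t-test")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("IRI replicates contain missing values; filter upstream")
    delta = float(b.mean() - a.mean())
    res = TrajectoryResult(
        intron_id=intron_id,
        label="discarded",
        X=np.array([a.mean(), b.mean()]),
        max_minus_min=abs(delta),
        delta_iri=delta,
    )
    if a.mean() < config.retention_cutoff and b.mean() < config.retention_cutoff:
        res.label = "no_IR"
        return res
    if abs(delta) < config.change_cutoff:
        res.label = "stable_IR"
        return res
    t = stats.ttest_ind(b, a, equal_var=True)
    res.p_value = float(t.pvalue)
    if np.isnan(t.pvalue):
        res.label = "discarded"
    elif delta >= config.change_cutoff and t.pvalue < config.alpha:
        res.label = "up_IR"
    elif delta <= -config.change_cutoff and t.pvalue < config.alpha:
        res.label = "down_IR"
    else:
        res.label = "discarded"
    return res


def _timeseries_means(
    iri: pd.DataFrame, design: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    order = list(dict.fromkeys(design["group"]))
    cols = {}
    for g in order:
        samples = design.loc[design["group"] == g, "sample_id"]
        cols[g] = iri[list(samples)].mean(axis=1)
    return pd.DataFrame(cols), order


def classify_all(
    matrix,
    design: pd.DataFrame,
    config: ClassifierConfig = ClassifierConfig(),
    mode: str = "timeseries",
) -> pd.DataFrame:
    """Classify every intron of a filtered IRI matrix.

    Returns a ClassificationTable DataFrame indexed by intron_id with columns
    gene_id, label and the supporting statistics for the chosen mode. The
    table's ``.attrs`` record the mode, config and the Student-t choice.
    """
    iri = matrix.iri if hasattr(matrix, "iri") else matrix
    meta = matrix.intron_meta if hasattr(matrix, "intron_meta") else None
    rows = []
    if mode == "timeseries":
        means, order = _timeseries_means(iri, design)
        if len(order) < 2:
            raise ValueError("time-series mode needs >= 2 ordered groups")
        for intron_id, x in means.iterrows():
            r = classify_timeseries(x.to_numpy(), config, intron_id=intron_id)
            rows.append(
                {
                    "intron_id": intron_id,
                    "label": r.label,
                    "max_minus_min": r.max_minus_min,
                    "cor_with_L": r.cor_with_L,
                    **{f"iri_{g}": v for g, v in zip(order, r.X)},
                }
            )
    elif mode == "two-condition":
        order = list(dict.fromkeys(design["group"]))
        if len(order) != 2:
            raise ValueError(
                f"two-condition mode needs exactly 2 groups, got {order}"
            )
        ga, gb = order
        sa = list(design.loc[design["group"] == ga, "sample_id"])
        sb = list(design.loc[design["group"] == gb, "sample_id"])
        for intron_id in iri.index:
            r = classify_two_condition(
                iri.loc[intron_id, sa].to_numpy(),
                iri.loc[intron_id, sb].to_numpy(),
                config,
                intron_id=intron_id,
            )
            rows.append(
                {
                    "intron_id": intron_id,
                    "label": r.label,
                    "delta_iri": r.delta_iri,
                    "p_value": r.p_value,
                    f"iri_{ga}": r.X[0],
                    f"iri_{gb}": r.X[1],
                }
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    table = pd.DataFrame(rows)
    if len(table):
        table = table.set_index("intron_id")
    else:
        table = pd.DataFrame(columns=["label"]).rename_axis("intron_id")
    if meta is not None and len(table):
        table.insert(0, "gene_id", meta.loc[table.index, "gene_id"])
    table.attrs["mode"] = mode
    table.attrs["config"] = config
    table.attrs["test"] = "student_t_pooled" if mode == "two-condition" else "pearson"
    return table


def label_counts(table: pd.DataFrame) -> dict[str, int]:
    """Per-label counts plus the changed-IR total (up_IR + down_IR)."""
    counts = {lab: int((table["label"] == lab).sum()) for lab in LABELS}
    counts["change_IR"] = counts["up_IR"] + counts["down_IR"]
    counts["classified"] = int(len(table))
    return counts
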