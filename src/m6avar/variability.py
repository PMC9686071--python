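"""Per-gene expression-variability statistics and HVG/LVG classification.

A gene's variability in one sample group is the squared coefficient of
variation of its replicate FPKMs, CV^2 = (scale * sd / mean)^2 with the
sample (n-1) standard deviation. Classification uses log2 CV^2 thresholds:
log2CV^2 above ``hvg_min`` -> highly variable gene (HVG), below ``lvg_max``
-> lowly variable gene (LVG). A gene with sd = 0 has log2CV^2 = -inf and is
an LVG (any finite lower threshold is satisfied); a gene with mean 0 is
``undefined``.

Note that with n nonnegative replicates the sample CV^2 is bounded by n, so
log2CV^2 <= log2 n; the shipped ``hvg_min`` default of 5 is therefore only
reachable under a rescaled CV (``cv_scale``, e.g. 100 for percent CV) and is
kept configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import ExpressionMatrix, GroupKey, logger

HVG = "HVG"
LVG = "LVG"
NEITHER = "neither"
UNDEFINED = "undefined"

QUARTILES = ("Q1", "Q2", "Q3", "Q4")


@dataclass(frozen=True)
class VariabilityThresholds:
    hvg_min: float = 5.0
    lvg_max: float = -10.0
    cv_scale: float = 1.0
    min_fpkm: float = 1.0  # group-mean floor applied before classification

    def __post_init__(self) -> None:
        if self.hvg_min <= self.lvg_max:
            raise ValueError("hvg_min must exceed lvg_max")
        if self.cv_scale <= 0:
            raise ValueError("cv_scale must be > 0")


def cv_squared(values, scale: float = 1.0) -> tuple[float, float, float]:
    """Return (mean, sd, cv2) of replicate FPKMs; cv2 is NaN when mean = 0.

    sd is the sample standard deviation (n-1 denominator).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 replicate values")
    if (arr < 0).any():
        raise ValueError("replicate values must be >= 0")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    cv2 = float("nan") if mean == 0 else (scale * sd / mean) ** 2
    return mean, sd, cv2


def classify_variability(log2cv2: float, thresholds: VariabilityThresholds) -> str:
    if np.isnan(log2cv2):
        return UNDEFINED
    if log2cv2 > thresholds.hvg_min:
        return HVG
    if log2cv2 < thresholds.lvg_max:  # -inf qualifies
        return LVG
    return NEITHER


def variability_table(
    expr: ExpressionMatrix,
    thresholds: VariabilityThresholds | None = None,
    groups: list[GroupKey] | None = None,
) -> pd.DataFrame:
    """One row per gene x group: mean, sd, cv2, log2cv2, class.

    Only input-fraction samples are used. Genes whose group mean FPKM falls
    below ``thresholds.min_fpkm`` are classed ``undefined`` (their CV^2 is
    numerically unstable), as are zero-mean genes.
    """
    thresholds = thresholds or VariabilityThresholds()
    groups = groups or expr.groups("input")
    records = []
    for grp in groups:
        block = expr.group_values(grp, "input")
        if block.shape[1] < 2:
            raise ValueError(f"group {grp.label()} has < 2 input replicates")
        arr = block.to_numpy(dtype=float)
        mean = arr.mean(axis=1)
        sd = arr.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv2 = np.where(mean > 0, (thresholds.cv_scale * sd / mean) ** 2, np.nan)
            log2cv2 = np.log2(cv2)  # cv2 = 0 -> -inf; undefined stays NaN
        for gi, gene in enumerate(block.index):
            if np.isnan(cv2[gi]) or mean[gi] < thresholds.min_fpkm:
                cls = UNDEFINED
            else:
                cls = classify_variability(log2cv2[gi], thresholds)
            records.append(
                (gene, grp.label(), mean[gi], sd[gi],
                 cv2[gi], log2cv2[gi] if not np.isnan(cv2[gi]) else np.nan, cls)
            )
    return pd.DataFrame(
        records,
        columns=["gene_id", "group", "mean", "sd", "cv2", "log2cv2", "class"],
    )


def class_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group HVG/LVG/neither/undefined counts from a variability table."""
    counts = (
        table.groupby(["group", "class"]).size().unstack(fill_value=0)
    )
    for cls in (HVG, LVG, NEITHER, UNDEFINED):
        if cls not in counts.columns:
            counts[cls] = 0
    return counts[[HVG, LVG, NEITHER, UNDEFINED]]


def variability_difference(
    expr: ExpressionMatrix,
    group_a: GroupKey,
    group_b: GroupKey,
    thresholds: VariabilityThresholds | None = None,
) -> pd.Series:
    """Per-gene delta log2CV^2 = log2cv2(group_b) - log2cv2(group_a).

    Genes undefined (or with cv2 = 0, hence log2cv2 = -inf) in either group
    are dropped; the dropped count is logged.
    """
    thresholds = thresholds or VariabilityThresholds()
    for grp in (group_a, group_b):
        if grp not in expr.groups("input"):
            raise KeyError(f"unknown group {grp.label()}")
    tab = variability_table(expr, thresholds, groups=[group_a, group_b])
    wide = tab.pivot(index="gene_id", columns="group", values="log2cv2")
    a, b = wide[group_a.label()], wide[group_b.label()]
    ok = np.isfinite(a) & np.isfinite(b)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("variability_difference: dropped %d undefined gene(s)", dropped)
    delta = (b - a)[ok]
    delta.name = "delta_log2cv2"
    return delta


def variability_quartiles(records: pd.DataFrame, group: str | None = None) -> pd.Series:
    """Map gene -> quartile Q1..Q4 by ascending log2cv2 (Q1 = least variable).

    Ties break by gene id; quartile sizes differ by at most one; genes with
    undefined cv2 are excluded.
    """
    tab = records
    if group is not None:
        tab = tab[tab["group"] == group]
    tab = tab[tab["cv2"].notna()]
    if len(tab) < 4:
        raise ValueError("need >= 4 genes with defined cv2")
    ordered = tab.sort_values(["log2cv2", "gene_id"], kind="mergesort")
    n = len(ordered)
    # split into 4 contiguous runs whose sizes differ by <= 1
    bounds = [round(i * n / 4) for i in range(5)]
    labels = np.empty(n, dtype=object)
    for q in range(4):
        labels[bounds[q]:bounds[q + 1]] = QUARTILES[q]
    return pd.Series(labels, index=ordered["gene_id"].to_numpy(), name="quartile")
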