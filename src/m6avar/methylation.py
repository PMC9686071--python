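"""m6A enrichment scoring, methylation calls, peak filtering and assignment.

Enrichment of a gene in a group is the log2 fold change of its mean IP
(m6A-immunoprecipitated) FPKM over its mean input FPKM, with a pseudocount
guarding zero means. A gene is called methylated when its enrichment is
strictly positive. Peaks are filtered for replicate reproducibility (kept
only when seen in both IP replicates) and assigned to genes by midpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .formats_io import (
    ExpressionMatrix,
    GenomicInterval,
    GroupKey,
    Peak,
    PeakSet,
    TranscriptModel,
    logger,
)

DEFAULT_PSEUDOCOUNT = 0.1  # FPKM


def enrichment_score(ip_values, input_values, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """log2((mean(ip)+pc) / (mean(input)+pc)); NaN when both means and pc are 0."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    ip = np.asarray(ip_values, dtype=float)
    inp = np.asarray(input_values, dtype=float)
    if ip.size == 0 or inp.size == 0:
        raise ValueError("replicate sets must be nonempty")
    if (ip < 0).any() or (inp < 0).any():
        raise ValueError("FPKM values must be >= 0")
    num = ip.mean() + pseudocount
    den = inp.mean() + pseudocount
    if num == 0 and den == 0:
        return float("nan")
    if num == 0:
        return float("-inf")
    if den == 0:
        return float("inf")
    return float(math.log2(num / den))


def enrichment_table(
    expr: ExpressionMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    groups: list[GroupKey] | None = None,
) -> pd.DataFrame:
    """Per gene x group enrichment records: ip_mean, input_mean, enrichment, methylated."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    groups = groups or expr.groups("IP")
    frames = []
    for grp in groups:
        ip = expr.group_values(grp, "IP").to_numpy(dtype=float).mean(axis=1)
        inp = expr.group_values(grp, "input").to_numpy(dtype=float).mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            enr = np.log2((ip + pseudocount) / (inp + pseudocount))
        enr = np.where((ip + pseudocount == 0) & (inp + pseudocount == 0), np.nan, enr)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": expr.genes,
                    "group": grp.label(),
                    "ip_mean": ip,
                    "input_mean": inp,
                    "enrichment": enr,
                    "methylated": enr > 0,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def call_methylated(records: pd.DataFrame, group: str | None = None, threshold: float = 0.0) -> set[str]:
    """Genes with enrichment strictly greater than ``threshold`` (per group)."""
    tab = records if group is None else records[records["group"] == group]
    return set(tab.loc[tab["enrichment"] > threshold, "gene_id"])


def methylated_counts(records: pd.DataFrame, threshold: float = 0.0) -> pd.Series:
    """Number of methylated genes per group."""
    return (
        records[records["enrichment"] > threshold].groupby("group").size().rename("n_methylated")
    )


def reproducible_peaks(rep1: PeakSet, rep2: PeakSet) -> PeakSet:
    """Keep rep1 peaks confirmed by >= 1 bp overlap with an unused rep2 peak.

    The output interval is the union of the matched pair and the score their
    mean; each rep2 peak is consumed at most once, matching greedily in
    ascending coordinate order.
    """
    if rep1.group is not None and rep2.group is not None and rep1.group != rep2.group:
        raise ValueError(
            f"group-key mismatch: {rep1.group.label()} vs {rep2.group.label()}"
        )
    a = rep1.sorted().peaks
    b = rep2.sorted().peaks
    used = [False] * len(b)
    out: list[Peak] = []
    j0 = 0
    for pa in a:
        ia = pa.interval
        match = None
        for j in range(j0, len(b)):
            ib = b[j].interval
            if ib.chrom < ia.chrom or (ib.chrom == ia.chrom and ib.end <= ia.start):
                if j == j0 and used[j]:
                    j0 = j + 1
                continue
            if ib.chrom > ia.chrom or ib.start >= ia.end:
                break
            if not used[j] and ia.overlap(ib) >= 1:
                match = j
                break
        if match is not None:
            used[match] = True
            ib = b[match].interval
            merged = GenomicInterval(
                ia.chrom, min(ia.start, ib.start), max(ia.end, ib.end), ia.strand
            )
            out.append(Peak(merged, (pa.score + b[match].score) / 2.0))
    return PeakSet(out, rep1.group, None)


@dataclass
class PeakAssignment:
    counts: pd.Series  # gene -> reproducible peak count
    assigned: list[tuple[Peak, str]]
    unassigned: list[Peak]


def assign_peaks(peaks: PeakSet, models: dict[str, TranscriptModel]) -> PeakAssignment:
    """Assign each peak to the gene whose transcript span contains its midpoint.

    Ties between overlapping genes break by largest overlap with the peak
    interval, then lexicographically smallest gene id. Midpoint uses integer
    floor division; unassigned peaks are counted and logged.
    """
    trees: dict[str, IntervalTree] = {}
    for gene_id, model in models.items():
        span = model.span
        trees.setdefault(span.chrom, IntervalTree()).addi(span.start, span.end, gene_id)
    counts = pd.Series(0, index=list(models), dtype=int, name="peak_count")
    assigned: list[tuple[Peak, str]] = []
    unassigned: list[Peak] = []
    for peak in peaks.peaks:
        iv = peak.interval
        mid = (iv.start + iv.end) // 2
        tree = trees.get(iv.chrom)
        hits = tree[mid] if tree is not None else set()
        if not hits:
            unassigned.append(peak)
            continue
        best = min(
            hits,
            key=lambda h: (-models[h.data].span.overlap(iv), h.data),
        )
        counts[best.data] += 1
        assigned.append((peak, best.data))
    if unassigned:
        logger.info("assign_peaks: %d unassigned peak(s)", len(unassigned))
    return PeakAssignment(counts, assigned, unassigned)


def differential_enrichment(
    wt_records: pd.DataFrame,
    mutant_records: pd.DataFrame,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Mutant-minus-wt enrichment deltas and the regulated-gene flag.

    A gene is regulated when its enrichment gain is at least
    log2(fold_threshold) (inclusive boundary). Genes with undefined
    enrichment in either genotype are dropped and counted.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    wt = wt_records.set_index("gene_id")["enrichment"]
    mut = mutant_records.set_index("gene_id")["enrichment"]
    shared = wt.index.intersection(mut.index)
    if shared.empty:
        raise ValueError("disjoint gene universes between genotypes")
    a, b = wt.loc[shared], mut.loc[shared]
    ok = np.isfinite(a) & np.isfinite(b)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("differential_enrichment: dropped %d undefined gene(s)", dropped)
    delta = (b - a)[ok]
    cut = math.log2(fold_threshold)
    return pd.DataFrame(
        {
            "gene_id": delta.index,
            "delta_enrichment": delta.to_numpy(),
            "regulated": delta.to_numpy() >= cut,
        }
    ).reset_index(drop=True)
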