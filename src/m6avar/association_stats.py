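"""Inferential layer: variability-methylation association, rank tests,
correlations, set overlaps and the heat-response matrix.

Group comparisons use the one-tailed Wilcoxon rank-sum (Mann-Whitney U)
test — exact null when both samples are small and tie-free, normal
approximation with tie and continuity corrections otherwise. Set overlaps
use the upper-tail hypergeometric probability. Random baselines are
size-matched draws without replacement from the complement of the query
set, seeded for reproducibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats_io import ExpressionMatrix, GroupKey
from .methylation import DEFAULT_PSEUDOCOUNT
from .variability import QUARTILES

EXACT_MAX_N = 20


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_value: float
    alternative: str
    n_x: int
    n_y: int


def rank_test_one_tailed(x, y, alternative: str) -> RankTestResult:
    """One-tailed Wilcoxon rank-sum test of x against y.

    ``alternative='less'`` tests whether x is stochastically smaller than y.
    The exact null distribution is used when n_x + n_y <= 20 and there are
    no ties; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= EXACT_MAX_N and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return RankTestResult(float(res.statistic), float(res.pvalue), alternative, x.size, y.size)


def fraction_methylated_by_quartile(
    quartiles: pd.Series, methylated_set: set[str]
) -> pd.DataFrame:
    """Per-quartile methylated-gene counts and fractions (plus monotonicity flag).

    ``quartiles`` maps gene id -> Q1..Q4 (Q1 = least variable). The returned
    frame carries a ``monotone_nonincreasing`` attribute reporting whether
    the fraction declines from Q1 to Q4; it is reported, never asserted.
    """
    rows = []
    for q in QUARTILES:
        genes = set(quartiles.index[quartiles == q])
        if not genes:
            raise ValueError(f"empty quartile {q}")
        n_meth = len(genes & methylated_set)
        rows.append((q, len(genes), n_meth, n_meth / len(genes)))
    table = pd.DataFrame(rows, columns=["quartile", "n_genes", "n_methylated", "fraction"])
    fr = table["fraction"].to_numpy()
    table.attrs["monotone_nonincreasing"] = bool(np.all(np.diff(fr) <= 0))
    return table


def fc_correlation(
    expr: ExpressionMatrix,
    tissue: str,
    genotype: str = "wt",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[float, int]:
    """Pearson r between heat-induced expression log2FC and m6A-enrichment change.

    For one tissue/genotype: x = log2((HS input mean + pc)/(CS input mean + pc));
    y = enrichment(HS) - enrichment(CS). Returns (r, n).
    """
    cs = GroupKey(tissue, "CS", genotype)
    hs = GroupKey(tissue, "HS", genotype)
    inp_cs = expr.group_values(cs, "input").mean(axis=1)
    inp_hs = expr.group_values(hs, "input").mean(axis=1)
    ip_cs = expr.group_values(cs, "IP").mean(axis=1)
    ip_hs = expr.group_values(hs, "IP").mean(axis=1)
    fc = np.log2((inp_hs + pseudocount) / (inp_cs + pseudocount))
    enr_cs = np.log2((ip_cs + pseudocount) / (inp_cs + pseudocount))
    enr_hs = np.log2((ip_hs + pseudocount) / (inp_hs + pseudocount))
    delta = enr_hs - enr_cs
    ok = np.isfinite(fc) & np.isfinite(delta)
    if ok.sum() < 3:
        raise ValueError("need >= 3 genes with finite values")
    r, _p = stats.pearsonr(fc[ok], delta[ok])
    return float(r), int(ok.sum())


@dataclass(frozen=True)
class OverlapResult:
    overlap: int
    expected: float
    fold_enrichment: float
    p_value: float


def set_overlap_test(set_a: set, set_b: set, universe: set) -> OverlapResult:
    """Upper-tail hypergeometric test of the overlap between two gene sets."""
    if not set_a <= universe:
        raise ValueError("set_a not contained in universe")
    if not set_b <= universe:
        raise ValueError("set_b not contained in universe")
    n_univ, k_a, n_b = len(universe), len(set_a), len(set_b)
    obs = len(set_a & set_b)
    expected = k_a * n_b / n_univ if n_univ else 0.0
    p = float(stats.hypergeom.sf(obs - 1, n_univ, k_a, n_b))
    fold = obs / expected if expected > 0 else math.inf if obs else 0.0
    return OverlapResult(obs, expected, fold, min(1.0, p))


@dataclass(frozen=True)
class ScoreComparisonResult:
    test: RankTestResult
    random_genes: tuple[str, ...]


def score_comparison(
    gene_set: set[str],
    score_table: pd.Series,
    alternative: str = "greater",
    seed: int = 0,
    n_random: int = 1,
) -> ScoreComparisonResult:
    """Rank-test a gene set's scores against a size-matched random baseline.

    The baseline is drawn without replacement from the universe minus the
    set, seeded; with ``n_random > 1`` the draws are concatenated (multi-draw
    mode). Returns the test and the drawn gene ids for reproducibility.
    """
    universe = set(score_table.index)
    if not gene_set <= universe:
        raise ValueError("gene_set not contained in score-table universe")
    complement = sorted(universe - gene_set)
    if len(gene_set) > len(complement):
        raise ValueError("gene_set larger than half the universe; cannot size-match")
    rng = np.random.default_rng(seed)
    drawn: list[str] = []
    for _ in range(max(1, n_random)):
        drawn.extend(rng.choice(complement, size=len(gene_set), replace=False))
    test = rank_test_one_tailed(
        score_table.loc[sorted(gene_set)].to_numpy(),
        score_table.loc[drawn].to_numpy(),
        alternative,
    )
    return ScoreComparisonResult(test, tuple(drawn))


HEAT_COLUMN_ORDER = ("leaf.wt", "flower.wt", "leaf.mutant", "flower.mutant")


def heat_response_matrix(
    expr: ExpressionMatrix,
    selection_fold: float = 2.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Heat-activated genes' log2 fold changes (HS/CS) across sample groups.

    Genes are selected by wt-leaf induction of at least ``selection_fold``
    (inclusive). Columns follow (wt leaf, wt flower, mutant leaf, mutant
    flower); per-column mean FCs are stored in ``attrs['column_means']``.
    """
    cols = {}
    for label in HEAT_COLUMN_ORDER:
        tissue, genotype = label.split(".")
        try:
            cs = expr.group_values(GroupKey(tissue, "CS", genotype), "input").mean(axis=1)
            hs = expr.group_values(GroupKey(tissue, "HS", genotype), "input").mean(axis=1)
        except KeyError as exc:
            raise ValueError(f"missing group for column {label}: {exc}") from exc
        cols[label] = np.log2((hs + pseudocount) / (cs + pseudocount))
    fc = pd.DataFrame(cols, index=expr.genes)
    selected = fc[fc["leaf.wt"] >= math.log2(selection_fold)]
    if selected.empty:
        from .formats_io import logger

        logger.warning("heat_response_matrix: no gene passes the selection fold")
    selected = selected.copy()
    selected.attrs["column_means"] = selected.mean(axis=0).to_dict()
    return selected


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted q-values (helper for users running many enrichments)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
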