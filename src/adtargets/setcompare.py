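"""Risk-ranked target-set construction and set-level comparison statistics.

Builds the top-scoring slice of a genome-wide risk table (e.g., the top 1% of
24,786 scored genes — 248 targets), and compares gene sets with the standard
battery: Fisher's exact overlap test on a shared universe, two-sample
Kolmogorov–Smirnov comparisons of score distributions, and target-development
-level (TDL) proportion summaries across the Pharos tiers Tclin / Tchem /
Tbio / Tdark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "attach_ranks", "top_fraction", "OverlapResult", "overlap_fisher",
    "overlap_percent", "KSResult", "ks_compare", "ks_gene_scores",
    "tdl_proportions", "TDL_LEVELS",
]

TDL_LEVELS = ("Tclin", "Tchem", "Tbio", "Tdark")

RISK_COLUMNS = ["gene", "total", "genetics", "omics"]


def attach_ranks(risk: pd.DataFrame) -> pd.DataFrame:
    """Add ``rank`` (1 = highest total score) and ``percentile`` columns.

    Ties on the total score break by genetics score (descending) then gene
    symbol, so ranks are always a permutation of 1..n. The percentile is the
    fraction of genes at or below the gene's rank position from the bottom,
    ×100 — the top-ranked gene sits at (essentially) 100%.
    """
    if risk.empty:
        raise ValueError("risk table is empty")
    out = risk.sort_values(
        ["total", "genetics", "gene"], ascending=[False, False, True],
        kind="mergesort").reset_index(drop=True)
    n = len(out)
    out["rank"] = np.arange(1, n + 1)
    out["percentile"] = (n - out["rank"] + 1) / n * 100.0
    return out


def top_fraction(risk: pd.DataFrame, fraction: float) -> set[str]:
    """The ceil(fraction · n) highest-scoring genes of the risk table.

    Ceiling matches printed convention (0.01 × 24,786 → 248). Cutoff ties
    break deterministically by (genetics score desc, gene symbol), so
    membership is stable under row shuffling of the input.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    ranked = attach_ranks(risk)
    k = math.ceil(fraction * len(ranked))
    return set(ranked["gene"].iloc[:k])


def overlap_percent(n_overlap: int, n_total: int, ndigits: int = 1) -> float:
    """Overlap as a percentage of the first set, rounded for reporting."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_overlap / n_total, ndigits)


@dataclass(frozen=True)
class OverlapResult:
    """2×2 overlap table (both / first-only / second-only / neither).

    Two odds-ratio conventions are reported and labeled, because published
    ORs for such tables are ambiguous between them: ``odds_sample`` is the
    cross-product ratio ad/bc (Haldane–Anscombe corrected when any cell is
    zero), ``odds_cmle`` the conditional maximum-likelihood estimate from
    the noncentral hypergeometric model.
    """

    a: int
    b: int
    c: int
    d: int
    odds_sample: float
    odds_cmle: float
    p: float

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def percent_of_first(self) -> float:
        return overlap_percent(self.a, self.a + self.b)

    @property
    def percent_of_second(self) -> float:
        return overlap_percent(self.a, self.a + self.c)


def overlap_fisher(setA: Iterable[str], setB: Iterable[str],
                   universe: Iterable[str],
                   alternative: str = "greater") -> OverlapResult:
    """Fisher's exact test for the overlap of two gene sets on a universe.

    One-sided toward enrichment by default (exact hypergeometric upper
    tail); pass ``alternative="two-sided"`` for the two-sided test. The p is
    invariant to swapping the two sets; the sample OR maps to its
    reciprocal under swap of either margin.
    """
    A, B, U = set(setA), set(setB), set(universe)
    if not A <= U or not B <= U:
        raise ValueError("both sets must be subsets of the universe")
    if len(U) < len(A | B):
        raise ValueError("universe smaller than the union of the sets")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(U) - len(A | B)
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative=alternative)
    if min(a, b, c, d) == 0:
        odds_sample = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds_sample = (a * d) / (b * c)
    odds_cmle = stats.contingency.odds_ratio(table, kind="conditional").statistic
    return OverlapResult(a, b, c, d, float(odds_sample), float(odds_cmle), float(p))


@dataclass(frozen=True)
class KSResult:
    D: float
    p: float
    direction: str  # "higher" | "lower" | "none", by median shift


def ks_compare(subset_scores, background_scores) -> KSResult:
    """Two-sample, two-sided Kolmogorov–Smirnov comparison of score samples.

    ``D`` is the maximum CDF gap; ``p`` is asymptotic; ``direction`` reports
    whether the subset's median sits above or below the background's. When
    both inputs are gene-indexed Series, shared genes are rejected to
    prevent double-counting (use :func:`ks_gene_scores` to split a risk
    table cleanly).
    """
    if isinstance(subset_scores, pd.Series) and isinstance(background_scores, pd.Series):
        shared = subset_scores.index.intersection(background_scores.index)
        if len(shared):
            raise ValueError(f"samples share {len(shared)} genes; "
                             "background must exclude the subset")
    x = np.asarray(subset_scores, dtype=float)
    y = np.asarray(background_scores, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    D = float(res.statistic)
    if D == 0:
        direction = "none"
    else:
        mx, my = np.median(x), np.median(y)
        direction = "higher" if mx > my else ("lower" if mx < my else "none")
    return KSResult(D, float(res.pvalue), direction)


def ks_gene_scores(risk: pd.DataFrame, subset: Iterable[str],
                   score: str = "total",
                   exclude_subset: bool = True) -> KSResult:
    """K-S comparison of a gene set's scores against all other genes.

    The background is every scored gene outside the subset (the subset is
    excluded so no gene is double-counted).
    """
    subset = set(subset)
    known = set(risk["gene"])
    missing = subset - known
    if missing:
        raise ValueError(f"{len(missing)} subset genes absent from risk table")
    in_set = risk["gene"].isin(subset)
    bg = risk.loc[~in_set, score] if exclude_subset else risk[score]
    return ks_compare(risk.loc[in_set, score].to_numpy(), bg.to_numpy())


def tdl_proportions(genes: Iterable[str],
                    tdl: pd.DataFrame | Mapping[str, str],
                    ) -> tuple[dict[str, float], int]:
    """Proportion of a gene set in each target development level.

    Returns ``(proportions, n_unknown)``; genes missing from the TDL table
    fall into the unknown bucket and are excluded from the denominator, so
    the proportions over known levels sum to 1.
    """
    genes = set(genes)
    if not genes:
        raise ValueError("gene set is empty")
    if isinstance(tdl, pd.DataFrame):
        mapping = dict(zip(tdl["gene"], tdl["level"]))
    else:
        mapping = dict(tdl)
    levels = [mapping.get(g) for g in genes]
    known = [lv for lv in levels if lv in TDL_LEVELS]
    n_unknown = len(genes) - len(known)
    if not known:
        return {lv: float("nan") for lv in TDL_LEVELS}, n_unknown
    props = {lv: known.count(lv) / len(known) for lv in TDL_LEVELS}
    assert abs(sum(props.values()) - 1.0) < 1e-12
    return props, n_unknown
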