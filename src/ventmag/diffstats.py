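"""Pairwise differential gene abundance between two metagenomes.

Each gene symbol is tested on a 2x2 contingency table of raw mapped-read
counts (symbol reads vs. all other gene-mapped reads, per sample) with a
two-sided Fisher's exact test; the difference of proportions gets a 95%
Newcombe hybrid-Wilson confidence interval; p-values are corrected by
Benjamini-Hochberg FDR across all symbols tested in one invocation.
Tests use raw integer counts; length-normalized abundances are reported
alongside for interpretation but never fed to the test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import normalize_abundance

log = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable", "fisher_exact_two_sided", "wilson_interval",
    "newcombe_diff_interval", "bh_adjust", "compare_metagenomes",
]

#: relative tolerance on the <= comparison of hypergeometric masses
TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """a/c: gene reads in samples 1/2; b/d: non-gene reads."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("each sample must have reads")


def _margin_pvalues(n: int, row1: int, col1: int) -> tuple[int, np.ndarray]:
    """Two-sided p-values for every table sharing the given margins.

    Returns ``(kmin, p)`` where ``p[i]`` is the p-value of the table with
    ``a = kmin + i`` and ``kmin`` is the smallest feasible cell count.
    """
    kmin = max(0, row1 + col1 - n)
    kmax = min(row1, col1)
    support = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    order = np.argsort(pmf, kind="mergesort")
    cum = np.cumsum(pmf[order])
    idx = np.searchsorted(pmf[order], pmf * (1.0 + TIE_RTOL), side="right")
    pvals = np.where(idx > 0, cum[np.maximum(idx - 1, 0)], 0.0)
    return kmin, np.minimum(pvals, 1.0)


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher's exact p-value by the probability-mass rule.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's (with
    a 1e-7 relative tolerance on the comparison, guarding against float
    ties).  Degenerate margins (a+c = 0 or b+d = 0) give p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if col1 == 0 or (b + d) == 0:
        return 1.0
    kmin, pvals = _margin_pvalues(n, row1, col1)
    return float(pvals[a - kmin])


def wilson_interval(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    z = stats.norm.ppf((1.0 + conf) / 2.0)
    z2 = z * z
    center = (x + z2 / 2.0) / (n + z2)
    half = z * math.sqrt(x * (n - x) / n + z2 / 4.0) / (n + z2)
    # the score bounds hit 0 / 1 exactly at x = 0 / x = n; avoid float dust
    low = 0.0 if x == 0 else max(center - half, 0.0)
    high = 1.0 if x == n else min(center + half, 1.0)
    return low, high


def newcombe_diff_interval(x1: int, n1: int, x2: int, n2: int,
                           conf: float = 0.95) -> tuple[float, float]:
    """Newcombe hybrid interval for a difference of proportions.

    Composes the two Wilson score intervals (l1,u1), (l2,u2)::

        low  = delta - sqrt((p1-l1)^2 + (u2-p2)^2)
        high = delta + sqrt((u1-p1)^2 + (p2-l2)^2)
    """
    p1, p2 = x1 / n1, x2 / n2
    l1, u1 = wilson_interval(x1, n1, conf)
    l2, u2 = wilson_interval(x2, n2, conf)
    delta = p1 - p2
    low = delta - math.sqrt((p1 - l1) ** 2 + (u2 - p2) ** 2)
    high = delta + math.sqrt((u1 - p1) ** 2 + (p2 - l2) ** 2)
    return max(low, -1.0), min(high, 1.0)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} (p_(j) * m / j)`` on the sorted p-values,
    mapped back to input order and capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0,1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def compare_metagenomes(genes_a: pd.DataFrame, genes_b: pd.DataFrame,
                        symbols: list[str] | None = None,
                        alpha: float = 0.05, conf: float = 0.95,
                        per_gene: bool = False,
                        label_a: str = "A", label_b: str = "B") -> pd.DataFrame:
    """Differential abundance of gene symbols between two metagenomes.

    Counts are aggregated per symbol (or tested per gene id with
    ``per_gene=True``); the non-gene margin of each 2x2 table is the
    total gene-mapped reads of the sample minus the symbol's reads.
    Symbols absent from both samples are skipped with a log entry.
    Returns one row per tested unit with p, BH q, proportion difference
    and its Newcombe interval, per-million abundances, and the enrichment
    direction at ``q < alpha``.
    """
    if genes_a.empty or genes_b.empty:
        raise ValueError("both samples must be nonempty")
    key = "gene_id" if per_gene else "symbol"
    count_a = genes_a.groupby(key)["reads"].sum()
    count_b = genes_b.groupby(key)["reads"].sum()
    total_a = int(genes_a["reads"].sum())
    total_b = int(genes_b["reads"].sum())

    abun_a = normalize_abundance(genes_a).groupby(key)["abundance"].sum()
    abun_b = normalize_abundance(genes_b).groupby(key)["abundance"].sum()

    if symbols is None:
        tested = sorted(set(count_a.index) | set(count_b.index))
    else:
        tested = []
        for s in symbols:
            if count_a.get(s, 0) == 0 and count_b.get(s, 0) == 0:
                log.warning("symbol %r absent from both samples; skipped", s)
            else:
                tested.append(s)

    rows = []
    for s in tested:
        x1 = int(count_a.get(s, 0))
        x2 = int(count_b.get(s, 0))
        t = ContingencyTable(x1, total_a - x1, x2, total_b - x2)
        p = fisher_exact_two_sided(t)
        p1, p2 = x1 / total_a, x2 / total_b
        low, high = newcombe_diff_interval(x1, total_a, x2, total_b, conf)
        rows.append({key: s, "reads_a": x1, "reads_b": x2,
                     "abundance_a": float(abun_a.get(s, 0.0)),
                     "abundance_b": float(abun_b.get(s, 0.0)),
                     "p1": p1, "p2": p2, "delta": p1 - p2,
                     "ci_low": low, "ci_high": high, "p": p})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    out["enriched_in"] = np.where(out["delta"] > 0, label_a,
                                  np.where(out["delta"] < 0, label_b, ""))
    return out
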