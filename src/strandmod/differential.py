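"""Differential modification calling from pooled stranded counts.

One exact conditional binomial test serves windows, TSS regions and gene
bodies alike: conditional on the total count n = c1 + c2 of a unit, c1 is
Binomial(n, N1/(N1+N2)) under the null of equal normalized rates, and the
two-sided p-value sums all outcomes no more likely than the observed one
(minimum-likelihood method).  This is a deliberate, self-contained
replacement for negative-binomial regression machinery.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import InvalidParameterError, WindowCounts

_MINLIKE_SLACK = 1.0 + 1e-7  # tolerance for pmf ties in the two-sided sum

DIRECTION_A = "A-up"
DIRECTION_B = "B-up"
DIRECTION_NONE = "none"


def exact_binomial_test(c1: int, c2: int, N1: int, N2: int) -> float:
    """Two-sided exact test of equal rates c1/N1 vs c2/N2.

    Conditions on n = c1 + c2; under the null X ~ Binomial(n, N1/(N1+N2)).
    p = sum of P(X=k) over all k with P(X=k) <= P(X=c1) * (1 + 1e-7).
    n = 0 returns 1.0 (nothing to test).
    """
    if c1 < 0 or c2 < 0:
        raise InvalidParameterError("counts must be non-negative")
    if N1 <= 0 or N2 <= 0:
        raise InvalidParameterError("library sizes must be positive")
    n = c1 + c2
    if n == 0:
        return 1.0
    p0 = N1 / (N1 + N2)
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    p = float(pmf[pmf <= pmf[c1] * _MINLIKE_SLACK].sum())
    return min(1.0, p)


def exact_binomial_test_vec(
    c1: np.ndarray, n: np.ndarray, p0: float
) -> np.ndarray:
    """Vectorized minimum-likelihood test for many units sharing one p0.

    Groups by unique n; per n the pmf is sorted once and each observed c1
    is resolved with a searchsorted lookup into the cumulative sorted pmf.
    Entries with n == 0 get p = 1.
    """
    c1 = np.asarray(c1, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    out = np.ones(len(n), dtype=float)
    for nv in np.unique(n):
        if nv == 0:
            continue
        sel = np.flatnonzero(n == nv)
        pmf = stats.binom.pmf(np.arange(nv + 1), nv, p0)
        order = np.argsort(pmf, kind="mergesort")
        sorted_pmf = pmf[order]
        cum = np.cumsum(sorted_pmf)
        thresh = pmf[c1[sel]] * _MINLIKE_SLACK
        pos = np.searchsorted(sorted_pmf, thresh, side="right")
        out[sel] = np.minimum(1.0, cum[pos - 1])
    return out


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.isnan(p).any() or (p < 0).any() or (p > 1).any()):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


def pool_counts(
    counts: WindowCounts,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Sum counts over replicates and strands per group.

    Returns (c1, c2, N1, N2) with c arrays over units and N the summed
    library sizes.  Groups must be disjoint and non-empty.
    """
    if not group_a or not group_b:
        raise InvalidParameterError("both groups must be non-empty")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise InvalidParameterError(f"samples in both groups: {sorted(overlap)}")
    ia = [counts.sample_index(s) for s in group_a]
    ib = [counts.sample_index(s) for s in group_b]
    assays = set(counts.sample_table.set_index("sample_id").loc[list(group_a) + list(group_b), "assay"])
    if len(assays) > 1:
        raise InvalidParameterError(f"groups mix assays: {sorted(assays)}")
    c1 = counts.counts[:, ia, :].sum(axis=(1, 2))
    c2 = counts.counts[:, ib, :].sum(axis=(1, 2))
    N1 = int(counts.library_sizes(group_a).sum())
    N2 = int(counts.library_sizes(group_b).sum())
    return c1, c2, N1, N2


def _log2fc(c1: np.ndarray, c2: np.ndarray, N1: int, N2: int) -> np.ndarray:
    # 0.5 pseudocount in the fold change only, never in the test
    return np.log2(((c1 + 0.5) / N1) / ((c2 + 0.5) / N2))


def differential_table(
    unit_ids: Sequence[str],
    units: pd.DataFrame,
    c1: np.ndarray,
    c2: np.ndarray,
    N1: int,
    N2: int,
    min_total: int = 10,
    alpha: float = 0.05,
    testable: np.ndarray | None = None,
) -> pd.DataFrame:
    """Exact test + BH over testable units; one row per unit.

    ``units`` carries chrom/start/end aligned with the count arrays.
    Units with c1 + c2 < min_total (or flagged untestable, e.g. partial
    windows) are excluded from the BH family and reported untested.
    """
    if min_total < 1:
        raise InvalidParameterError("min_total must be >= 1")
    if not (0 < alpha < 1):
        raise InvalidParameterError("alpha must be in (0, 1)")
    c1 = np.asarray(c1, dtype=np.int64)
    c2 = np.asarray(c2, dtype=np.int64)
    n = c1 + c2
    tested = n >= min_total
    if testable is not None:
        tested &= np.asarray(testable, dtype=bool)
    p0 = N1 / (N1 + N2)
    pvalue = np.full(len(n), np.nan)
    pvalue[tested] = exact_binomial_test_vec(c1[tested], n[tested], p0)
    padj = np.full(len(n), np.nan)
    padj[tested] = bh_adjust(pvalue[tested])
    log2fc = _log2fc(c1, c2, N1, N2)
    significant = tested & (padj < alpha)
    direction = np.where(
        significant & (log2fc > 0),
        DIRECTION_A,
        np.where(significant & (log2fc < 0), DIRECTION_B, DIRECTION_NONE),
    )
    out = units[["chrom", "start", "end"]].reset_index(drop=True).copy()
    out.insert(0, "unit_id", list(unit_ids))
    out["c1"] = c1
    out["c2"] = c2
    out["N1"] = N1
    out["N2"] = N2
    out["log2fc"] = log2fc
    out["pvalue"] = pvalue
    out["padj"] = padj
    out["direction"] = direction
    out["tested"] = tested
    out["significant"] = significant
    return out


def differential_windows(
    counts: WindowCounts,
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_total: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Window-level differential calls; partial windows are never tested."""
    c1, c2, N1, N2 = pool_counts(counts, group_a, group_b)
    win = counts.windows
    unit_ids = [
        f"{c}:{s}-{e}" for c, s, e in zip(win["chrom"], win["start"], win["end"])
    ]
    return differential_table(
        unit_ids,
        win,
        c1,
        c2,
        N1,
        N2,
        min_total=min_total,
        alpha=alpha,
        testable=~win["partial"].to_numpy(),
    )


def differential_regions(
    region_counts_by_sample: dict[str, pd.DataFrame],
    unit_ids: Sequence[str],
    group_a: Sequence[str],
    group_b: Sequence[str],
    library_sizes: dict[str, int],
    min_total: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential calls for arbitrary regions (TSS flanks, gene bodies).

    ``region_counts_by_sample`` maps sample_id to the chrom/start/end/
    plus/minus frame returned by ``count_reads_in_regions`` — one frame per
    sample, all aligned on the same region list.
    """
    if not group_a or not group_b:
        raise InvalidParameterError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise InvalidParameterError("groups must be disjoint")
    first = region_counts_by_sample[group_a[0]]

    def pooled(group):
        tot = np.zeros(len(first), dtype=np.int64)
        for sid in group:
            df = region_counts_by_sample[sid]
            tot += df["plus"].to_numpy(np.int64) + df["minus"].to_numpy(np.int64)
        return tot

    c1 = pooled(group_a)
    c2 = pooled(group_b)
    N1 = int(sum(library_sizes[s] for s in group_a))
    N2 = int(sum(library_sizes[s] for s in group_b))
    return differential_table(
        unit_ids, first, c1, c2, N1, N2, min_total=min_total, alpha=alpha
    )
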