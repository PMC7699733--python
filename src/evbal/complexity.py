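"""Per-sample proteome complexity: unique-protein counts and their
association with clinical outcome.

A protein is "unique" to a sample when it is identified (value > 0) in
exactly that one sample across the analyzed cohort.  Only the zero-pattern
matters, so the counts are invariant to any monotone transform of the
intensities.  Group differences are tested by the Wilcoxon rank-sum test,
exactly (full enumeration of the permutation null) when group sizes allow
and there are no ties, otherwise with mid-ranks and a tie-corrected normal
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import QuantMatrix, SampleMetadata


def unique_protein_counts(m: QuantMatrix, level: str = "isoform") -> pd.Series:
    """Count, per sample, the proteins detected in exactly that sample.

    ``level="isoform"`` counts protein-isoform rows; ``level="gene"``
    collapses detection to gene level first (a gene is detected in a sample
    if any of its isoforms is).
    """
    if m.shape[0] == 0 or m.shape[1] == 0:
        raise ValueError("matrix is empty")
    if level == "isoform":
        det = m.detected()
    elif level == "gene":
        det = m.detected().groupby(m.gene_symbols.values).any()
    else:
        raise ValueError("level must be 'isoform' or 'gene'")
    once = det.sum(axis=1) == 1
    counts = det.loc[once].sum(axis=0)
    counts.name = "unique_count"
    return counts.astype(int)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------


def _ranksum_counts(n: int, N: int) -> np.ndarray:
    """counts[s] = number of n-subsets of ranks {1..N} with rank sum s."""
    max_sum = n * N
    dp = np.zeros((n + 1, max_sum + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in range(1, N + 1):
        for j in range(min(n, r), 0, -1):
            dp[j, r:] += dp[j - 1, : max_sum + 1 - r]
    return dp[n]


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    continuity: bool = True,
    exact_limit: int = 30,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where W is the rank sum of ``x`` (mid-ranks under
    ties).  ``mode="exact"`` enumerates the full permutation null over all
    C(n+m, n) rank assignments (ties not allowed); ``mode="approx"`` uses
    the tie-corrected normal approximation with optional continuity
    correction; ``mode="auto"`` picks exact when there are no ties and
    n + m ≤ ``exact_limit``.  The two-sided p doubles the smaller tail,
    capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = len(x), len(y)
    N = n + m
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks under ties
    W = float(ranks[:n].sum())
    has_ties = len(np.unique(pooled)) < N

    if mode == "auto":
        mode = "exact" if (not has_ties and N <= exact_limit) else "approx"
    if mode == "exact":
        if has_ties:
            raise ValueError("exact mode requires untied observations")
        counts = _ranksum_counts(n, N)
        total = comb(N, n)
        w = int(round(W))
        p_lower = counts[: w + 1].sum() / total
        p_upper = counts[w:].sum() / total
        p = min(1.0, 2.0 * min(p_lower, p_upper))
        return W, float(p)
    if mode != "approx":
        raise ValueError("mode must be 'exact', 'approx' or 'auto'")

    mu = n * (N + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (N * (N - 1))
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return W, 1.0
    diff = W - mu
    if continuity and diff != 0:
        diff -= 0.5 * np.sign(diff)
    z = diff / np.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return W, float(p)


# ---------------------------------------------------------------------------
# Outcome association
# ---------------------------------------------------------------------------


@dataclass
class ComplexityResult:
    """Unique-count association between an outcome partition and the rest."""

    per_sample: pd.DataFrame  # unique_count, in_group
    statistic: float
    p_value: float
    direction: str  # which side has the larger median count
    contrast: str
    level: str
    mode_used: str


def complexity_association(
    counts: pd.Series,
    meta: SampleMetadata,
    contrast: str = "stage4_or_dead",
    mode: str = "auto",
    level: str = "isoform",
) -> ComplexityResult:
    """Test whether unique-protein counts differ across an outcome partition.

    ``contrast`` follows :meth:`SampleMetadata.poor_outcome_mask`
    (default: stage-IV disease or death during follow-up vs all other
    samples).  No outliers are removed.
    """
    meta_t = meta.table.loc[counts.index]
    mask = SampleMetadata(meta_t).poor_outcome_mask(contrast).to_numpy()
    if mask.all() or not mask.any():
        raise ValueError(f"contrast {contrast!r} leaves one side of the partition empty")
    x = counts.values[mask].astype(float)
    y = counts.values[~mask].astype(float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    mode_used = mode
    if mode == "auto":
        mode_used = "exact" if (not has_ties and len(pooled) <= 30) else "approx"
    W, p = wilcoxon_rank_sum(x, y, mode=mode_used)
    direction = (
        f"{contrast} higher"
        if np.median(x) > np.median(y)
        else (f"{contrast} lower" if np.median(x) < np.median(y) else "no difference")
    )
    per_sample = pd.DataFrame(
        {"unique_count": counts.values, "in_group": mask}, index=counts.index
    )
    return ComplexityResult(per_sample, W, p, direction, contrast, level, mode_used)
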