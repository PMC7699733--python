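"""iBAQ preprocessing: the three strategies used for quantitative analysis.

1. ``log_only``: contaminant removal, then log2(x + 1).
2. ``log_quantile``: additionally quantile normalization.
3. ``log_quantile_gaussfilter``: additionally abundance filtering chosen to
   optimize the overall Gaussian shape of the pooled quantitative values.

Zeros encode "not identified" and are excluded from normality scoring;
quantile normalization operates on the full dense matrix (all cells ranked,
zeros included), with ties receiving the mean of the quantile reference
over their tied ranks — the convention of the dominant microarray
implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import QuantMatrix

logger = logging.getLogger("evbal")

STRATEGIES = ("log_only", "log_quantile", "log_quantile_gaussfilter")


@dataclass
class PreprocessConfig:
    strategy: str = "log_quantile"
    contaminant_list: frozenset = frozenset()
    gauss_grid: tuple[float, ...] | None = None
    normality_metric: str = "anderson_darling"  # or "shapiro"
    subsample: int = 5000
    subsample_seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.normality_metric not in ("anderson_darling", "shapiro"):
            raise ValueError("normality_metric must be 'anderson_darling' or 'shapiro'")
        if self.gauss_grid is not None:
            grid = tuple(self.gauss_grid)
            if any(b <= a for a, b in zip(grid, grid[1:])):
                raise ValueError("gauss_grid must be strictly ascending")
            self.gauss_grid = grid


def remove_contaminants(m: QuantMatrix, contaminants: Iterable[str] = ()) -> QuantMatrix:
    """Drop rows flagged at read time or listed as contaminants.

    Matching is on protein id or gene symbol.  An empty list with no
    flagged rows is the identity.
    """
    bad = set(contaminants)
    drop = m.flagged.to_numpy().copy()
    if bad:
        drop |= np.array([pid in bad for pid in m.protein_ids])
        drop |= np.array([sym in bad for sym in m.gene_symbols])
    n_drop = int(drop.sum())
    if n_drop:
        logger.info("remove_contaminants: dropped %d of %d rows", n_drop, len(drop))
    keep = ~drop
    return QuantMatrix(
        m.data.loc[keep], m.gene_symbols.loc[keep], m.flagged.loc[keep]
    )


def log_transform(m: QuantMatrix) -> QuantMatrix:
    """log2(x + 1) on every cell; zeros stay zeros, negative input errors."""
    vals = m.values
    if (vals < 0).any():
        raise ValueError("log_transform requires non-negative intensities")
    return QuantMatrix(
        pd.DataFrame(np.log2(vals + 1.0), index=m.data.index, columns=m.data.columns),
        m.gene_symbols.copy(),
        m.flagged.copy(),
    )


def quantile_normalize(m: QuantMatrix) -> QuantMatrix:
    """Force every sample column onto the common quantile reference.

    The reference is the across-sample mean of the column-sorted values;
    each column's values are replaced by the reference value at their rank,
    tied values receiving the mean of the reference over their tied ranks.
    After the operation all columns share the same sorted value multiset
    (exactly so in the absence of ties).
    """
    if m.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    vals = m.values
    n_rows, n_cols = vals.shape
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals, dtype=float)
    for j in range(n_cols):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        assigned = ref.copy()
        # average the reference over runs of tied values
        start = 0
        for i in range(1, n_rows + 1):
            if i == n_rows or sorted_col[i] != sorted_col[start]:
                if i - start > 1:
                    assigned[start:i] = ref[start:i].mean()
                start = i
        out[order, j] = assigned
    return QuantMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
        m.gene_symbols.copy(),
        m.flagged.copy(),
    )


def normality_score(
    values: np.ndarray,
    metric: str = "anderson_darling",
    subsample: int = 5000,
    seed: int = 0,
) -> float:
    """Score how Gaussian a pooled sample looks (higher = more Gaussian).

    ``anderson_darling`` returns the negated A-D statistic; ``shapiro``
    returns the W statistic.  Samples larger than ``subsample`` are
    subsampled with a fixed seed for speed.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 8:
        raise ValueError("need at least 8 values for a normality score")
    if len(v) > subsample:
        rng = np.random.default_rng(seed)
        v = rng.choice(v, size=subsample, replace=False)
    if np.ptp(v) == 0:
        raise ValueError("constant values have no normality score")
    if metric == "anderson_darling":
        # A-D statistic against the normal with estimated mean/sd
        z = np.sort((v - v.mean()) / v.std(ddof=1))
        n = len(z)
        cdf = stats.norm.cdf(z)
        eps = np.finfo(float).tiny
        cdf = np.clip(cdf, eps, 1 - eps)
        i = np.arange(1, n + 1)
        a2 = -n - np.mean((2 * i - 1) * (np.log(cdf) + np.log1p(-cdf[::-1])))
        return -float(a2)
    if metric == "shapiro":
        return float(stats.shapiro(v).statistic)
    raise ValueError(f"unknown normality metric {metric!r}")


def gaussian_abundance_filter(
    m: QuantMatrix,
    grid: Sequence[float] | None = None,
    metric: str = "anderson_darling",
    subsample: int = 5000,
    seed: int = 0,
) -> tuple[QuantMatrix, float, pd.DataFrame]:
    """Abundance filtering that optimizes the Gaussian shape of the data.

    Expects a log-transformed matrix.  Every candidate minimum-abundance
    threshold in ``grid`` is evaluated by zeroing values at or below it and
    scoring the pooled retained nonzero values for normality; the threshold
    with the maximal score wins.  Returns the filtered matrix, the chosen
    threshold and the full score trace.

    With no explicit grid, candidates run from just below the smallest
    nonzero value (no filtering) to the 40% quantile of nonzero values in
    20 steps.
    """
    vals = m.values
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        raise ValueError("matrix has no nonzero values to filter")
    if grid is None:
        lo = float(nonzero.min()) - 1e-9
        hi = float(np.quantile(nonzero, 0.4))
        grid = list(np.linspace(lo, hi, 20))
    grid = list(grid)
    if not grid:
        raise ValueError("gauss_grid is empty")

    scores = []
    for thr in grid:
        retained = nonzero[nonzero > thr]
        if retained.size < 8:
            scores.append(-np.inf)
            continue
        scores.append(normality_score(retained, metric, subsample, seed))
    trace = pd.DataFrame({"threshold": grid, "score": scores})
    best = int(np.argmax(scores))
    chosen = float(grid[best])
    logger.info(
        "gaussian_abundance_filter: threshold %.4g (score %.4g)", chosen, scores[best]
    )
    filtered = np.where(vals > chosen, vals, 0.0)
    out = QuantMatrix(
        pd.DataFrame(filtered, index=m.data.index, columns=m.data.columns),
        m.gene_symbols.copy(),
        m.flagged.copy(),
    )
    return out, chosen, trace


def preprocess(
    m: QuantMatrix, config: PreprocessConfig | None = None
) -> tuple[QuantMatrix, dict]:
    """Apply one of the three preprocessing strategies end to end."""
    cfg = config or PreprocessConfig()
    info: dict = {"strategy": cfg.strategy}
    out = remove_contaminants(m, cfg.contaminant_list)
    out = log_transform(out)
    if cfg.strategy in ("log_quantile", "log_quantile_gaussfilter"):
        out = quantile_normalize(out)
    if cfg.strategy == "log_quantile_gaussfilter":
        out, chosen, trace = gaussian_abundance_filter(
            out, cfg.gauss_grid, cfg.normality_metric, cfg.subsample, cfg.subsample_seed
        )
        info["abundance_threshold"] = chosen
        info["score_trace"] = trace
    return out, info
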