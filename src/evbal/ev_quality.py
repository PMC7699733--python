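"""EV preparation quality: MS-based marker scaling, particle/protein purity
classification, and NTA size-distribution comparison.

The marker heatmap scales each marker's group-averaged iBAQ to [0, 1]
across columns (samples, groups or reference preparations), so relative
exosome-marker content can be compared between preparations without
absolute calibration; organelle markers (mitochondrial BCL2, Golgi GOLGA2,
nuclear NUP98, ER CANX) serve as contamination readouts.  Particle-to-
protein ratios are classified against literature purity thresholds
(> 3×10^10 particles/µg high purity; 2×10^9–2×10^10 low).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MarkerPanel, QuantMatrix, SizeDistribution
from .diffexpr import adjust_bh


# ---------------------------------------------------------------------------
# Marker scaling and purity scores
# ---------------------------------------------------------------------------


def scale_marker_matrix(
    marker_values: pd.DataFrame, method: str = "minmax"
) -> pd.DataFrame:
    """Scale each marker row to [0, 1] across columns.

    ``method="minmax"``: (v − min) / (max − min); constant rows map to 0.5.
    ``method="rank"``: (rank − 1) / (n − 1) with mid-ranks for ties.
    Input rows are markers, columns are samples/groups/references.
    """
    if marker_values.shape[1] < 2:
        raise ValueError("need at least 2 columns to scale across")
    if marker_values.shape[0] == 0:
        raise ValueError("no marker rows to scale")
    vals = marker_values.to_numpy(dtype=float)
    if method == "minmax":
        lo = vals.min(axis=1, keepdims=True)
        hi = vals.max(axis=1, keepdims=True)
        span = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = (vals - lo) / span
        scaled[np.repeat(span == 0, vals.shape[1], axis=1)] = 0.5
    elif method == "rank":
        n = vals.shape[1]
        scaled = (np.vstack([stats.rankdata(r) for r in vals]) - 1.0) / (n - 1.0)
    else:
        raise ValueError("method must be 'minmax' or 'rank'")
    return pd.DataFrame(scaled, index=marker_values.index, columns=marker_values.columns)


def marker_matrix(m: QuantMatrix, panel: MarkerPanel) -> pd.DataFrame:
    """Extract panel marker rows (EV + non-EV) by gene symbol.

    Matching is case-insensitive on gene symbols; isoforms collapse by
    maximum.  Errors if none of the panel markers are present, listing the
    missing ones.
    """
    wanted = panel.ev_markers + panel.non_ev_markers
    sym_upper = m.gene_symbols.astype(str).str.upper()
    rows = {}
    for marker in wanted:
        hit = sym_upper == marker.upper()
        if hit.any():
            rows[marker] = m.data.loc[hit.values].max(axis=0)
    missing = [w for w in wanted if w not in rows]
    if not rows:
        raise KeyError(f"no panel markers found in matrix; missing: {missing}")
    return pd.DataFrame(rows).T


@dataclass
class PurityReport:
    """Per-column EV purity summary from scaled marker values."""

    scaled: pd.DataFrame  # markers × columns, in [0, 1]
    ev_score: pd.Series
    contamination_score: pd.Series


def purity_scores(scaled: pd.DataFrame, panel: MarkerPanel) -> PurityReport:
    """Average scaled values over EV and non-EV markers per column.

    A flag class with no marker present in ``scaled`` yields an
    all-NaN (undefined) score series.
    """
    ev = [m for m in panel.ev_markers if m in scaled.index]
    non_ev = [m for m in panel.non_ev_markers if m in scaled.index]
    unflagged = [
        m
        for m in scaled.index
        if panel.compartment.get(m) not in ("EV", "non-EV")
    ]
    if unflagged:
        raise KeyError(f"markers without EV/non-EV flags: {unflagged}")
    nan = pd.Series(np.nan, index=scaled.columns)
    ev_score = scaled.loc[ev].mean(axis=0) if ev else nan.copy()
    cont_score = scaled.loc[non_ev].mean(axis=0) if non_ev else nan.copy()
    ev_score.name = "ev_score"
    cont_score.name = "contamination_score"
    return PurityReport(scaled, ev_score, cont_score)


# ---------------------------------------------------------------------------
# Particle / protein purity thresholds
# ---------------------------------------------------------------------------

HIGH_PURITY_RATIO = 3e10  # particles per microgram protein
LOW_PURITY_RANGE = (2e9, 2e10)


def classify_particle_protein_ratio(particles: float, protein_ug: float) -> str:
    """Classify an EV prep by its particles-per-µg-protein ratio.

    ``high``: ratio > 3×10^10; ``low``: 2×10^9 ≤ ratio ≤ 2×10^10;
    ``indeterminate``: the gap between the published bands
    (2×10^10, 3×10^10]; ``below-low``: ratio < 2×10^9.
    """
    if protein_ug <= 0:
        raise ValueError("protein amount must be positive")
    if particles < 0:
        raise ValueError("particle count must be non-negative")
    r = particles / protein_ug
    if r > HIGH_PURITY_RATIO:
        return "high"
    if LOW_PURITY_RANGE[0] <= r <= LOW_PURITY_RANGE[1]:
        return "low"
    if r < LOW_PURITY_RANGE[0]:
        return "below-low"
    return "indeterminate"


# ---------------------------------------------------------------------------
# NTA size-distribution comparison
# ---------------------------------------------------------------------------


@dataclass
class NTAComparison:
    """Per-bin two-group comparison of normalized NTA size distributions."""

    per_bin: pd.DataFrame  # bin_left_nm, mean_a, mean_b, t, p_value, adj_p_value
    per_sample: pd.DataFrame  # modal_size_nm, total_particles, group
    normalized: pd.DataFrame  # bins × samples, columns sum to 1


def nta_normalize_and_test(
    dists: list[SizeDistribution], groups: dict[str, str]
) -> NTAComparison:
    """Normalize each sample's counts to sum 1 and Welch-t-test every bin.

    ``groups`` maps sample id → group label (exactly two labels, each with
    ≥ 2 samples).  Distributions on different grids are compared on the
    intersection of their bins.  BH adjustment is applied across bins; raw
    p values are reported alongside.
    """
    if not dists:
        raise ValueError("no size distributions given")
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    for lab in labels:
        if sum(1 for d in dists if groups.get(d.sample_id) == lab) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")

    common = None
    for d in dists:
        edges = set(np.round(d.bin_left_edges, 6))
        common = edges if common is None else (common & edges)
    if not common:
        raise ValueError("size distributions share no bins")
    grid = np.array(sorted(common))

    norm_cols = {}
    per_sample_rows = []
    for d in dists:
        idx = np.searchsorted(np.round(d.bin_left_edges, 6), grid)
        frac = d.normalized()[idx]
        norm_cols[d.sample_id] = frac
        per_sample_rows.append(
            {
                "sample_id": d.sample_id,
                "modal_size_nm": d.modal_size(),
                "total_particles": d.total(),
                "group": groups.get(d.sample_id, ""),
            }
        )
    normalized = pd.DataFrame(norm_cols, index=grid)
    # renormalize on the common grid so columns sum to 1 exactly
    normalized = normalized / normalized.sum(axis=0)

    a_cols = [d.sample_id for d in dists if groups.get(d.sample_id) == labels[0]]
    b_cols = [d.sample_id for d in dists if groups.get(d.sample_id) == labels[1]]
    A = normalized[a_cols].to_numpy()
    B = normalized[b_cols].to_numpy()
    tvals = np.zeros(len(grid))
    pvals = np.ones(len(grid))
    for i in range(len(grid)):
        a, b = A[i], B[i]
        if np.var(a) == 0 and np.var(b) == 0:
            if a.mean() == b.mean():
                tvals[i], pvals[i] = 0.0, 1.0
            else:
                tvals[i] = np.inf if a.mean() > b.mean() else -np.inf
                pvals[i] = 0.0
        else:
            with warnings.catch_warnings():
                # groups can be near-identical in low-mass bins; the t of
                # ~0/0 is caught by the zero-variance branch above, and
                # precision-loss warnings here are expected under the null
                warnings.simplefilter("ignore", RuntimeWarning)
                t, p = stats.ttest_ind(a, b, equal_var=False)
            tvals[i], pvals[i] = float(t), float(p)
    per_bin = pd.DataFrame(
        {
            "bin_left_nm": grid,
            f"mean_{labels[0]}": A.mean(axis=1),
            f"mean_{labels[1]}": B.mean(axis=1),
            "t": tvals,
            "p_value": pvals,
            "adj_p_value": adjust_bh(pvals),
        }
    )
    per_sample = pd.DataFrame(per_sample_rows).set_index("sample_id")
    return NTAComparison(per_bin, per_sample, normalized)
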