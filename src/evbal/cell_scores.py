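"""Marker-based abundance scores for immune and stromal cell populations.

Each population's score in a sample is the arithmetic mean of the log2
abundances of that population's marker genes that are present in the
matrix — an abundance score, not a proportion.  Markers that are not
detected (zero) in a sample are excluded from the mean rather than imputed,
because zeros encode non-identification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .containers import MarkerPanel, QuantMatrix, SampleMetadata


@dataclass
class PopulationScores:
    """Population × sample score matrix plus detected-marker bookkeeping."""

    scores: pd.DataFrame  # populations × samples; NaN = undefined
    n_markers_detected: pd.Series  # per population, markers present in matrix

    @property
    def populations(self) -> list[str]:
        return list(self.scores.index)


def population_scores(m: QuantMatrix, panels: MarkerPanel) -> PopulationScores:
    """Mean log2 marker abundance per population and sample.

    ``m`` must be on the log2 scale.  Gene-symbol matching is
    case-insensitive and exact; isoforms collapse by maximum.  Populations
    with no detected marker get an all-NaN row and
    ``n_markers_detected = 0``.
    """
    pop_panels = panels.population_panels()
    if not pop_panels:
        raise ValueError("marker panel has no cell-population panels")
    sym_upper = m.gene_symbols.astype(str).str.upper()
    score_rows = {}
    n_detected = {}
    for pop, markers in pop_panels.items():
        marker_rows = []
        found = 0
        for marker in markers:
            hit = sym_upper == marker.upper()
            if hit.any():
                row = m.data.loc[hit.values].max(axis=0)
                if (row > 0).any():
                    found += 1
                    marker_rows.append(row.where(row > 0))
        n_detected[pop] = found
        if marker_rows:
            score_rows[pop] = pd.concat(marker_rows, axis=1).mean(axis=1)
        else:
            score_rows[pop] = pd.Series(np.nan, index=m.data.columns)
    scores = pd.DataFrame(score_rows).T
    scores = scores.loc[list(pop_panels)]
    return PopulationScores(scores, pd.Series(n_detected).loc[list(pop_panels)])


def score_group_summary(
    scores: PopulationScores,
    meta: SampleMetadata,
    grouping: str = "cancer_status",
) -> tuple[pd.DataFrame, list[str]]:
    """Group means per population + hierarchically clustered sample order.

    Clustering: average linkage on Euclidean distances between sample
    score vectors (populations with undefined scores dropped from the
    distance computation).  Returns (group-mean table, leaf-ordered sample
    ids).
    """
    s = scores.scores
    defined = s.dropna(axis=0, how="any")
    if defined.empty:
        raise ValueError("no population has scores defined for every sample")
    groups = meta.table.loc[s.columns, grouping]
    group_means = s.T.groupby(groups.values).mean().T

    samples = list(s.columns)
    if len(samples) < 3:
        return group_means, samples
    dist = pdist(defined.T.to_numpy(), metric="euclidean")
    order = leaves_list(average(dist))
    return group_means, [samples[i] for i in order]
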