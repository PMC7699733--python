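"""Complete functional regulation analysis (CFRA).

CFRA couples two tests per annotation category: a hypergeometric
enrichment test of the category within a query protein list, and a test of
whether the category's member log2 ratios are jointly shifted away from
zero.  A category is called regulated only when all three retention
filters hold simultaneously: enrichment p < alpha, |fold change| > the
two-fold threshold, and regulation p < alpha; its direction is the sign of
the mean log2 ratio.  Star annotations mark p-value strata
(* < 0.05, ** < 0.01, *** < 0.001).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection, QuantMatrix, SampleMetadata
from .diffexpr import DEResult, adjust_bh

logger = logging.getLogger("evbal")


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    """Per-category hypergeometric upper-tail enrichment."""

    table: pd.DataFrame  # category, N, K, n, k, p_value, adj_p_value


def hypergeom_enrichment(
    query: Iterable[str],
    universe: Iterable[str],
    sets: GeneSetCollection,
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of each category in a query list.

    With universe size N, category size K (after intersection with the
    universe), query size n and overlap k, the enrichment p value is
    P(X ≥ k) for X ~ Hypergeometric(N, K, n).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe is empty")
    q = set(query) & uni
    if set(query) - uni:
        extra = sorted(set(query) - uni)[:5]
        raise ValueError(f"query contains symbols outside the universe, e.g. {extra}")
    N, n = len(uni), len(q)
    rows = []
    for gs in sets:
        members = set(gs.members) & uni
        K = len(members)
        if K == 0:
            continue
        k = len(members & q)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"category": gs.name, "N": N, "K": K, "n": n, "k": k, "p_value": min(p, 1.0)}
        )
    table = pd.DataFrame(rows, columns=["category", "N", "K", "n", "k", "p_value"])
    if len(table):
        table["adj_p_value"] = adjust_bh(table["p_value"].values)
    else:
        table["adj_p_value"] = []
    return EnrichmentResult(table.set_index("category"))


# ---------------------------------------------------------------------------
# Per-protein log2 ratios
# ---------------------------------------------------------------------------


def ratios_from_groups(
    m: QuantMatrix,
    meta: SampleMetadata,
    contrast_column: str = "cancer_status",
    case_level: str = "YES",
    collapse: str | None = "max",
) -> pd.Series:
    """Difference of group means of log-scale values per protein (case − control).

    ``m`` must be on the log2 scale.  With ``collapse`` set, isoforms are
    collapsed to gene level first so ratios index gene symbols.
    """
    if collapse is not None:
        m = m.collapse_genes(how=collapse)
    meta = meta.aligned_to(m)
    mask = (meta.table[contrast_column] == case_level).to_numpy()
    if mask.all() or not mask.any():
        raise ValueError("contrast needs samples on both sides")
    vals = m.values
    ratios = vals[:, mask].mean(axis=1) - vals[:, ~mask].mean(axis=1)
    return pd.Series(ratios, index=m.data.index, name="log2_ratio")


def ratios_from_de(de: DEResult, collapse: str = "max") -> pd.Series:
    """Covariate-corrected per-gene log2 ratios from a DE fit.

    Isoform coefficients collapse per gene by the coefficient of largest
    magnitude (``collapse="max"``) or the mean (``collapse="mean"``).
    """
    t = de.table
    g = t.groupby(t["gene_symbol"].values)["log2fc"]
    if collapse == "max":
        out = g.agg(lambda v: v.iloc[int(np.argmax(np.abs(v.values)))])
    elif collapse == "mean":
        out = g.mean()
    else:
        raise ValueError("collapse must be 'max' or 'mean'")
    out.name = "log2_ratio"
    return out


# ---------------------------------------------------------------------------
# Category regulation
# ---------------------------------------------------------------------------


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CategoryRegulation:
    """Joint enrichment + regulation call for one category."""

    category: str
    n_identified: int
    n_annotated: int
    mean_log2_ratio: float
    fold_change: float
    p_regulation: float
    p_enrichment: float
    direction: str  # up | down | unregulated
    stars_regulation: str
    stars_enrichment: str


def category_regulation(
    ratios: pd.Series,
    sets: GeneSetCollection,
    query_list: Iterable[str],
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
    regulation_test: str = "t",
) -> list[CategoryRegulation]:
    """Classify every category as up, down or unregulated.

    ``ratios``: per-protein (or per-gene) log2 case/control ratios over the
    quantified universe (its index defines the enrichment universe).
    ``query_list``: the protein list tested for category enrichment —
    typically the significantly regulated proteins (raw p < alpha) of the
    comparison; an identification-based query (proteins detected in the
    comparison) may be passed instead when identification itself is
    informative.  Per category, the regulation p value is a two-sided
    one-sample test of the identified members' log2 ratios against 0
    (Student t by default, Wilcoxon signed-rank with
    ``regulation_test="wilcoxon"``); the fold change is 2^(mean log2
    ratio); the enrichment p value is the hypergeometric upper tail of the
    category within the query list.  A category is directional only if
    enrichment p < alpha AND |FC| > fc_threshold AND regulation p < alpha;
    otherwise it is unregulated.  Categories with fewer than two
    identified members are excluded with a log entry.
    """
    universe = list(ratios.index)
    qset = [g for g in query_list if g in set(universe)]
    enr = hypergeom_enrichment(qset, universe, sets).table

    results: list[CategoryRegulation] = []
    uni = set(universe)
    for gs in sets:
        members = sorted(set(gs.members) & uni)
        n_annot = len(set(gs.members))
        if len(members) < 2:
            logger.info(
                "category_regulation: %s has %d identified member(s); excluded",
                gs.name,
                len(members),
            )
            continue
        vals = ratios.loc[members].to_numpy(dtype=float)
        mean_ratio = float(vals.mean())
        fc = float(2.0**mean_ratio)
        if np.ptp(vals) == 0:
            # degenerate constant ratios: no shift -> p 1, constant shift -> p 0
            p_reg = 1.0 if vals[0] == 0 else 0.0
        elif regulation_test == "t":
            p_reg = float(stats.ttest_1samp(vals, 0.0).pvalue)
        elif regulation_test == "wilcoxon":
            nz = vals[vals != 0]
            p_reg = float(stats.wilcoxon(nz).pvalue) if len(nz) else 1.0
        else:
            raise ValueError("regulation_test must be 't' or 'wilcoxon'")

        p_enr = float(enr.loc[gs.name, "p_value"]) if gs.name in enr.index else 1.0

        if p_enr < alpha and p_reg < alpha and (fc > fc_threshold or fc < 1.0 / fc_threshold):
            direction = "up" if mean_ratio > 0 else "down"
        else:
            direction = "unregulated"
        results.append(
            CategoryRegulation(
                category=gs.name,
                n_identified=len(members),
                n_annotated=n_annot,
                mean_log2_ratio=mean_ratio,
                fold_change=fc,
                p_regulation=p_reg,
                p_enrichment=p_enr,
                direction=direction,
                stars_regulation=_stars(p_reg),
                stars_enrichment=_stars(p_enr),
            )
        )
    return results


def cfra_matrix(
    results_per_comparison: Mapping[str, Sequence[CategoryRegulation]],
) -> pd.DataFrame:
    """Long-format cross-comparison table for the CFRA heatmap.

    Categories are retained if they are directional (up/down) in at least
    one comparison; a category absent from a comparison is rendered
    unregulated (``n_identified`` 0).  Columns: category, comparison,
    direction, n_identified, n_annotated, log2fc, p_reg, p_enr, stars_reg,
    stars_enr.
    """
    if not results_per_comparison:
        raise ValueError("need at least one comparison")
    keep: set[str] = set()
    for res in results_per_comparison.values():
        keep.update(r.category for r in res if r.direction != "unregulated")
    rows = []
    annotated: dict[str, int] = {}
    for res in results_per_comparison.values():
        for r in res:
            annotated.setdefault(r.category, r.n_annotated)
    for cat in sorted(keep):
        for comp, res in results_per_comparison.items():
            hit = next((r for r in res if r.category == cat), None)
            if hit is None:
                rows.append(
                    {
                        "category": cat,
                        "comparison": comp,
                        "direction": "unregulated",
                        "n_identified": 0,
                        "n_annotated": annotated.get(cat, 0),
                        "log2fc": np.nan,
                        "p_reg": np.nan,
                        "p_enr": np.nan,
                        "stars_reg": "",
                        "stars_enr": "",
                    }
                )
            else:
                rows.append(
                    {
                        "category": cat,
                        "comparison": comp,
                        "direction": hit.direction,
                        "n_identified": hit.n_identified,
                        "n_annotated": hit.n_annotated,
                        "log2fc": hit.mean_log2_ratio,
                        "p_reg": hit.p_regulation,
                        "p_enr": hit.p_enrichment,
                        "stars_reg": hit.stars_regulation,
                        "stars_enr": hit.stars_enrichment,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "category",
            "comparison",
            "direction",
            "n_identified",
            "n_annotated",
            "log2fc",
            "p_reg",
            "p_enr",
            "stars_reg",
            "stars_enr",
        ],
    )
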