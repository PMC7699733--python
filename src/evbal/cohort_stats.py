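"""Baseline-characteristics table with association tests.

Counts and one-decimal percentages per clinical variable, split by a
grouping variable (typically cancer status), with a per-variable
association test: Pearson chi-square without continuity correction, or
Fisher's exact test (2×2 via the standard two-sided rule; r×c by full
enumeration of tables with fixed margins).  ``auto`` selects Fisher when
any expected cell count is below 5.  Not-available levels are shown as
display rows but excluded from the tests by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .containers import SampleMetadata

NA_LEVELS = {"NA", "unknown"}

_LEVEL_ORDER = {
    "age_group": ["<55", ">55", "NA"],
    "smoking": ["current", "former", "non", "unknown"],
    "gender": ["NA", "F", "M"],
    "stage": ["2", "3", "4", "NA", "no"],
    "vital_status": ["alive", "dead"],
}


# ---------------------------------------------------------------------------
# Association tests
# ---------------------------------------------------------------------------


def _fisher_rxc(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for an r×c table by full enumeration.

    p = sum of probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's.  Intended for small
    tables (the per-variable contingency tables of a cohort of tens).
    """
    table = np.asarray(table, dtype=int)
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    n = table.sum()
    log_const = gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum() - gammaln(n + 1)

    def log_prob(t: np.ndarray) -> float:
        return float(log_const - gammaln(t + 1).sum())

    obs_lp = log_prob(table)
    r, c = table.shape
    total = 0.0

    def recurse(i: int, j: int, current: np.ndarray, row_rem: np.ndarray, col_rem: np.ndarray):
        nonlocal total
        if i == r - 1:
            # last row is determined by the column remainders
            if (col_rem >= 0).all():
                t = current.copy()
                t[r - 1, :] = col_rem
                lp = log_prob(t)
                if lp <= obs_lp + 1e-7:
                    total += np.exp(lp)
            return
        if j == c - 1:
            v = row_rem[i]
            if 0 <= v <= col_rem[j]:
                current[i, j] = v
                col_rem[j] -= v
                recurse(i + 1, 0, current, row_rem, col_rem)
                col_rem[j] += v
                current[i, j] = 0
            return
        hi = min(row_rem[i], col_rem[j])
        for v in range(hi + 1):
            current[i, j] = v
            row_rem[i] -= v
            col_rem[j] -= v
            recurse(i, j + 1, current, row_rem, col_rem)
            row_rem[i] += v
            col_rem[j] += v
            current[i, j] = 0

    recurse(0, 0, np.zeros_like(table), row_sums.copy(), col_sums.copy())
    return min(1.0, total)


def association_test(
    table: Sequence[Sequence[float]] | np.ndarray, method: str = "auto"
) -> tuple[float, float, str]:
    """Association between the rows and columns of a contingency table.

    Returns ``(statistic, p, test_used)``.  ``chi2`` is the Pearson
    chi-square without continuity correction; ``fisher`` the exact test
    (the conventional two-sided rule: sum of table probabilities ≤ the
    observed one).  ``auto`` picks Fisher when any expected count is < 5.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError("degenerate margin: a row or column sums to zero")

    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if method == "auto":
        method = "fisher" if (expected < 5).any() else "chi2"
    if method == "chi2":
        res = stats.chi2_contingency(t, correction=False)
        return float(res.statistic), float(res.pvalue), "chi2"
    if method == "fisher":
        ti = np.round(t).astype(int)
        if not np.allclose(t, ti):
            raise ValueError("Fisher's exact test requires integer counts")
        if ti.shape == (2, 2):
            odds, p = stats.fisher_exact(ti, alternative="two-sided")
            return float(odds), float(p), "fisher"
        return float("nan"), _fisher_rxc(ti), "fisher"
    raise ValueError("method must be 'auto', 'chi2' or 'fisher'")


# ---------------------------------------------------------------------------
# Baseline table
# ---------------------------------------------------------------------------


@dataclass
class BaselineTable:
    """Counts/percentages per level and group, plus per-variable tests."""

    rows: pd.DataFrame  # variable, level, count_/pct_ per group and total
    tests: pd.DataFrame  # per variable: statistic, p_value, test_used
    group_sizes: dict[str, int]

    def formatted(self) -> pd.DataFrame:
        """Publication-style strings: "5 (41.7%)" per cell."""
        out = self.rows[["variable", "level"]].copy()
        for g in [*self.group_sizes, "total"]:
            out[g] = [
                f"{int(c)} ({p:.1f}%)"
                for c, p in zip(self.rows[f"count_{g}"], self.rows[f"pct_{g}"])
            ]
        out["p_value"] = [
            (
                f"{self.tests.loc[v, 'p_value']:.3f}"
                if self.rows["level"].iloc[i] == self.rows[self.rows['variable'] == v]["level"].iloc[0]
                else ""
            )
            for i, v in enumerate(self.rows["variable"])
        ]
        return out


def baseline_table(
    meta: SampleMetadata,
    group_var: str = "cancer_status",
    variables: Sequence[str] = (
        "age_group",
        "smoking",
        "gender",
        "batch",
        "stage",
        "vital_status",
    ),
    na_policy: str = "exclude",
    test_method: str = "auto",
) -> BaselineTable:
    """Build the baseline-characteristics table for a cohort.

    Percentages are relative to the group size (one decimal).  Levels in
    ``NA_LEVELS`` ("NA", "unknown") appear as display rows; with
    ``na_policy="exclude"`` (default) they are dropped from the
    association test, with ``"include"`` they are kept.
    """
    t = meta.table
    if group_var not in t.columns:
        raise KeyError(f"grouping variable {group_var!r} absent from metadata")
    groups = sorted(t[group_var].astype(str).unique())
    if len(groups) < 2:
        raise ValueError(f"grouping variable {group_var!r} has fewer than 2 levels")
    if na_policy not in ("exclude", "include"):
        raise ValueError("na_policy must be 'exclude' or 'include'")
    sizes = {g: int((t[group_var].astype(str) == g).sum()) for g in groups}

    rows = []
    test_rows = []
    for var in variables:
        if var not in t.columns:
            raise KeyError(f"variable {var!r} absent from metadata")
        col = t[var].astype(str)
        observed = list(dict.fromkeys(col))
        order = _LEVEL_ORDER.get(var)
        levels = [l for l in order if l in observed] if order else sorted(observed)
        levels += [l for l in observed if l not in levels]
        for level in levels:
            row = {"variable": var, "level": level}
            total_count = 0
            for g in groups:
                c = int(((col == level) & (t[group_var].astype(str) == g)).sum())
                row[f"count_{g}"] = c
                row[f"pct_{g}"] = round(100.0 * c / sizes[g], 1)
                total_count += c
            row["count_total"] = total_count
            row["pct_total"] = round(100.0 * total_count / len(t), 1)
            rows.append(row)

        test_levels = (
            [l for l in levels if l not in NA_LEVELS] if na_policy == "exclude" else levels
        )
        contingency = np.array(
            [
                [
                    int(((col == level) & (t[group_var].astype(str) == g)).sum())
                    for level in test_levels
                ]
                for g in groups
            ]
        )
        keep_cols = contingency.sum(axis=0) > 0
        contingency = contingency[:, keep_cols]
        if contingency.shape[1] >= 2 and (contingency.sum(axis=1) > 0).all():
            stat, p, used = association_test(contingency, method=test_method)
        else:
            stat, p, used = float("nan"), float("nan"), "none"
        test_rows.append(
            {"variable": var, "statistic": stat, "p_value": p, "test_used": used}
        )

    rows_df = pd.DataFrame(rows)
    tests_df = pd.DataFrame(test_rows).set_index("variable")
    return BaselineTable(rows_df, tests_df, sizes)
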