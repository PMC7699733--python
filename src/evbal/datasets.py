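"""Small built-in datasets constructed in code (no data files).

:func:`study_cohort_metadata` returns the 24-sample clinical annotation of
the emulated BAL-EV case-control cohort: 12 non-cancer controls and 12
lung-cancer cases with the published per-group marginal distributions of
age group, smoking history, gender, batch, stage and two-year vital
status.  Only the per-group marginals are published; the joint assignment
across variables within a group is otherwise arbitrary, except that the
five deceased cancer cases are the five stage-IV cases (stage IV and
mortality travel together in this cohort).
"""

from __future__ import annotations

import pandas as pd

from .containers import SampleMetadata


def _expand(spec: list[tuple[str, int]]) -> list[str]:
    out: list[str] = []
    for level, n in spec:
        out.extend([level] * n)
    return out


def study_cohort_metadata() -> SampleMetadata:
    """The 24-sample baseline cohort (12 controls, 12 cancer cases)."""
    control = pd.DataFrame(
        {
            "cancer_status": ["NO"] * 12,
            "gender": _expand([("F", 8), ("M", 4)]),
            "smoking": _expand(
                [("current", 4), ("former", 2), ("non", 2), ("unknown", 4)]
            ),
            "batch": _expand([("1", 2), ("2", 9), ("3", 1)]),
            "stage": _expand([("no", 11), ("NA", 1)]),
            "vital_status": ["alive"] * 12,
            "age_group": _expand([("<55", 4), (">55", 1), ("NA", 7)]),
        },
        index=[f"C{i+1:02d}" for i in range(12)],
    )
    cancer = pd.DataFrame(
        {
            "cancer_status": ["YES"] * 12,
            "gender": _expand([("F", 3), ("M", 8), ("NA", 1)]),
            "smoking": _expand(
                [("current", 3), ("former", 6), ("non", 1), ("unknown", 2)]
            ),
            "batch": _expand([("1", 5), ("2", 6), ("3", 1)]),
            # the five stage-IV cases are the five deceased cases
            "stage": _expand([("4", 5), ("2", 1), ("3", 1), ("NA", 5)]),
            "vital_status": _expand([("dead", 5), ("alive", 7)]),
            "age_group": _expand([("<55", 1), (">55", 1), ("NA", 10)]),
        },
        index=[f"T{i+1:02d}" for i in range(12)],
    )
    table = pd.concat([control, cancer])
    table.index.name = "sample_id"
    return SampleMetadata(table)
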