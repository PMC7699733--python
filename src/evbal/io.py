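"""Readers and writers for every external format the pipeline touches.

Quant tables follow MaxQuant ``proteinGroups.txt`` conventions: tab-delimited,
iBAQ-prefixed intensity columns, "+"-flag columns for reverse hits and
potential contaminants.  Gene sets use the standard GMT dialect.  Sample
metadata and NTA size distributions are plain CSV.  Marker panels are YAML.

All writers emit a leading ``#`` comment line recording the tool version and
the parameters used; readers skip such lines.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .containers import (
    BIN_WIDTH_NM,
    FormatError,
    GeneSet,
    GeneSetCollection,
    MarkerPanel,
    METADATA_COLUMNS,
    QuantMatrix,
    SampleMetadata,
    SizeDistribution,
)

logger = logging.getLogger("evbal")


def _provenance(stage: str, **params) -> str:
    from . import __version__

    kv = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# evbal {__version__} | {stage} | {kv}".rstrip(" |")


# ---------------------------------------------------------------------------
# Quant tables (MaxQuant proteinGroups dialect)
# ---------------------------------------------------------------------------


def read_quant_table(
    path: str | Path,
    id_column: str = "Protein IDs",
    gene_column: str = "Gene names",
    ibaq_prefix: str = "iBAQ ",
    reverse_column: str = "Reverse",
    contaminant_column: str = "Potential contaminant",
) -> QuantMatrix:
    """Read a tab-delimited protein quantification table.

    One matrix row per table row; sample ids are the iBAQ column names with
    the prefix stripped.  Blank or missing intensities are coerced to 0
    ("not identified").  Rows flagged "+" in the reverse/contaminant columns
    are kept but marked for downstream filtering.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if id_column not in df.columns:
        raise FormatError(f"{path.name}: missing id column {id_column!r}")
    sample_cols = [c for c in df.columns if c.startswith(ibaq_prefix)]
    if not sample_cols:
        raise FormatError(
            f"{path.name}: no intensity columns with prefix {ibaq_prefix!r}"
        )
    ids = df[id_column].astype(str)
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].unique().tolist()
        raise FormatError(f"{path.name}: duplicate protein ids {dups}")

    values = pd.DataFrame(index=ids.values, dtype=float)
    for col in sample_cols:
        raw = df[col].fillna("").str.strip().replace("", "0")
        try:
            values[col[len(ibaq_prefix):]] = raw.astype(float).values
        except ValueError:
            bad = raw[pd.to_numeric(raw, errors="coerce").isna()]
            row = ids.iloc[bad.index[0]]
            raise FormatError(
                f"{path.name}: non-numeric intensity {bad.iloc[0]!r} "
                f"in column {col!r}, row {row!r}"
            ) from None

    if gene_column in df.columns:
        genes = df[gene_column].fillna("").astype(str).values
    else:
        genes = ids.values
    flagged = np.zeros(len(df), dtype=bool)
    for flag_col in (reverse_column, contaminant_column):
        if flag_col in df.columns:
            flagged |= (df[flag_col].fillna("") == "+").values
    return QuantMatrix(
        values, pd.Series(genes, index=values.index), pd.Series(flagged, index=values.index)
    )


def write_quant_table(
    m: QuantMatrix,
    path: str | Path,
    id_column: str = "Protein IDs",
    gene_column: str = "Gene names",
    ibaq_prefix: str = "iBAQ ",
    **params,
) -> None:
    path = Path(path)
    out = pd.DataFrame({id_column: m.protein_ids, gene_column: m.gene_symbols.values})
    for s in m.sample_ids:
        out[f"{ibaq_prefix}{s}"] = m.data[s].values
    out["Reverse"] = ""
    out["Potential contaminant"] = np.where(m.flagged.values, "+", "")
    with open(path, "w") as fh:
        fh.write(_provenance("quant_table", **params) + "\n")
        out.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    # "NA" is a real factor level here, not a missing value
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise FormatError(f"{Path(path).name}: missing 'sample_id' column")
    df = df.set_index("sample_id")
    return SampleMetadata(df)


def write_sample_metadata(meta: SampleMetadata, path: str | Path, **params) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance("sample_metadata", **params) + "\n")
        meta.table.to_csv(fh, index_label="sample_id")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name <TAB> description <TAB> member symbols."""
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path.name}: line {lineno} has {len(fields)} fields; "
                    "GMT requires name, description and at least one member"
                )
            name, desc, *members = fields
            members = [m for m in members if m.strip()]
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                dropped = len(members) - len(deduped)
                warnings.warn(
                    f"{path.name}: line {lineno} ({name}): removed {dropped} "
                    "duplicate member(s)"
                )
                logger.warning("GMT %s line %d: %d duplicates removed", name, lineno, dropped)
            if name in sets:
                raise FormatError(f"{path.name}: duplicate set name {name!r}")
            sets[name] = GeneSet(name, desc, tuple(deduped))
    return GeneSetCollection(sets)


def write_gene_sets(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


# ---------------------------------------------------------------------------
# NTA size distributions
# ---------------------------------------------------------------------------


def read_size_distribution(
    path: str | Path,
    sample_id: str | None = None,
    size_column: str = "size_nm",
    count_column: str = "count",
) -> SizeDistribution:
    """Read a CSV export of NTA particle counts per size bin.

    Input on a grid finer than 0.5 nm is rebinned by summing counts into
    0.5 nm bins; a grid coarser than 0.5 nm is rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    for col in (size_column, count_column):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing column {col!r}")
    sizes = df[size_column].to_numpy(dtype=float)
    counts = df[count_column].to_numpy(dtype=float)
    if (counts < 0).any():
        bad = sizes[counts < 0][0]
        raise FormatError(f"{path.name}: negative count at size {bad} nm")
    order = np.argsort(sizes)
    sizes, counts = sizes[order], counts[order]
    sid = sample_id if sample_id is not None else path.stem

    spacing = np.diff(sizes)
    if len(sizes) >= 2 and not np.allclose(spacing, BIN_WIDTH_NM, atol=1e-9):
        step = float(np.median(spacing))
        if step > BIN_WIDTH_NM + 1e-9:
            raise FormatError(
                f"{path.name}: bin spacing {step} nm is coarser than "
                f"{BIN_WIDTH_NM} nm and cannot be rebinned"
            )
        left = np.floor(sizes / BIN_WIDTH_NM) * BIN_WIDTH_NM
        grid = np.arange(left.min(), left.max() + BIN_WIDTH_NM / 2, BIN_WIDTH_NM)
        binned = np.zeros(len(grid))
        idx = np.round((left - left.min()) / BIN_WIDTH_NM).astype(int)
        np.add.at(binned, idx, counts)
        return SizeDistribution(sid, grid, binned)
    return SizeDistribution(sid, sizes, counts)


def write_size_distribution(dist: SizeDistribution, path: str | Path, **params) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance("size_distribution", sample=dist.sample_id, **params) + "\n")
        pd.DataFrame(
            {"size_nm": dist.bin_left_edges, "count": dist.counts}
        ).to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Marker panels (YAML)
# ---------------------------------------------------------------------------


def read_marker_panels(path: str | Path) -> MarkerPanel:
    """Read a YAML marker-panel file.

    Layout::

        panels:
          exosome_markers: [CD63, CD9, CD81]
          monocytic_lineage: [MONO1, MONO2]
        compartment:
          CD63: EV
          MONO1: cell-population
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "panels" not in doc or "compartment" not in doc:
        raise FormatError(f"{Path(path).name}: expected 'panels' and 'compartment' keys")
    panels = {str(k): tuple(map(str, v)) for k, v in doc["panels"].items()}
    compartment = {str(k): str(v) for k, v in doc["compartment"].items()}
    return MarkerPanel(panels, compartment)


def write_marker_panels(panel: MarkerPanel, path: str | Path) -> None:
    doc = {
        "panels": {k: list(v) for k, v in panel.panels.items()},
        "compartment": dict(panel.compartment),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Generic result tables
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path, stage: str, index: bool = False, **params) -> None:
    """Write a result table as TSV with a provenance comment line."""
    with open(path, "w") as fh:
        fh.write(_provenance(stage, **params) + "\n")
        df.to_csv(fh, sep="\t", index=index)
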