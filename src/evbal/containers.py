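"""In-memory containers shared by every pipeline stage.

The central object is :class:`QuantMatrix`, a dense proteins × samples
iBAQ abundance table in which an explicit 0 means "not identified in that
sample" — never NaN.  Detection (`value > 0`) is therefore a property of
the raw matrix and survives any monotone transform of the intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file or table violates an invariant of its domain type."""


# ---------------------------------------------------------------------------
# QuantMatrix
# ---------------------------------------------------------------------------

CANCER_LEVELS = ("NO", "YES")
GENDER_LEVELS = ("F", "M", "NA")
SMOKING_LEVELS = ("current", "former", "non", "unknown")
STAGE_LEVELS = ("no", "2", "3", "4", "NA")
VITAL_LEVELS = ("alive", "dead")
AGE_LEVELS = ("<55", ">55", "NA")

METADATA_COLUMNS = (
    "cancer_status",
    "gender",
    "smoking",
    "batch",
    "stage",
    "vital_status",
    "age_group",
)

_LEVELS: Mapping[str, tuple] = {
    "cancer_status": CANCER_LEVELS,
    "gender": GENDER_LEVELS,
    "smoking": SMOKING_LEVELS,
    "stage": STAGE_LEVELS,
    "vital_status": VITAL_LEVELS,
    "age_group": AGE_LEVELS,
}


@dataclass
class QuantMatrix:
    """Protein-isoform × sample abundance matrix (iBAQ intensity units).

    Parameters
    ----------
    data
        Dense non-negative matrix; index = protein-isoform accessions,
        columns = sample identifiers.  Zero encodes "not identified".
    gene_symbols
        Gene symbol per protein row, aligned with ``data.index``.  Symbols
        repeat across isoforms of the same gene.
    flagged
        Boolean per protein row: marked reverse/decoy or contaminant at
        read time.  Flagged rows are preserved until
        :func:`evbal.preprocess.remove_contaminants` drops them.
    """

    data: pd.DataFrame
    gene_symbols: pd.Series
    flagged: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate protein ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        self.data = self.data.astype(float)
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            raise FormatError("non-finite abundance values")
        if (vals < 0).any():
            raise FormatError("negative abundance values")
        self.gene_symbols = pd.Series(self.gene_symbols, dtype=object)
        if len(self.gene_symbols) != self.data.shape[0]:
            raise FormatError(
                "gene_symbols length does not match number of protein rows"
            )
        self.gene_symbols.index = self.data.index
        if self.flagged is None:
            self.flagged = pd.Series(False, index=self.data.index)
        else:
            self.flagged = pd.Series(self.flagged, dtype=bool)
            if len(self.flagged) != self.data.shape[0]:
                raise FormatError("flagged length does not match protein rows")
            self.flagged.index = self.data.index

    # -- basic accessors ---------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def detected(self) -> pd.DataFrame:
        """Boolean identification mask: value strictly positive."""
        return self.data > 0

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(
            self.data.copy(), self.gene_symbols.copy(), self.flagged.copy()
        )

    def subset_proteins(self, protein_ids: Sequence[str]) -> "QuantMatrix":
        idx = pd.Index(protein_ids)
        missing = idx.difference(self.data.index)
        if len(missing):
            raise KeyError(f"unknown protein ids: {list(missing)}")
        return QuantMatrix(
            self.data.loc[idx],
            self.gene_symbols.loc[idx],
            self.flagged.loc[idx],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "QuantMatrix":
        idx = pd.Index(sample_ids)
        missing = idx.difference(self.data.columns)
        if len(missing):
            raise KeyError(f"unknown sample ids: {list(missing)}")
        return QuantMatrix(
            self.data.loc[:, idx], self.gene_symbols.copy(), self.flagged.copy()
        )

    def collapse_genes(self, how: str = "max") -> "QuantMatrix":
        """Collapse isoform rows to gene level.

        ``how="max"`` keeps the per-sample maximum across isoforms (the
        dominant isoform's iBAQ dominates the gene signal); ``how="sum"``
        adds isoforms.  Rows without a gene symbol are dropped.
        """
        if how not in ("max", "sum"):
            raise ValueError("how must be 'max' or 'sum'")
        keep = self.gene_symbols.notna() & (self.gene_symbols != "")
        df = self.data.loc[keep.values]
        sym = self.gene_symbols.loc[keep.values]
        grouped = df.groupby(sym.values, sort=True)
        collapsed = grouped.max() if how == "max" else grouped.sum()
        flags = self.flagged.loc[keep.values].groupby(sym.values, sort=True).any()
        return QuantMatrix(
            collapsed,
            pd.Series(collapsed.index, index=collapsed.index, dtype=object),
            flags,
        )


# ---------------------------------------------------------------------------
# SampleMetadata
# ---------------------------------------------------------------------------


@dataclass
class SampleMetadata:
    """Per-sample clinical/technical annotations, indexed by sample id.

    Columns: cancer_status {NO,YES}, gender {F,M,NA}, smoking
    {current,former,non,unknown}, batch (small integer), stage
    {no,2,3,4,NA}, vital_status {alive,dead}, age_group {<55,>55,NA}.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids in metadata: {dups}")
        missing = [c for c in METADATA_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"metadata missing required columns: {missing}")
        t = t.copy()
        for col, levels in _LEVELS.items():
            t[col] = t[col].astype(str)
            bad = sorted(set(t[col]) - set(levels))
            if bad:
                raise FormatError(
                    f"metadata column {col!r} has invalid levels {bad}; "
                    f"allowed: {levels}"
                )
        t["batch"] = t["batch"].astype(int)
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def aligned_to(self, quant: QuantMatrix) -> "SampleMetadata":
        """Subset + reorder to a QuantMatrix's samples; error on missing."""
        missing = [s for s in quant.sample_ids if s not in self.table.index]
        if missing:
            raise FormatError(f"samples absent from metadata: {missing}")
        return SampleMetadata(self.table.loc[quant.sample_ids])

    def group_mask(self, column: str, level: str) -> pd.Series:
        return self.table[column] == level

    def poor_outcome_mask(self, contrast: str = "stage4_or_dead") -> pd.Series:
        """Partition used for the proteome-complexity association.

        ``stage4_or_dead`` (default): stage-IV disease or death during
        follow-up; ``stage4`` and ``dead`` isolate each component.
        """
        t = self.table
        if contrast == "stage4_or_dead":
            return (t["stage"] == "4") | (t["vital_status"] == "dead")
        if contrast == "stage4":
            return t["stage"] == "4"
        if contrast == "dead":
            return t["vital_status"] == "dead"
        if contrast == "cancer":
            return t["cancer_status"] == "YES"
        raise ValueError(f"unknown contrast {contrast!r}")


# ---------------------------------------------------------------------------
# GeneSetCollection
# ---------------------------------------------------------------------------


@dataclass
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise FormatError(f"gene set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise FormatError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """Named functional categories (KEGG/GO/CORUM-like) → member symbols."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[str]]) -> "GeneSetCollection":
        return cls(
            {name: GeneSet(name, "", tuple(dict.fromkeys(m))) for name, m in d.items()}
        )

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def restrict_to(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every category with a universe; drop emptied sets."""
        uni = set(universe)
        out: dict[str, GeneSet] = {}
        for gs in self:
            members = tuple(g for g in gs.members if g in uni)
            if members:
                out[gs.name] = GeneSet(gs.name, gs.description, members)
        return GeneSetCollection(out)


# ---------------------------------------------------------------------------
# SizeDistribution
# ---------------------------------------------------------------------------

BIN_WIDTH_NM = 0.5


@dataclass
class SizeDistribution:
    """NTA particle counts on a uniform 0.5 nm size grid."""

    sample_id: str
    bin_left_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_left_edges = np.asarray(self.bin_left_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_left_edges.ndim != 1 or self.counts.ndim != 1:
            raise FormatError("bin edges and counts must be 1-D")
        if len(self.bin_left_edges) != len(self.counts):
            raise FormatError("bin edges and counts differ in length")
        if len(self.bin_left_edges) >= 2:
            diffs = np.diff(self.bin_left_edges)
            if not np.allclose(diffs, BIN_WIDTH_NM, atol=1e-9):
                raise FormatError(
                    f"bins of {self.sample_id!r} are not uniformly "
                    f"{BIN_WIDTH_NM} nm apart"
                )
        if (self.counts < 0).any():
            bad = self.bin_left_edges[self.counts < 0][0]
            raise FormatError(
                f"negative particle count at bin {bad} nm in {self.sample_id!r}"
            )

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_left_edges + BIN_WIDTH_NM / 2.0

    def total(self) -> float:
        return float(self.counts.sum())

    def normalized(self) -> np.ndarray:
        tot = self.counts.sum()
        if tot == 0:
            raise FormatError(f"{self.sample_id!r} has zero total particle count")
        return self.counts / tot

    def modal_size(self) -> float:
        """Center of the bin with the maximal count."""
        return float(self.bin_centers[int(np.argmax(self.counts))])


# ---------------------------------------------------------------------------
# MarkerPanel
# ---------------------------------------------------------------------------

COMPARTMENT_FLAGS = ("EV", "non-EV", "cell-population")


@dataclass
class MarkerPanel:
    """Marker symbols for subcellular compartments and cell populations.

    ``panels`` maps a population/compartment name to member symbols;
    ``compartment`` assigns each marker exactly one flag among
    {EV, non-EV, cell-population}.
    """

    panels: dict[str, tuple[str, ...]]
    compartment: dict[str, str]

    def __post_init__(self) -> None:
        self.panels = {k: tuple(v) for k, v in self.panels.items()}
        for name, members in self.panels.items():
            if len(members) == 0:
                raise FormatError(f"panel {name!r} has no markers")
            if len(set(members)) != len(members):
                raise FormatError(f"panel {name!r} has duplicate markers")
        for marker, flag in self.compartment.items():
            if flag not in COMPARTMENT_FLAGS:
                raise FormatError(
                    f"marker {marker!r} has invalid compartment flag {flag!r}"
                )
        all_members = {m for members in self.panels.values() for m in members}
        missing = sorted(all_members - set(self.compartment))
        if missing:
            raise FormatError(f"markers without a compartment flag: {missing}")

    def markers_with_flag(self, flag: str) -> list[str]:
        if flag not in COMPARTMENT_FLAGS:
            raise ValueError(f"unknown flag {flag!r}")
        return sorted(m for m, f in self.compartment.items() if f == flag)

    @property
    def ev_markers(self) -> list[str]:
        return self.markers_with_flag("EV")

    @property
    def non_ev_markers(self) -> list[str]:
        return self.markers_with_flag("non-EV")

    def population_panels(self) -> dict[str, tuple[str, ...]]:
        """Panels whose members are all cell-population markers."""
        return {
            name: members
            for name, members in self.panels.items()
            if all(self.compartment.get(m) == "cell-population" for m in members)
        }
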