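"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the product of a label-free LC-MS experiment on BAL
small-EV isolates: a dense proteins × samples iBAQ matrix whose log2
intensities are approximately normal, with intensity-dependent missingness
(zero-inflation via a logistic detection model), case/control structure with
gender/smoking/batch nuisance effects, planted differentially-expressed
proteins, planted sample-unique proteins concentrated in poor-outcome
samples, marker panels spiked at controlled abundance, and unimodal NTA
size distributions with a mode near 100 nm.

Defaults mirror the study design being emulated: 12 controls + 12 cancer
cases, ~3000 genes expanding to ~7500 protein isoforms, 5/12 of cancer
cases stage-IV and deceased.  A single seed drives everything; child
generators are derived deterministically so any stage is reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import (
    FormatError,
    GeneSetCollection,
    MarkerPanel,
    QuantMatrix,
    SampleMetadata,
    SizeDistribution,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic BAL-EV cohort.

    Abundances are generated in log2 iBAQ units: per-gene baselines are
    Normal(``mu_log2``, ``sigma_log2``), isoforms scatter around their gene
    with sd ``isoform_sd``, and each matrix cell adds Normal(0,
    ``noise_sd``).  A cell is detected with probability
    ``expit(detect_prob_slope * (log2_abundance - detect_mid))``, so
    missingness concentrates in the low-abundance tail as in label-free MS.
    Planted two-group effects (``n_de`` proteins shifted by ``de_log2fc`` in
    cancer) are drawn from reliably detected proteins so that recovery
    measures the statistics rather than the missingness process.  Each
    poor-outcome (stage-IV/deceased) sample receives
    Poisson(``extra_unique_mean``) proteins detected only in that sample —
    the mechanism behind the proteome-complexity signal attributed to tumor
    heterogeneity.
    """

    n_control: int = 12
    n_cancer: int = 12
    n_genes: int = 3000
    isoforms_per_gene_mean: float = 2.5
    mu_log2: float = 20.0
    sigma_log2: float = 4.0
    isoform_sd: float = 1.0
    noise_sd: float = 1.0
    detect_prob_slope: float = 2.0
    detect_mid: float | None = None  # default: mu_log2 - 1.5 * sigma_log2
    n_de: int = 100
    de_log2fc: float = 2.0
    frac_stage4: float = 5.0 / 12.0
    extra_unique_mean: float = 40.0
    unique_abundance_log2: float = 16.0
    batch_sd: float = 0.3
    covariate_effect_sd: float = 0.3
    n_batches: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_control", "n_cancer", "n_genes", "n_de", "n_batches"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_control + self.n_cancer < 2:
            raise ConfigError("need at least 2 samples in total")
        if not 0.0 <= self.frac_stage4 <= 1.0:
            raise ConfigError("frac_stage4 must be in [0, 1]")
        if self.isoforms_per_gene_mean < 1.0:
            raise ConfigError("isoforms_per_gene_mean must be >= 1")
        if self.extra_unique_mean < 0:
            raise ConfigError("extra_unique_mean must be non-negative")

    @property
    def detection_midpoint(self) -> float:
        if self.detect_mid is not None:
            return self.detect_mid
        return self.mu_log2 - 1.5 * self.sigma_log2


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    seqs = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(s) for s in seqs]


# Group-conditional covariate frequencies patterned on the emulated
# case-control cohort (12 vs 12): gender and smoking mildly imbalanced
# across cancer status, batches shared.
_GENDER_P = {"NO": (8 / 12, 4 / 12, 0.0), "YES": (3 / 12, 8 / 12, 1 / 12)}
_SMOKING_P = {"NO": (4 / 12, 2 / 12, 2 / 12, 4 / 12), "YES": (3 / 12, 6 / 12, 1 / 12, 2 / 12)}
_BATCH_P = (7 / 24, 15 / 24, 2 / 24)


def _simulate_metadata(cfg: SimulationConfig, rng: np.random.Generator) -> SampleMetadata:
    sample_ids = [f"C{i+1:02d}" for i in range(cfg.n_control)] + [
        f"T{i+1:02d}" for i in range(cfg.n_cancer)
    ]
    status = ["NO"] * cfg.n_control + ["YES"] * cfg.n_cancer
    gender = [
        ("F", "M", "NA")[rng.choice(3, p=_GENDER_P[s])] for s in status
    ]
    smoking = [
        ("current", "former", "non", "unknown")[rng.choice(4, p=_SMOKING_P[s])]
        for s in status
    ]
    batch_p = np.array(_BATCH_P[: cfg.n_batches])
    batch_p = batch_p / batch_p.sum()
    batch = [int(rng.choice(cfg.n_batches, p=batch_p)) + 1 for _ in status]

    n_stage4 = int(round(cfg.frac_stage4 * cfg.n_cancer))
    cancer_idx = [i for i, s in enumerate(status) if s == "YES"]
    stage4_idx = set(rng.choice(cancer_idx, size=n_stage4, replace=False).tolist()) if n_stage4 else set()
    stage, vital = [], []
    for i, s in enumerate(status):
        if s == "NO":
            stage.append("no")
            vital.append("alive")
        elif i in stage4_idx:
            stage.append("4")
            vital.append("dead")  # stage IV coupled to two-year mortality
        else:
            stage.append(("2", "3", "NA")[rng.choice(3, p=(1 / 7, 1 / 7, 5 / 7))])
            vital.append("alive")
    age = [("<55", ">55", "NA")[rng.choice(3, p=(0.2, 0.1, 0.7))] for _ in status]
    table = pd.DataFrame(
        {
            "cancer_status": status,
            "gender": gender,
            "smoking": smoking,
            "batch": batch,
            "stage": stage,
            "vital_status": vital,
            "age_group": age,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SampleMetadata(table)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[QuantMatrix, SampleMetadata, dict]:
    """Simulate a full case-control cohort.

    Returns the iBAQ matrix (raw intensity scale, zeros = not identified),
    the sample metadata, and a truth record listing the planted DE protein
    ids, the planted sample-unique protein ids per sample, the nuisance
    offsets and the group labels.  Identical configs (including seed) yield
    identical output.
    """
    cfg = config
    (
        rng_meta,
        rng_genes,
        rng_effects,
        rng_abund,
        rng_detect,
        rng_unique,
    ) = _child_rngs(cfg.seed, 6)

    meta = _simulate_metadata(cfg, rng_meta)
    samples = meta.sample_ids
    n_samples = len(samples)

    # gene/isoform skeleton
    gene_base = rng_genes.normal(cfg.mu_log2, cfg.sigma_log2, size=cfg.n_genes)
    iso_counts = 1 + rng_genes.poisson(cfg.isoforms_per_gene_mean - 1.0, size=cfg.n_genes)
    gene_of_row = np.repeat(np.arange(cfg.n_genes), iso_counts)
    n_rows = len(gene_of_row)
    iso_base = gene_base[gene_of_row] + rng_genes.normal(0.0, cfg.isoform_sd, size=n_rows)
    protein_ids = []
    counter = np.zeros(cfg.n_genes, dtype=int)
    for g in gene_of_row:
        counter[g] += 1
        protein_ids.append(f"P{g:05d}-{counter[g]}")
    gene_symbols = [f"G{g:05d}" for g in gene_of_row]

    # nuisance per-sample offsets
    t = meta.table
    batch_eff = {b: rng_effects.normal(0, cfg.batch_sd) for b in sorted(t["batch"].unique())}
    gender_eff = {g: rng_effects.normal(0, cfg.covariate_effect_sd) for g in ("F", "M", "NA")}
    smoke_eff = {
        s: rng_effects.normal(0, cfg.covariate_effect_sd)
        for s in ("current", "former", "non", "unknown")
    }
    offsets = np.array(
        [
            batch_eff[t.loc[s, "batch"]]
            + gender_eff[t.loc[s, "gender"]]
            + smoke_eff[t.loc[s, "smoking"]]
            for s in samples
        ]
    )
    cancer_mask = (t["cancer_status"] == "YES").to_numpy()

    # planted DE rows: restricted to reliably detected proteins (detection
    # still near-certain 2.5 noise-sd below the isoform baseline) outside
    # the extreme top tail, where rank-based normalization saturates
    mid = cfg.detection_midpoint
    p_detect_base = expit(cfg.detect_prob_slope * (iso_base - mid))
    p_detect_worst = expit(
        cfg.detect_prob_slope * (iso_base - 2.5 * cfg.noise_sd - mid)
    )
    cap = np.quantile(iso_base, 0.90)
    eligible = np.where((p_detect_worst >= 0.999) & (iso_base <= cap))[0]
    if cfg.n_de > 0:
        if len(eligible) >= cfg.n_de:
            de_rows = rng_effects.choice(eligible, size=cfg.n_de, replace=False)
        else:
            de_rows = np.argsort(p_detect_base)[-cfg.n_de:]
    else:
        de_rows = np.array([], dtype=int)
    # balanced directions: half up-, half down-regulated in cancer
    de_sign = np.ones(len(de_rows))
    de_sign[1::2] = -1.0
    de_effect = np.zeros(n_rows)
    de_effect[de_rows] = de_sign * cfg.de_log2fc

    # log2 abundance and logistic detection
    log2_ab = (
        iso_base[:, None]
        + offsets[None, :]
        + rng_abund.normal(0.0, cfg.noise_sd, size=(n_rows, n_samples))
    )
    log2_ab[:, cancer_mask] += de_effect[:, None]
    p_detect = expit(cfg.detect_prob_slope * (log2_ab - mid))
    detected = rng_detect.random(size=(n_rows, n_samples)) < p_detect
    values = np.where(detected, np.maximum(np.exp2(log2_ab) - 1.0, 0.0), 0.0)

    data = pd.DataFrame(values, index=protein_ids, columns=samples)
    symbols = list(gene_symbols)

    # planted sample-unique proteins in poor-outcome samples
    poor = meta.poor_outcome_mask().to_numpy()
    unique_truth: dict[str, list[str]] = {}
    extra_frames = []
    for j, s in enumerate(samples):
        if not poor[j] or cfg.extra_unique_mean <= 0:
            unique_truth[s] = []
            continue
        k = int(rng_unique.poisson(cfg.extra_unique_mean))
        ids = [f"U{s}_{i+1:03d}" for i in range(k)]
        unique_truth[s] = ids
        if k == 0:
            continue
        vals = np.zeros((k, n_samples))
        vals[:, j] = np.exp2(
            cfg.unique_abundance_log2 + rng_unique.normal(0.0, 1.0, size=k)
        ) - 1.0
        extra_frames.append(pd.DataFrame(vals, index=ids, columns=samples))
        symbols.extend(f"GU_{s}_{i+1:03d}" for i in range(k))
    if extra_frames:
        data = pd.concat([data, *extra_frames])

    quant = QuantMatrix(data, pd.Series(symbols, index=data.index))
    truth = {
        "config": asdict(cfg),
        "de_protein_ids": [protein_ids[r] for r in de_rows],
        "de_up_protein_ids": [
            protein_ids[r] for r, s in zip(de_rows, de_sign) if s > 0
        ],
        "de_down_protein_ids": [
            protein_ids[r] for r, s in zip(de_rows, de_sign) if s < 0
        ],
        "de_gene_symbols": sorted({gene_symbols[r] for r in de_rows}),
        "de_up_gene_symbols": sorted(
            {gene_symbols[r] for r, s in zip(de_rows, de_sign) if s > 0}
        ),
        "unique_protein_ids": unique_truth,
        "poor_outcome_samples": [s for s, p in zip(samples, poor) if p],
        "cancer_samples": [s for s, c in zip(samples, cancer_mask) if c],
        "sample_offsets": dict(zip(samples, offsets.tolist())),
    }
    return quant, meta, truth


# ---------------------------------------------------------------------------
# Marker panels
# ---------------------------------------------------------------------------

DEFAULT_EV_MARKERS = (
    "CD63",
    "CD9",
    "CD81",
    "TSG101",
    "PDCD6IP",
    "SDCBP",
    "FLOT1",
    "HSPA8",
)
DEFAULT_NON_EV_MARKERS = ("BCL2", "GOLGA2", "NUP98", "CANX")
DEFAULT_POPULATIONS = (
    "T_cells",
    "CD8_T_cells",
    "cytotoxic_lymphocytes",
    "B_lineage",
    "NK_cells",
    "monocytic_lineage",
    "myeloid_dendritic_cells",
    "neutrophils",
    "endothelial_cells",
    "fibroblasts",
)


def generate_marker_panels(
    sample_ids: Sequence[str],
    *,
    ev_level_log2: float = 20.0,
    contamination_level: float = 0.05,
    population_base_log2: float = 16.0,
    markers_per_population: int = 3,
    population_shifts: Mapping[str, Mapping[str, float]] | None = None,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[MarkerPanel, QuantMatrix]:
    """Create marker panels and a spiked marker QuantMatrix.

    EV markers (tetraspanin-like) are spiked at ``ev_level_log2`` (log2
    iBAQ); non-EV organelle markers at ``contamination_level`` times the EV
    intensity on the raw scale (0 → absent); each of the ten cell
    populations gets ``markers_per_population`` synthetic markers at
    ``population_base_log2`` plus any per-sample shift from
    ``population_shifts[population][sample_id]``.  Gaussian log2 noise of
    sd ``noise_sd`` is added to nonzero spikes.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    shifts = population_shifts or {}
    samples = list(sample_ids)

    panels: dict[str, tuple[str, ...]] = {
        "exosome_markers": DEFAULT_EV_MARKERS,
        "non_ev_markers": DEFAULT_NON_EV_MARKERS,
    }
    compartment = {m: "EV" for m in DEFAULT_EV_MARKERS}
    compartment.update({m: "non-EV" for m in DEFAULT_NON_EV_MARKERS})

    rows: dict[str, np.ndarray] = {}
    symbols: list[str] = []

    def _spike(level_log2: np.ndarray) -> np.ndarray:
        noisy = level_log2 + (
            rng.normal(0.0, noise_sd, size=len(samples)) if noise_sd > 0 else 0.0
        )
        return np.maximum(np.exp2(noisy) - 1.0, 0.0)

    for m in DEFAULT_EV_MARKERS:
        rows[m] = _spike(np.full(len(samples), ev_level_log2))
        symbols.append(m)
    for m in DEFAULT_NON_EV_MARKERS:
        if contamination_level <= 0:
            rows[m] = np.zeros(len(samples))
        else:
            rows[m] = contamination_level * _spike(np.full(len(samples), ev_level_log2))
        symbols.append(m)

    for pop in DEFAULT_POPULATIONS:
        members = tuple(
            f"{pop.upper()}_M{i+1}" for i in range(markers_per_population)
        )
        panels[pop] = members
        pop_shift = shifts.get(pop, {})
        level = np.array(
            [population_base_log2 + float(pop_shift.get(s, 0.0)) for s in samples]
        )
        for m in members:
            compartment[m] = "cell-population"
            rows[m] = _spike(level)
            symbols.append(m)

    data = pd.DataFrame(rows, index=samples).T
    panel = MarkerPanel(panels, compartment)
    quant = QuantMatrix(data, pd.Series(symbols, index=data.index))
    return panel, quant


def vstack_quant(top: QuantMatrix, bottom: QuantMatrix) -> QuantMatrix:
    """Stack two QuantMatrix objects sharing the same samples."""
    if list(top.sample_ids) != list(bottom.sample_ids):
        raise FormatError("sample ids differ between matrices")
    data = pd.concat([top.data, bottom.data])
    genes = pd.concat([top.gene_symbols, bottom.gene_symbols])
    flags = pd.concat([top.flagged, bottom.flagged])
    return QuantMatrix(data, genes, flags)


# ---------------------------------------------------------------------------
# Gene sets for the demo pipeline / recovery tests
# ---------------------------------------------------------------------------


def generate_gene_sets(
    universe: Sequence[str],
    planted: Sequence[str] = (),
    n_null_sets: int = 20,
    set_size: int = 30,
    seed: int = 0,
) -> GeneSetCollection:
    """Random annotation categories over a universe, plus a planted one.

    ``planted`` members become the category ``planted_category``; null
    categories draw ``set_size`` symbols uniformly from the rest.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    pool = [g for g in dict.fromkeys(universe) if g not in set(planted)]
    sets: dict[str, list[str]] = {}
    if planted:
        sets["planted_category"] = list(dict.fromkeys(planted))
    for i in range(n_null_sets):
        size = min(set_size, len(pool))
        sets[f"null_set_{i+1:02d}"] = list(rng.choice(pool, size=size, replace=False))
    return GeneSetCollection.from_dict(sets)


# ---------------------------------------------------------------------------
# NTA size distributions
# ---------------------------------------------------------------------------


def generate_size_distributions(
    n_samples: int,
    mode_nm: float = 100.0,
    spread: float = 0.35,
    n_particles: int = 50_000,
    seed: int = 0,
    size_range_nm: tuple[float, float] = (0.0, 500.0),
) -> list[SizeDistribution]:
    """Simulate NTA exports: log-normal particle sizes binned at 0.5 nm.

    Sizes follow LogNormal(mu, sigma) with ``sigma = spread`` and
    ``mu = ln(mode_nm) + spread**2`` so that the analytic mode of the
    density equals ``mode_nm`` exactly.
    """
    if mode_nm <= 0:
        raise ConfigError("mode_nm must be positive")
    if n_particles <= 0:
        raise ConfigError("n_particles must be positive")
    if n_samples <= 0:
        raise ConfigError("n_samples must be positive")
    rngs = _child_rngs(seed, n_samples)
    lo, hi = size_range_nm
    edges = np.arange(lo, hi + 0.25, 0.5)
    mu = np.log(mode_nm) + spread**2
    dists = []
    for i, rng in enumerate(rngs):
        sizes = rng.lognormal(mean=mu, sigma=spread, size=n_particles)
        counts, _ = np.histogram(sizes, bins=edges)
        dists.append(
            SizeDistribution(f"N{i+1:02d}", edges[:-1], counts.astype(float))
        )
    return dists
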