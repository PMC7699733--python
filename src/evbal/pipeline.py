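"""Full-pipeline driver: chain every analysis stage from one config.

The config is a plain mapping (usually loaded from YAML)::

    quant: demo/quant.tsv          # required
    metadata: demo/metadata.csv    # required
    gene_sets: demo/sets.gmt       # optional -> cfra stage skipped if absent
    panels: demo/panels.yaml       # optional -> evqc/cellscores skipped
    nta_dir: demo/nta              # optional -> NTA comparison skipped
    strategy: log_quantile
    covariates: [gender, smoking]
    contrast: stage4_or_dead
    alpha: 0.05
    fc_threshold: 2.0
    seed: 0

Every stage writes a provenance-stamped TSV into the output directory and
logs one line with the md5 of its output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import io as evio
from .cell_scores import population_scores, score_group_summary
from .cfra import category_regulation, cfra_matrix, ratios_from_groups
from .cohort_stats import baseline_table
from .complexity import complexity_association, unique_protein_counts
from .containers import SizeDistribution
from .diffexpr import fit_moderated_model, volcano_table
from .ev_quality import marker_matrix, nta_normalize_and_test, purity_scores, scale_marker_matrix
from .preprocess import PreprocessConfig, preprocess

logger = logging.getLogger("evbal")


class PipelineError(RuntimeError):
    pass


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def _require(config: Mapping, key: str) -> Path:
    if key not in config:
        raise PipelineError(f"config is missing required key {key!r}")
    p = Path(config[key])
    if not p.exists():
        raise PipelineError(f"input path for {key!r} does not exist: {p}")
    return p


def _stage_done(name: str, out: Path) -> None:
    logger.info("stage=%s output=%s md5=%s", name, out, _md5(out))


def run_pipeline(config: Mapping, outdir: str | Path) -> dict[str, Path]:
    """Execute preprocess → de → complexity → evqc → cfra → cellscores →
    baseline and return the stage-output paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    quant = evio.read_quant_table(_require(config, "quant"))
    meta = evio.read_sample_metadata(_require(config, "metadata")).aligned_to(quant)
    strategy = config.get("strategy", "log_quantile")
    alpha = float(config.get("alpha", 0.05))
    fc_threshold = float(config.get("fc_threshold", 2.0))
    covariates = tuple(config.get("covariates", ("gender", "smoking")))
    contrast = config.get("contrast", "stage4_or_dead")

    # 1. preprocess
    norm, info = preprocess(quant, PreprocessConfig(strategy=strategy))
    out = outdir / "normalized.tsv"
    evio.write_quant_table(norm, out, strategy=strategy)
    outputs["preprocess"] = out
    _stage_done("preprocess", out)

    # 2. differential expression
    de = fit_moderated_model(norm, meta, covariates=covariates)
    out = outdir / "de.tsv"
    evio.write_table(de.table.reset_index(names="protein_id"), out, "de",
                     covariates=",".join(covariates), prior_df=f"{de.df_prior:.3f}")
    outputs["de"] = out
    _stage_done("de", out)
    out = outdir / "volcano.tsv"
    evio.write_table(volcano_table(de).reset_index(names="protein_id"), out, "volcano")
    outputs["volcano"] = out

    # 3. complexity (on the raw detection pattern)
    counts = unique_protein_counts(quant)
    assoc = complexity_association(counts, meta, contrast=contrast)
    out = outdir / "complexity.tsv"
    tbl = assoc.per_sample.reset_index(names="sample_id")
    evio.write_table(tbl, out, "complexity", contrast=contrast,
                     W=assoc.statistic, p=f"{assoc.p_value:.6g}", mode=assoc.mode_used)
    outputs["complexity"] = out
    _stage_done("complexity", out)

    # 4. EV quality
    if "panels" in config:
        panel = evio.read_marker_panels(_require(config, "panels"))
        markers = marker_matrix(norm, panel)
        status = meta.table["cancer_status"]
        grouped = markers.T.groupby(status.values).mean().T
        scaled = scale_marker_matrix(grouped)
        report = purity_scores(scaled, panel)
        out = outdir / "ev_quality.tsv"
        qc = scaled.copy()
        qc.loc["ev_score"] = report.ev_score
        qc.loc["contamination_score"] = report.contamination_score
        evio.write_table(qc.reset_index(names="marker"), out, "evqc")
        outputs["evqc"] = out
        _stage_done("evqc", out)

    if "nta_dir" in config:
        nta_dir = _require(config, "nta_dir")
        dists: list[SizeDistribution] = [
            evio.read_size_distribution(p) for p in sorted(nta_dir.glob("*.csv"))
        ]
        groups = {
            d.sample_id: meta.table.loc[d.sample_id, "cancer_status"]
            for d in dists
            if d.sample_id in meta.table.index
        }
        dists = [d for d in dists if d.sample_id in groups]
        comp = nta_normalize_and_test(dists, groups)
        out = outdir / "nta_comparison.tsv"
        evio.write_table(comp.per_bin, out, "nta")
        outputs["nta"] = out
        _stage_done("nta", out)

    # 5. CFRA
    if "gene_sets" in config:
        sets = evio.read_gene_sets(_require(config, "gene_sets"))
        ratios = ratios_from_groups(norm, meta)
        gene_de = de.table.groupby(de.table["gene_symbol"].values)["p_value"].min()
        significant = list(gene_de.index[gene_de < alpha])
        res = category_regulation(
            ratios, sets, significant, alpha=alpha, fc_threshold=fc_threshold
        )
        table = cfra_matrix({"cancer_vs_control": res}) if res else pd.DataFrame()
        out = outdir / "cfra.tsv"
        evio.write_table(table, out, "cfra", alpha=alpha, fc=fc_threshold)
        outputs["cfra"] = out
        _stage_done("cfra", out)

    # 6. cell scores
    if "panels" in config:
        scores = population_scores(norm, panel)
        group_means, order = score_group_summary(scores, meta)
        out = outdir / "cell_scores.tsv"
        full = scores.scores.copy()
        full["n_markers_detected"] = scores.n_markers_detected
        evio.write_table(full.reset_index(names="population"), out, "cellscores",
                         leaf_order=",".join(order))
        outputs["cellscores"] = out
        _stage_done("cellscores", out)

    # 7. baseline characteristics
    bt = baseline_table(meta)
    out = outdir / "baseline.tsv"
    evio.write_table(bt.formatted(), out, "baseline")
    outputs["baseline"] = out
    _stage_done("baseline", out)

    manifest = outdir / "manifest.json"
    manifest.write_text(
        json.dumps({k: str(v) for k, v in outputs.items()}, indent=2)
    )
    return outputs
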