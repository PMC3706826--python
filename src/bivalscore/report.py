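"""Pipeline orchestration: join the day-2-specific differential-expression
set with promoter bivalency scores and a transcription-factor annotation
into a per-gene report, and run the full analysis from one configuration.

Pathway-software gene mapping is replaced by a user-supplied probe-to-gene
table and TF symbol list; report membership therefore depends on that
annotation.  A gene missing from the bivalency table is reported with an
absent score, never score 0: an unscored gene is not a never-bivalent gene.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bivalency import (DEFAULT_FLANK, read_genes_bed, read_genes_gtf,
                        score_all_genes)
from .domains import (CallerParams, DEFAULT_GAPS, read_genome_tsv,
                      read_tags_bed)
from .expression import (DEFAULT_ALPHA, ExpressionMatrix, background_subtract,
                         pairwise_de, pca_scores, quantile_normalize,
                         read_sample_sheet, timepoint_specific_set)

logger = logging.getLogger("bivalscore")


def map_probes_to_genes(de_table: pd.DataFrame,
                        mapping: pd.DataFrame) -> pd.DataFrame:
    """Collapse probe-level results to one best probe per gene.

    ``mapping`` has columns probe_id, gene_symbol.  Probes without a
    mapping are dropped (count logged).  Multiple probes per gene collapse
    to the smallest q; ties break to the larger |fold change|, then the
    lexicographically smallest probe id.
    """
    if mapping.empty:
        raise ValueError("empty probe-to-gene mapping")
    merged = de_table.merge(mapping, on="probe_id", how="left")
    dropped = int(merged["gene_symbol"].isna().sum())
    if dropped:
        logger.info("map_probes_to_genes: %d probes had no gene mapping "
                    "and were dropped", dropped)
    merged = merged.dropna(subset=["gene_symbol"])
    merged = merged.assign(_absfc=merged["fold_change"].abs())
    merged = merged.sort_values(["gene_symbol", "q", "_absfc", "probe_id"],
                                ascending=[True, True, False, True])
    best = merged.groupby("gene_symbol", as_index=False).first()
    return best.drop(columns="_absfc")


def build_report(de_genes: pd.DataFrame, bivalency: pd.DataFrame,
                 tf_list: set[str] | list[str]) -> pd.DataFrame:
    """Left-join DE genes with bivalency scores and TF membership.

    Output columns mirror the per-gene report: gene_symbol, probe_id,
    fold_change, fdr_q, bivalency_score (nullable integer; absent when the
    gene was never scored), is_tf.  Sorted by gene symbol; joins never
    invent rows.
    """
    tf_set = set(tf_list)
    out = de_genes[["gene_symbol", "probe_id", "fold_change", "q"]].rename(
        columns={"q": "fdr_q"})
    biv = bivalency[["gene_id", "bivalency_score"]].rename(
        columns={"gene_id": "gene_symbol"})
    out = out.merge(biv, on="gene_symbol", how="left")
    unscored = int(out["bivalency_score"].isna().sum())
    if unscored:
        logger.info("build_report: %d genes missing a bivalency score "
                    "(reported as absent, not 0)", unscored)
    out["bivalency_score"] = out["bivalency_score"].astype("Int64")
    out["is_tf"] = out["gene_symbol"].isin(tf_set)
    return out.sort_values("gene_symbol").reset_index(drop=True)


# ---------------------------------------------------------------------------
# configuration-driven pipeline
# ---------------------------------------------------------------------------

REQUIRED_PATHS = ("k4_tags", "k27_tags", "genes", "genome", "expression",
                  "samples", "probe_map", "tf_list")


@dataclass
class PipelineConfig:
    """Paths plus analysis parameters for one end-to-end run."""

    k4_tags: Path
    k27_tags: Path
    genes: Path
    genome: Path
    expression: Path
    samples: Path
    probe_map: Path
    tf_list: Path
    outdir: Path
    gaps: tuple[int, ...] = DEFAULT_GAPS
    flank: int = DEFAULT_FLANK
    alpha: float = DEFAULT_ALPHA
    seed: int = 0
    window: int = 200
    evalue: float = 0.1
    effective_fraction: float = 1.0
    contrasts: tuple[tuple[str, str], ...] = (("day0", "day2"),
                                              ("day0", "day4"),
                                              ("day0", "day10"))
    focal_contrast: str = "day2:day0"
    specific_mode: str = "specific"
    negctrl_probes: tuple[str, ...] = ()
    normalize: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        missing = [k for k in REQUIRED_PATHS + ("outdir",) if k not in raw]
        if missing:
            raise ValueError(f"config missing required field(s): {missing}")
        kwargs = dict(raw)
        for key in REQUIRED_PATHS + ("outdir",):
            kwargs[key] = Path(raw[key])
        if "gaps" in raw:
            kwargs["gaps"] = tuple(int(g) for g in raw["gaps"])
        if "contrasts" in raw:
            kwargs["contrasts"] = tuple((a, b) for a, b in raw["contrasts"])
        if "negctrl_probes" in raw:
            kwargs["negctrl_probes"] = tuple(raw["negctrl_probes"])
        cfg = cls(**kwargs)
        for key in REQUIRED_PATHS:
            p = getattr(cfg, key)
            if not Path(p).exists():
                raise ValueError(f"config field {key!r}: path {p} not found")
        return cfg


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute DE -> timepoint-specific set -> probe mapping -> bivalency
    scoring -> report; write all intermediates, a log and a manifest.

    Deterministic for a fixed seed.  Any stage failure aborts with the
    stage name attached.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}, "outputs": {}}
    log_lines: list[str] = []
    t_all = time.perf_counter()

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                if exc is not None:
                    log_lines.append(f"{name}: FAILED after {dt:.2f}s: {exc}")
                    (outdir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                manifest["stages"][name] = round(dt, 3)
                log_lines.append(f"{name}: ok in {dt:.2f}s")
                return False
        return _Stage()

    with stage("load_expression"):
        samples = read_sample_sheet(config.samples)
        em = ExpressionMatrix.from_tsv(config.expression, samples)
    with stage("preprocess"):
        if config.negctrl_probes:
            em = background_subtract(em, list(config.negctrl_probes))
        if config.normalize:
            em = quantile_normalize(em)
    with stage("pairwise_de"):
        de = pairwise_de(em, config.contrasts, config.alpha)
        de_path = outdir / "de_results.tsv"
        de.to_csv(de_path, sep="\t", index=False)
        manifest["outputs"]["de_results"] = de_path.name
    with stage("pca"):
        scores, var = pca_scores(em, n_components=2)
        scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
        manifest["outputs"]["pca_scores"] = "pca_scores.tsv"
        manifest["pca_variance_explained"] = [round(float(v), 4) for v in var]
    with stage("timepoint_specific_set"):
        focal_set = timepoint_specific_set(de, config.focal_contrast,
                                           config.specific_mode)
        manifest["focal_contrast"] = config.focal_contrast
        manifest["specific_mode"] = config.specific_mode
        manifest["n_focal_probes"] = len(focal_set)
    with stage("map_probes_to_genes"):
        mapping = pd.read_csv(config.probe_map, sep="\t")
        focal_de = de[(de["contrast"] == config.focal_contrast)
                      & de["probe_id"].isin(focal_set)]
        de_genes = map_probes_to_genes(focal_de, mapping)
        de_genes.to_csv(outdir / "de_genes.tsv", sep="\t", index=False)
        manifest["outputs"]["de_genes"] = "de_genes.tsv"
    with stage("score_all_genes"):
        layout = read_genome_tsv(config.genome, config.effective_fraction)
        genes_path = Path(config.genes)
        genes = (read_genes_gtf(genes_path)
                 if genes_path.suffix in (".gtf", ".gff") else
                 read_genes_bed(genes_path))
        k4 = read_tags_bed(config.k4_tags, "H3K4me3")
        k27 = read_tags_bed(config.k27_tags, "H3K27me3")
        params = CallerParams(w=config.window, E=config.evalue,
                              effective_fraction=config.effective_fraction,
                              seed=config.seed)
        biv = score_all_genes(genes, k4, k27, layout, params,
                              tuple(config.gaps), config.flank)
        biv.to_csv(outdir / "bivalency_scores.tsv", sep="\t", index=False)
        manifest["outputs"]["bivalency_scores"] = "bivalency_scores.tsv"
        manifest["flank_bp"] = config.flank
        manifest["tss_window_span"] = "closed +/-flank (2*flank+1 bases)"
    with stage("build_report"):
        tf_list = {line.strip() for line in
                   Path(config.tf_list).read_text().splitlines() if line.strip()}
        report = build_report(de_genes, biv, tf_list)
        report.to_csv(outdir / "report.tsv", sep="\t", index=False)
        manifest["outputs"]["report"] = "report.tsv"
        manifest["n_report_rows"] = len(report)

    manifest["total_seconds"] = round(time.perf_counter() - t_all, 3)
    manifest["provenance"] = {
        "de_results": "pairwise_de on the (pre-processed) expression matrix",
        "de_genes": "focal-contrast probes collapsed per gene (best q)",
        "bivalency_scores": "score_all_genes over both marks at all gaps",
        "report": "de_genes left-joined with bivalency_scores and TF list",
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log_lines.append(f"pipeline: done in {manifest['total_seconds']:.2f}s")
    (outdir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return outdir
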