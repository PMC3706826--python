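"""Synthetic genomes, planted chromatin domains, expression matrices and
Ct tables with known ground truth.

Every downstream stage of the package is testable without external data:
the generator plants H3K4me3/H3K27me3 enriched regions on a toy genome,
derives gene models whose promoter class (bivalent / k4_only / k27_only /
unmarked) is known by construction, draws window-level Poisson tag counts
(background rate 0.25 tags per 200-bp window, 8-fold enrichment inside
planted regions by default), and emulates the array and qPCR layers: a
probe x sample intensity matrix with group structure over differentiation
timepoints (day0/day2/day4/day10) plus a mature-endothelial reference
group, planted fold changes and per-value standard errors, and Ct tables
for comparative-quantitation round trips.

What it does not emulate: read-level sequences, mappability, duplicate
reads, batch effects.  Tag positions are emitted directly at the counted
location, so the caller's read shift is exercised separately with
hand-built records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bivalency import DEFAULT_FLANK, GeneModel, write_genes_bed
from .domains import GenomeLayout, TagCollection, write_tags_bed
from .expression import ExpressionMatrix

# study-condition defaults for the ChIP-seq layer
DEFAULT_BACKGROUND_RATE = 0.25   # tags per 200-bp window
DEFAULT_ENRICHMENT_FOLD = 8.0
DEFAULT_REGION_WIDTH = 2000      # bp
DEFAULT_GENE_LENGTH = 1000       # bp

TRUTH_CLASSES = ("bivalent", "k4_only", "k27_only", "unmarked")


@dataclass
class PlantedTruth:
    """Planted enriched regions, gene models and per-gene promoter class."""

    k4_regions: list[tuple[str, int, int]]
    k27_regions: list[tuple[str, int, int]]
    genes: list[GeneModel]
    truth_class: dict[str, str]
    enrichment_fold: float = DEFAULT_ENRICHMENT_FOLD
    background_rate: float = DEFAULT_BACKGROUND_RATE

    def regions_for(self, mark: str) -> list[tuple[str, int, int]]:
        if mark == "H3K4me3":
            return self.k4_regions
        if mark == "H3K27me3":
            return self.k27_regions
        raise ValueError(f"unknown mark {mark!r}")


def make_genome(n_chroms: int, chrom_length: int, seed: int = 0,
                effective_fraction: float = 1.0) -> GenomeLayout:
    """A toy genome of equal-length chromosomes named chrS1..chrSn."""
    if n_chroms < 1:
        raise ValueError("n_chroms must be >= 1")
    if chrom_length < 10_000:
        raise ValueError("chrom_length must be >= 10,000 bp")
    names = tuple(f"chrS{i + 1}" for i in range(n_chroms))
    return GenomeLayout(names, (chrom_length,) * n_chroms, effective_fraction)


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def plant_truth(layout: GenomeLayout, n_bivalent: int = 5, n_k4_only: int = 5,
                n_k27_only: int = 5, n_unmarked: int = 5,
                region_width: int = DEFAULT_REGION_WIDTH, seed: int = 0,
                enrichment_fold: float = DEFAULT_ENRICHMENT_FOLD,
                background_rate: float = DEFAULT_BACKGROUND_RATE,
                ) -> PlantedTruth:
    """Plant non-overlapping enriched regions and matching gene models.

    Region centres are laid out chromosome by chromosome on a regular grid
    with spacing 2*(region_width + 4000) bp, which guarantees that no two
    planted regions (nor their +/-2 kb promoter windows) interact.  The
    class assignment over slots and each gene's strand are shuffled by the
    seed.  Each gene's TSS sits at the centre of its planted region(s); a
    bivalent gene gets co-located H3K4me3 and H3K27me3 regions.
    """
    counts = dict(zip(TRUTH_CLASSES,
                      (n_bivalent, n_k4_only, n_k27_only, n_unmarked)))
    if any(c < 0 for c in counts.values()):
        raise ValueError("class counts must be non-negative")
    n_total = sum(counts.values())
    spacing = 2 * (region_width + 4000)
    centres: list[tuple[str, int]] = []
    for chrom, length in zip(layout.chrom_names, layout.chrom_lengths):
        n_fit = int(length // spacing)
        for i in range(n_fit):
            if len(centres) == n_total:
                break
            centres.append((chrom, spacing // 2 + i * spacing))
    if len(centres) < n_total:
        raise ValueError(
            f"genome too small: fits {len(centres)} regions, need {n_total}")

    rng = np.random.default_rng(seed)
    classes = [cls for cls in TRUTH_CLASSES for _ in range(counts[cls])]
    rng.shuffle(classes)
    half = region_width // 2

    k4_regions, k27_regions, genes = [], [], []
    truth_class: dict[str, str] = {}
    for i, ((chrom, centre), cls) in enumerate(zip(centres, classes)):
        region = (chrom, centre - half, centre + half)
        if cls in ("bivalent", "k4_only"):
            k4_regions.append(region)
        if cls in ("bivalent", "k27_only"):
            k27_regions.append(region)
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"g{i + 1:04d}"
        if strand == "+":
            gene = GeneModel(gid, chrom, centre, centre + DEFAULT_GENE_LENGTH,
                             strand)
        else:
            gene = GeneModel(gid, chrom, centre - DEFAULT_GENE_LENGTH + 1,
                             centre + 1, strand)
        genes.append(gene)
        truth_class[gid] = cls

    truth = PlantedTruth(k4_regions, k27_regions, genes, truth_class,
                         enrichment_fold, background_rate)
    _assert_truth_consistent(truth, layout)
    return truth


def _classify_by_overlap(gene: GeneModel, truth: PlantedTruth,
                         layout: GenomeLayout,
                         flank: int = DEFAULT_FLANK) -> str:
    """Brute-force re-derivation of a gene's class from planted regions."""
    from .bivalency import tss_window
    w = tss_window(gene, layout, flank)
    k4 = any(c == w.chrom and _overlaps((s, e), (w.start, w.end))
             for c, s, e in truth.k4_regions)
    k27 = any(c == w.chrom and _overlaps((s, e), (w.start, w.end))
              for c, s, e in truth.k27_regions)
    if k4 and k27:
        return "bivalent"
    if k4:
        return "k4_only"
    if k27:
        return "k27_only"
    return "unmarked"


def _assert_truth_consistent(truth: PlantedTruth, layout: GenomeLayout) -> None:
    for chrom, s, e in truth.k4_regions + truth.k27_regions:
        length = layout.length_of(chrom)
        if not (0 <= s < e <= length):
            raise AssertionError(f"planted region {chrom}:{s}-{e} out of bounds")
    for gene in truth.genes:
        derived = _classify_by_overlap(gene, truth, layout)
        if derived != truth.truth_class[gene.gene_id]:
            raise AssertionError(
                f"{gene.gene_id}: stored class {truth.truth_class[gene.gene_id]}"
                f" != derived {derived}")


def simulate_tags(truth: PlantedTruth, layout: GenomeLayout, mark: str,
                  window: int = 200, seed: int = 0) -> TagCollection:
    """Draw window-level Poisson tag counts and place tags uniformly.

    Window rate is ``background_rate`` outside planted regions of the mark
    and ``background_rate * enrichment_fold`` for windows fully inside one.
    """
    regions = truth.regions_for(mark)
    if truth.background_rate <= 0:
        raise ValueError("background_rate must be positive")
    rng = np.random.default_rng(seed)
    positions: dict[str, np.ndarray] = {}
    for chrom, length in zip(layout.chrom_names, layout.chrom_lengths):
        n_win = -(-length // window)
        rate = np.full(n_win, truth.background_rate)
        for c, s, e in regions:
            if c != chrom:
                continue
            first = -(-s // window)            # first window fully inside
            last = e // window                 # one past last fully inside
            rate[first:last] = truth.background_rate * truth.enrichment_fold
        counts = rng.poisson(rate)
        starts = np.repeat(np.arange(n_win, dtype=np.int64) * window, counts)
        offsets = rng.integers(0, window, size=starts.size)
        pos = np.minimum(starts + offsets, length - 1)
        positions[chrom] = np.sort(pos)
    return TagCollection(mark=mark, positions=positions)


# ---------------------------------------------------------------------------
# expression layer
# ---------------------------------------------------------------------------

DEFAULT_DESIGN = tuple(
    g for g in ("day0", "day2", "day4", "day10", "HSVEC") for _ in range(3))


def simulate_expression(n_probes: int, design: tuple[str, ...] = DEFAULT_DESIGN,
                        n_de: int = 0, lfc: float = 1.0,
                        se_scale: float = 0.05, seed: int = 0,
                        de_group: str = "day2",
                        de_indices: np.ndarray | None = None,
                        ) -> tuple[ExpressionMatrix, pd.Series]:
    """Linear-scale probe x sample intensities with planted fold changes.

    Per-probe baselines are log-normal; per-value standard errors are
    ``se_scale * baseline`` times a scaled-chi draw (4 df, unit mean-square),
    and the observation noise is Gaussian with exactly that standard error,
    so inverse-variance weights are correctly specified.  DE probes are
    multiplied by 2**lfc in ``de_group`` only.  Returns the matrix and a
    boolean truth flag per probe.
    """
    groups = pd.Series(list(design))
    if groups.nunique() < 2:
        raise ValueError("design must contain at least two groups")
    if (groups.value_counts() < 2).any():
        raise ValueError("every group needs >= 2 samples")
    if n_de > n_probes:
        raise ValueError("n_de cannot exceed n_probes")
    rng = np.random.default_rng(seed)
    n_samples = len(design)
    probe_ids = [f"P{i + 1:05d}" for i in range(n_probes)]
    counters: dict[str, int] = {}
    sample_ids = []
    for g in design:
        counters[g] = counters.get(g, 0) + 1
        sample_ids.append(f"{g}_{counters[g]}")

    base = rng.lognormal(mean=np.log(100.0), sigma=0.7, size=n_probes)
    if de_indices is None:
        de_indices = rng.choice(n_probes, size=n_de, replace=False)
    else:
        de_indices = np.asarray(de_indices)
        if de_indices.size != n_de:
            raise ValueError("de_indices length must equal n_de")
    truth = np.zeros(n_probes, dtype=bool)
    truth[de_indices] = True

    mean = np.tile(base[:, None], (1, n_samples))
    in_group = np.array([g == de_group for g in design])
    mean[np.ix_(truth, in_group)] *= 2.0 ** lfc

    chi = np.sqrt(rng.chisquare(4, size=(n_probes, n_samples)) / 4.0)
    ses = se_scale * base[:, None] * chi
    values = mean + rng.normal(size=(n_probes, n_samples)) * ses
    values = np.maximum(values, 1e-6)  # log-normal base keeps this rare

    em = ExpressionMatrix(
        intensities=pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        ses=pd.DataFrame(ses, index=probe_ids, columns=sample_ids),
        groups=pd.Series(list(design), index=sample_ids, name="group"),
    )
    return em, pd.Series(truth, index=probe_ids, name="planted_de")


# ---------------------------------------------------------------------------
# qPCR layer
# ---------------------------------------------------------------------------

def simulate_ct_tables(true_rq: float, ct_ref: float = 25.0,
                       noise_sd: float = 0.0, n_rep: int = 3,
                       seed: int = 0) -> pd.DataFrame:
    """Two-sample Ct table (calibrator + test) for the comparative method.

    The test sample's target Ct is ``ct_ref - log2(true_rq)`` plus Gaussian
    cycle noise; endogenous-control Cts are flat, so at zero noise the
    comparative pipeline recovers ``true_rq`` exactly.
    """
    if true_rq <= 0:
        raise ValueError("true_rq must be positive")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    ct_control = 20.0
    for rep in range(1, n_rep + 1):
        rows.append(("calibrator", "GOI", rep,
                     ct_ref + rng.normal(0, noise_sd) if noise_sd else ct_ref))
        rows.append(("calibrator", "REF", rep, ct_control))
        test_ct = ct_ref - math.log2(true_rq)
        rows.append(("test", "GOI", rep,
                     test_ct + rng.normal(0, noise_sd) if noise_sd else test_ct))
        rows.append(("test", "REF", rep, ct_control))
    return pd.DataFrame(rows, columns=["sample", "target", "replicate", "ct"])


# ---------------------------------------------------------------------------
# bundled demo dataset
# ---------------------------------------------------------------------------

def write_truth_tsv(truth: PlantedTruth, path) -> None:
    rows = [(g.gene_id, g.chrom, g.start, g.end, g.strand,
             truth.truth_class[g.gene_id]) for g in truth.genes]
    pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand",
                                "truth_class"]).to_csv(path, sep="\t",
                                                       index=False)


def make_demo_dataset(outdir: str | Path, seed: int = 0,
                      n_probes: int = 300, n_de: int = 30,
                      lfc: float = 1.0) -> dict[str, Path]:
    """Write a coherent synthetic study to ``outdir`` and return its paths.

    The first probes map one-to-one onto the planted genes, the planted DE
    probes include every bivalent gene's probe, and the transcription-factor
    list contains the bivalent genes plus one k4_only gene — so the
    end-to-end report must surface planted DE + bivalent TF genes with their
    planted direction and score.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = make_genome(2, 500_000, seed)
    truth = plant_truth(layout, seed=seed)
    paths: dict[str, Path] = {}

    paths["genome"] = outdir / "genome.tsv"
    pd.DataFrame({"chrom": layout.chrom_names,
                  "length": layout.chrom_lengths}).to_csv(
        paths["genome"], sep="\t", header=False, index=False)

    for mark, key in (("H3K4me3", "k4_tags"), ("H3K27me3", "k27_tags")):
        tags = simulate_tags(truth, layout, mark, seed=seed + (1 if key == "k4_tags" else 2))
        paths[key] = outdir / f"{mark}.tags.bed"
        write_tags_bed(tags, paths[key])

    paths["genes"] = outdir / "genes.bed"
    write_genes_bed(truth.genes, paths["genes"])
    paths["truth"] = outdir / "truth.tsv"
    write_truth_tsv(truth, paths["truth"])

    # expression matrix: probe i <-> gene i for the first len(genes) probes
    gene_ids = [g.gene_id for g in truth.genes]
    probe_of_gene = {gid: f"P{i + 1:05d}" for i, gid in enumerate(gene_ids)}
    bivalent_idx = [i for i, g in enumerate(truth.genes)
                    if truth.truth_class[g.gene_id] == "bivalent"]
    rng = np.random.default_rng(seed + 17)
    extra = rng.choice(np.arange(len(gene_ids), n_probes),
                       size=n_de - len(bivalent_idx), replace=False)
    de_indices = np.concatenate([np.array(bivalent_idx, dtype=int), extra])
    em, de_truth = simulate_expression(n_probes, n_de=n_de, lfc=lfc,
                                       seed=seed + 3, de_indices=de_indices)
    paths["expression"] = outdir / "expression.tsv"
    em.to_tsv(paths["expression"])
    paths["samples"] = outdir / "samples.tsv"
    em.groups.rename_axis("sample").reset_index().to_csv(
        paths["samples"], sep="\t", index=False)
    paths["de_truth"] = outdir / "de_truth.tsv"
    de_truth.rename_axis("probe_id").reset_index().to_csv(
        paths["de_truth"], sep="\t", index=False)

    paths["probe_map"] = outdir / "probe_gene_map.tsv"
    pd.DataFrame({"probe_id": [probe_of_gene[g] for g in gene_ids],
                  "gene_symbol": gene_ids}).to_csv(
        paths["probe_map"], sep="\t", index=False)

    tf_genes = [g for g in gene_ids if truth.truth_class[g] == "bivalent"]
    k4_only = [g for g in gene_ids if truth.truth_class[g] == "k4_only"]
    if k4_only:
        tf_genes.append(k4_only[0])
    paths["tf_list"] = outdir / "tf_list.txt"
    Path(paths["tf_list"]).write_text("\n".join(sorted(tf_genes)) + "\n")

    paths["ct_table"] = outdir / "ct_table.tsv"
    simulate_ct_tables(true_rq=2.0, noise_sd=0.1, seed=seed + 5).to_csv(
        paths["ct_table"], sep="\t", index=False)
    return paths
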