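"""Promoter bivalency scoring across island-caller gap sizes.

A gene's promoter window is the closed +/-2 kb interval around its
transcription start site (TSS), held as the 0-based half-open interval
[TSS - flank, TSS + flank + 1).  At a given gap size a gene is *bivalent*
when that window intersects (by at least one base) an enriched domain of
both the activating H3K4me3 mark and the repressive H3K27me3 mark.  The
bivalency score counts, over the five gap sizes at which domains were
called, how often the gene was classified bivalent: 0 means never, 5 means
bivalent regardless of the gap size chosen.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domains import (CallerParams, DomainSet, GenomeLayout, TagCollection,
                      DEFAULT_GAPS, call_domains)

logger = logging.getLogger("bivalscore")

DEFAULT_FLANK = 2000


@dataclass(frozen=True)
class GeneModel:
    """A gene-level model: one interval, one strand, one TSS."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")


@dataclass(frozen=True)
class TssWindow:
    gene_id: str
    chrom: str
    start: int
    end: int  # half-open


@dataclass
class BivalencyRecord:
    """Per-gap bivalent flags and the resulting 0-5 score for one gene."""

    gene_id: str
    flags: dict[int, bool]

    @property
    def score(self) -> int:
        return int(sum(self.flags.values()))


def tss_position(gene: GeneModel) -> int:
    """5'-most transcribed base: start on +, end - 1 on - (0-based)."""
    return gene.start if gene.strand == "+" else gene.end - 1


def tss_window(gene: GeneModel, layout: GenomeLayout,
               flank: int = DEFAULT_FLANK) -> TssWindow:
    """Closed symmetric +/-flank interval around the TSS, clamped to the
    chromosome; spans flank*2 + 1 bases when unclamped."""
    if flank < 0:
        raise ValueError("flank must be non-negative")
    tss = tss_position(gene)
    length = layout.length_of(gene.chrom)
    if not (0 <= tss < length):
        raise ValueError(f"{gene.gene_id}: TSS {tss} outside chromosome")
    return TssWindow(gene.gene_id, gene.chrom,
                     max(0, tss - flank), min(length, tss + flank + 1))


def interval_overlaps_any(window: TssWindow, domains: DomainSet) -> bool:
    """True iff the window shares >= 1 bp with any domain (half-open:
    touching endpoints do not overlap)."""
    return domains.overlaps(window.chrom, window.start, window.end)


def bivalent_at_gap(window: TssWindow, k4: DomainSet, k27: DomainSet) -> bool:
    """Bivalent iff the window overlaps an enriched domain of each mark."""
    if k4.gap != k27.gap:
        raise ValueError(f"gap mismatch: {k4.gap} vs {k27.gap}")
    return interval_overlaps_any(window, k4) and interval_overlaps_any(window, k27)


def bivalency_score(gene: GeneModel, k4_sets: dict[int, DomainSet],
                    k27_sets: dict[int, DomainSet], layout: GenomeLayout,
                    flank: int = DEFAULT_FLANK) -> BivalencyRecord:
    """Count the gap sizes at which the gene is bivalent."""
    if set(k4_sets) != set(k27_sets):
        raise ValueError("the two marks cover different gap-size collections")
    window = tss_window(gene, layout, flank)
    flags = {g: bivalent_at_gap(window, k4_sets[g], k27_sets[g])
             for g in sorted(k4_sets)}
    return BivalencyRecord(gene.gene_id, flags)


def _derive_seed(base: int, mark: str, gap: int) -> int:
    """Deterministic per-(mark, gap) calibration seed, kept below 2^31."""
    return (base * 100003 + gap * 13 + (7 if mark == "H3K4me3" else 11)) % (2**31)


def call_domains_all_gaps(tags: TagCollection, layout: GenomeLayout,
                          params: CallerParams,
                          gaps: tuple[int, ...] = DEFAULT_GAPS,
                          ) -> dict[int, DomainSet]:
    """Run the caller once per gap size; each gap gets its own calibration."""
    out = {}
    for g in gaps:
        p = CallerParams(w=params.w, g=g, E=params.E, p0=params.p0,
                         shift=params.shift,
                         effective_fraction=params.effective_fraction,
                         mc_reps=params.mc_reps,
                         seed=_derive_seed(params.seed, tags.mark, g))
        out[g] = call_domains(tags, layout, p)
    return out


def score_all_genes(genes: list[GeneModel], k4_tags: TagCollection,
                    k27_tags: TagCollection, layout: GenomeLayout,
                    params: CallerParams | None = None,
                    gaps: tuple[int, ...] = DEFAULT_GAPS,
                    flank: int = DEFAULT_FLANK) -> pd.DataFrame:
    """Full in-silico bivalency prediction: call both marks at every gap
    size, then score every gene.

    Returns one row per input gene with columns ``gene_id``,
    ``flag_g<gap>`` per gap, and ``bivalency_score``.
    """
    if k4_tags.total_tags == 0 or k27_tags.total_tags == 0:
        raise ValueError("both tag collections must be non-empty")
    params = params or CallerParams()
    k4_sets = call_domains_all_gaps(k4_tags, layout, params, gaps)
    k27_sets = call_domains_all_gaps(k27_tags, layout, params, gaps)
    rows = []
    for gene in genes:
        rec = bivalency_score(gene, k4_sets, k27_sets, layout, flank)
        row = {"gene_id": gene.gene_id}
        row.update({f"flag_g{g}": rec.flags[g] for g in sorted(rec.flags)})
        row["bivalency_score"] = rec.score
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene model input / output
# ---------------------------------------------------------------------------

def read_genes_bed(path) -> list[GeneModel]:
    """BED6 gene models; the name column is the gene id."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score", "strand"],
                     usecols=[0, 1, 2, 3, 4, 5])
    return [GeneModel(str(r.name), str(r.chrom), int(r.start), int(r.end),
                      str(r.strand))
            for r in df.itertuples(index=False)]


_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


def read_genes_gtf(path) -> list[GeneModel]:
    """Minimal GTF reader: gene features, 1-based closed coordinates
    converted to 0-based half-open, gene_id from the attribute column.

    Genes with multiple annotated feature lines collapse to the 5'-most
    start on the coding strand (a warning is logged).
    """
    by_id: dict[str, GeneModel] = {}
    multi = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in ("gene", "transcript"):
                continue
            m = _GENE_ID_RE.search(f[8])
            if not m:
                continue
            gid = m.group(1)
            gene = GeneModel(gid, f[0], int(f[3]) - 1, int(f[4]), f[6])
            if gid in by_id:
                multi.add(gid)
                prev = by_id[gid]
                start = min(prev.start, gene.start)
                end = max(prev.end, gene.end)
                by_id[gid] = GeneModel(gid, gene.chrom, start, end, gene.strand)
            else:
                by_id[gid] = gene
    if multi:
        logger.warning("%d genes had multiple annotated starts; using the "
                       "5'-most on the coding strand", len(multi))
    return list(by_id.values())


def write_genes_bed(genes: list[GeneModel], path) -> None:
    rows = [(g.chrom, g.start, g.end, g.gene_id, 0, g.strand) for g in genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_tss_windows_bed(genes: list[GeneModel], layout: GenomeLayout,
                          path, flank: int = DEFAULT_FLANK) -> None:
    rows = []
    for g in genes:
        w = tss_window(g, layout, flank)
        rows.append((w.chrom, w.start, w.end, g.gene_id, 0, g.strand))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
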