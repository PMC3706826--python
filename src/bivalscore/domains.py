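"""Enriched-domain ("island") calling for histone-mark ChIP-seq tags.

The caller partitions each chromosome into fixed non-overlapping windows
(default 200 bp), counts tags per window, and models the background as a
genome-wide Poisson rate

    lambda = total_tags * w / (genome_length * effective_fraction)

tags per window.  Windows whose count k satisfies P(X >= k | lambda) < p0
are *eligible*; maximal runs of eligible windows, in which internal runs of
ineligible windows no longer than ``gap`` base pairs are bridged, form
candidate islands.  Each island is scored

    score = sum over eligible windows of -ln P(X = k_i | lambda)

and islands survive if their score reaches a threshold calibrated by Monte
Carlo simulation of pure Poisson background so that the expected number of
surviving background islands genome-wide is at most the E-value (default
0.1).  Domains are reported per mark and per gap size; re-calling at the
five conventional gap sizes (200..1000 bp) feeds the promoter bivalency
score downstream.

The calibration is Monte-Carlo rather than analytic: it is transparent,
seedable, and testable by re-simulation, at the cost of a small calibration
variance controlled by ``mc_reps``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger("bivalscore")

# Caller defaults: 200-bp windows, the five conventional gap sizes, a
# stringent genome-wide E-value of 0.1 and window eligibility at p0 = 0.2.
DEFAULT_WINDOW = 200
DEFAULT_GAPS = (200, 400, 600, 800, 1000)
DEFAULT_EVALUE = 0.1
DEFAULT_P0 = 0.2
DEFAULT_MC_REPS = 100
#: mappable fraction of the human genome; synthetic genomes use 1.0
HUMAN_EFFECTIVE_FRACTION = 0.74

MARKS = ("H3K4me3", "H3K27me3")


# ---------------------------------------------------------------------------
# genome layout and tag containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names/lengths plus the effective (mappable) fraction."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    effective_fraction: float = 1.0

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if not (0 < self.effective_fraction <= 1):
            raise ValueError("effective_fraction must lie in (0, 1]")

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        return self.chrom_lengths[self.chrom_names.index(chrom)]

    def n_windows(self, w: int) -> int:
        """Total number of w-bp windows genome-wide (last window may be short)."""
        return int(sum(-(-l // w) for l in self.chrom_lengths))


def read_genome_tsv(path: str | Path, effective_fraction: float = 1.0) -> GenomeLayout:
    """Read a two-column chrom/length table (chrom.sizes style, no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return GenomeLayout(tuple(df["chrom"].astype(str)),
                        tuple(int(x) for x in df["length"]),
                        effective_fraction)


@dataclass
class TagCollection:
    """Per-chromosome sorted tag positions (0-based) for one histone mark.

    ``strands`` holds +1/-1 per tag and is only consulted when a non-zero
    read-to-tag shift is applied; simulated tags are emitted directly at the
    counted location with strand +1.
    """

    mark: str
    positions: dict[str, np.ndarray]
    strands: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if np.any(np.diff(pos) < 0):
                order = np.argsort(pos, kind="stable")
                pos = pos[order]
                if self.strands is not None:
                    self.strands[chrom] = np.asarray(self.strands[chrom])[order]
            self.positions[chrom] = pos

    @property
    def total_tags(self) -> int:
        return int(sum(p.size for p in self.positions.values()))


@dataclass
class WindowCounts:
    """Tags per fixed-width window, one count vector per chromosome."""

    window_size: int
    counts: dict[str, np.ndarray]

    @property
    def total(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))


@dataclass
class CallerParams:
    """Tunable parameters of the island caller (see module docstring)."""

    w: int = DEFAULT_WINDOW
    g: int = 600
    E: float = DEFAULT_EVALUE
    p0: float = DEFAULT_P0
    shift: int = 0
    effective_fraction: float = 1.0
    mc_reps: int = DEFAULT_MC_REPS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("window size must be positive")
        if self.g % self.w != 0:
            raise ValueError("gap must be a multiple of the window size")
        if self.E <= 0:
            raise ValueError("E-value must be positive")
        if not (0 < self.p0 < 1):
            raise ValueError("p0 must lie in (0, 1)")
        if self.mc_reps < 1:
            raise ValueError("mc_reps must be >= 1")


@dataclass
class DomainSet:
    """Called enriched domains for one mark at one gap size.

    ``domains`` is a list of (chrom, start, end, island_score) with 0-based
    half-open intervals, window-aligned, sorted and non-overlapping within
    each chromosome.
    """

    mark: str
    gap: int
    domains: list[tuple[str, int, int, float]]
    background_rate: float
    k_min: int = 0
    s_thr: float = 0.0
    params: CallerParams | None = None
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def tree(self, chrom: str) -> IntervalTree:
        if chrom not in self._trees:
            self._trees[chrom] = IntervalTree.from_tuples(
                (s, e) for c, s, e, _ in self.domains if c == chrom and e > s
            )
        return self._trees[chrom]

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) intersects any domain by >= 1 bp."""
        return bool(self.tree(chrom).overlap(start, end))

    def __len__(self) -> int:
        return len(self.domains)


# ---------------------------------------------------------------------------
# statistical kernel
# ---------------------------------------------------------------------------

def poisson_tail(k: int, lam: float) -> float:
    """Upper tail P(X >= k) for X ~ Poisson(lam), stable in log space."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if k == 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def eligibility_threshold(lam: float, p0: float) -> int:
    """Smallest count k with P(X >= k | lam) < p0 (always >= 1)."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if not (0 < p0 < 1):
        raise ValueError("p0 must lie in (0, 1)")
    k = 1
    while poisson_tail(k, lam) >= p0:
        k += 1
    return k


def count_window_tags(tags: TagCollection, layout: GenomeLayout, w: int,
                      shift: int = 0) -> WindowCounts:
    """Assign each tag to window floor((pos + strand*shift) / w).

    Shifted positions are clamped to the chromosome, so tag count is
    conserved exactly.
    """
    if w <= 0:
        raise ValueError("window size must be positive")
    if not layout.chrom_names:
        raise ValueError("empty genome layout")
    counts: dict[str, np.ndarray] = {}
    for chrom, length in zip(layout.chrom_names, layout.chrom_lengths):
        n_win = -(-length // w)
        pos = tags.positions.get(chrom, np.empty(0, dtype=np.int64))
        if shift != 0 and pos.size:
            if tags.strands is not None and chrom in tags.strands:
                sgn = np.asarray(tags.strands[chrom], dtype=np.int64)
            else:
                sgn = np.ones(pos.size, dtype=np.int64)
            pos = np.clip(pos + shift * sgn, 0, length - 1)
        idx = pos // w
        counts[chrom] = np.bincount(idx, minlength=n_win).astype(np.int64)
    return WindowCounts(window_size=w, counts=counts)


# ---------------------------------------------------------------------------
# island formation and scoring
# ---------------------------------------------------------------------------

def link_islands(eligible_mask: np.ndarray, g: int, w: int) -> list[tuple[int, int]]:
    """Maximal runs of eligible windows bridging ineligible gaps <= g bp.

    Returns half-open window-index ranges; each island begins and ends on an
    eligible window.
    """
    if g % w != 0:
        raise ValueError("gap must be a multiple of the window size")
    mask = np.asarray(eligible_mask, dtype=bool)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    max_bridge = g // w
    breaks = np.flatnonzero(np.diff(idx) > max_bridge + 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e]) + 1) for s, e in zip(starts, ends)]


def island_score(counts_in_island: np.ndarray, eligible_mask: np.ndarray,
                 lam: float) -> float:
    """Sum of -ln P(X = k_i | lam) over eligible windows; bridged windows add 0."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    counts = np.asarray(counts_in_island)
    mask = np.asarray(eligible_mask, dtype=bool)
    if not mask.any():
        return 0.0
    return float(np.sum(-stats.poisson.logpmf(counts[mask], lam)))


def _island_scores(counts: np.ndarray, mask: np.ndarray, g: int, w: int,
                   lam: float) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Vectorised islands + scores for one chromosome-length count vector.

    Uses a per-count -logpmf lookup table and a cumulative sum so that all
    island scores come from two array operations; equals per-island
    ``island_score`` exactly.
    """
    islands = link_islands(mask, g, w)
    if not islands:
        return [], np.empty(0)
    table = -stats.poisson.logpmf(np.arange(int(counts.max()) + 1), lam)
    contrib = np.where(mask, table[counts], 0.0)
    cs = np.concatenate(([0.0], np.cumsum(contrib)))
    scores = np.array([cs[b] - cs[a] for a, b in islands])
    return islands, scores


def calibrate_score_threshold(lam: float, n_windows: int, g: int, w: int,
                              p0: float, E: float, mc_reps: int,
                              seed: int) -> float:
    """Monte-Carlo island-score threshold for an expected background count E.

    Simulates ``mc_reps`` pure-Poisson window fields of ``n_windows``, forms
    candidate islands, and returns the smallest score s such that the mean
    number of background islands scoring >= s is <= E.  Returns 0.0 when E is
    so large that no filtering is needed.  Deterministic for a fixed seed and
    non-increasing in E.
    """
    k_min = eligibility_threshold(lam, p0)
    rng = np.random.default_rng(seed)
    all_scores: list[np.ndarray] = []
    for _ in range(mc_reps):
        counts = rng.poisson(lam, n_windows)
        mask = counts >= k_min
        _, scores = _island_scores(counts, mask, g, w, lam)
        if scores.size:
            all_scores.append(scores)
    scores = (np.sort(np.concatenate(all_scores))[::-1]
              if all_scores else np.empty(0))
    allowed = int(np.floor(E * mc_reps))
    if scores.size <= allowed:
        return 0.0
    # smallest s with (#background scores >= s) / mc_reps <= E
    return float(np.nextafter(scores[allowed], np.inf))


def call_domains(tags: TagCollection, layout: GenomeLayout,
                 params: CallerParams) -> DomainSet:
    """Full caller: count -> eligibility -> link -> score -> threshold."""
    if tags.total_tags == 0:
        raise ValueError("empty tag collection")
    w, g = params.w, params.g
    lam = tags.total_tags * w / (layout.total_length * params.effective_fraction)
    if lam <= 0:
        raise ValueError("background rate is zero")
    k_min = eligibility_threshold(lam, params.p0)
    s_thr = calibrate_score_threshold(
        lam, layout.n_windows(w), g, w, params.p0, params.E,
        params.mc_reps, params.seed)
    window_counts = count_window_tags(tags, layout, w, params.shift)
    domains: list[tuple[str, int, int, float]] = []
    for chrom, length in zip(layout.chrom_names, layout.chrom_lengths):
        counts = window_counts.counts[chrom]
        mask = counts >= k_min
        islands, scores = _island_scores(counts, mask, g, w, lam)
        for (a, b), s in zip(islands, scores):
            if s >= s_thr:
                domains.append((chrom, a * w, min(b * w, length), float(s)))
    logger.debug("call_domains mark=%s g=%d lambda=%.4g k_min=%d s_thr=%.3f "
                 "-> %d domains", tags.mark, g, lam, k_min, s_thr, len(domains))
    return DomainSet(mark=tags.mark, gap=g, domains=domains,
                     background_rate=lam, k_min=k_min, s_thr=s_thr,
                     params=params)


# ---------------------------------------------------------------------------
# BED input / output
# ---------------------------------------------------------------------------

def read_tags_bed(path: str | Path, mark: str) -> TagCollection:
    """Read tags from BED6 (gzip accepted); position = strand-aware 5' end."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score", "strand"],
                     usecols=[0, 1, 2, 3, 4, 5])
    positions: dict[str, np.ndarray] = {}
    strands: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sgn = np.where(sub["strand"].to_numpy() == "-", -1, 1)
        pos = np.where(sgn == 1, sub["start"].to_numpy(),
                       sub["end"].to_numpy() - 1).astype(np.int64)
        order = np.argsort(pos, kind="stable")
        positions[str(chrom)] = pos[order]
        strands[str(chrom)] = sgn[order]
    return TagCollection(mark=mark, positions=positions, strands=strands)


def write_tags_bed(tags: TagCollection, path: str | Path) -> None:
    rows = []
    for chrom, pos in tags.positions.items():
        sgn = (tags.strands or {}).get(chrom, np.ones(pos.size, dtype=int))
        for i, (p, s) in enumerate(zip(pos, sgn)):
            rows.append((chrom, int(p), int(p) + 1, f"tag_{chrom}_{i}", 0,
                         "+" if s >= 0 else "-"))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_domains_bed(domain_set: DomainSet, path: str | Path,
                      sidecar: bool = True) -> None:
    """Write domains as BED (name=island_k, score=island score) + JSON sidecar."""
    path = Path(path)
    rows = [(c, s, e, f"island_{i}", f"{score:.4f}", ".")
            for i, (c, s, e, score) in enumerate(domain_set.domains)]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
    if sidecar:
        meta = {
            "mark": domain_set.mark,
            "gap": domain_set.gap,
            "background_rate": domain_set.background_rate,
            "k_min": domain_set.k_min,
            "s_thr": domain_set.s_thr,
            "n_domains": len(domain_set),
            "params": asdict(domain_set.params) if domain_set.params else None,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2))


def read_domains_bed(path: str | Path, mark: str, gap: int) -> DomainSet:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"])
    domains = [(str(r.chrom), int(r.start), int(r.end), float(r.score))
               for r in df.itertuples()]
    return DomainSet(mark=mark, gap=gap, domains=domains, background_rate=0.0)
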