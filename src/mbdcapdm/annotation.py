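"""Promoter and background-region annotation.

Promoters are TSS +/- 2 kb windows from a refFlat gene table (one record
per distinct TSS). Background regions measure the non-specific pull-down
noise of MBD capture: the genome is tiled into 100 bp windows and, per
promoter, a small set of nearby windows that cannot carry methylation
signal is selected in three stages:

1. Filtering  - drop windows overlapping any promoter, CpG island or
   assembly gap, and windows containing ambiguous bases;
2. Construction - among the survivors with GC fraction < 40%, keep the
   80 windows closest to the TSS;
3. Finalization - of those, keep the 40 with the lowest mean TPM so the
   final set is depleted of residual signal.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomeLayout",
    "Promoter",
    "Window",
    "BackgroundAnnotation",
    "load_refflat",
    "load_bed_intervals",
    "load_chrom_sizes",
    "tile_genome",
    "filter_windows",
    "construct_candidates",
    "compute_tpm",
    "finalize_background",
    "build_background",
]

logger = logging.getLogger(__name__)

PROMOTER_FLANK = 2000  # bp each side of the TSS
WINDOW_SIZE = 100  # bp tiling resolution
GC_CUTOFF = 0.40  # candidate windows must be below this GC fraction
N_CANDIDATES = 80
N_FINAL = 40


@dataclass
class GenomeLayout:
    """Chromosome sizes plus optional gap / CpG-island interval sets."""

    chrom_sizes: dict[str, int]
    gaps: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    cpg_islands: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, ivs in list(self.gaps.items()) + list(self.cpg_islands.items()):
            size = self.chrom_sizes.get(name)
            for start, end in ivs:
                if start < 0 or (size is not None and end > size):
                    raise ValueError(
                        f"interval {name}:{start}-{end} outside chromosome bounds"
                    )


@dataclass(frozen=True)
class Promoter:
    gene: str
    chrom: str
    strand: str
    tss: int
    start: int
    end: int
    clipped: bool = False

    @property
    def id(self) -> str:
        return self.gene


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int
    end: int
    gc_fraction: float = float("nan")
    has_ambiguous_base: bool = False

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class BackgroundAnnotation:
    """Per-promoter finalized background windows plus audit trail."""

    windows: dict[str, list[Window]]  # promoter id -> <=40 finalized windows
    candidates: dict[str, list[Window]]  # promoter id -> <=80 stage-2 windows
    flags: dict[str, list[str]] = field(default_factory=dict)

    @property
    def no_background(self) -> set[str]:
        return {
            pid for pid, flg in self.flags.items() if "no_background" in flg
        }

    def window_ids(self, promoter_id: str) -> list[str]:
        return [w.id for w in self.windows[promoter_id]]


# ---------------------------------------------------------------------------
# input formats


def load_chrom_sizes(path) -> dict[str, int]:
    """Two-column chrom.sizes text file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, size = line.split()[:2]
            sizes[name] = int(size)
    return sizes


def load_bed_intervals(path) -> dict[str, list[tuple[int, int]]]:
    """BED3(+) file into a chrom -> [(start, end)] mapping."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            out.setdefault(chrom, []).append((start, end))
    for ivs in out.values():
        ivs.sort()
    return out


def load_refflat(path, layout: GenomeLayout | None = None) -> list[Promoter]:
    """Parse a UCSC refFlat table into deduplicated TSS +/- 2 kb promoters.

    The TSS is ``txStart`` on the + strand and ``txEnd - 1`` on the -
    strand (refFlat coordinates are 0-based half-open). Transcripts that
    share a TSS collapse to a single promoter; malformed rows are
    skipped with a logged line number. Promoter intervals are clipped at
    chromosome ends (when sizes are known) and flagged rather than
    dropped.
    """
    seen: dict[tuple[str, int], Promoter] = {}
    name_counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                logger.warning("refFlat line %d malformed; skipped", lineno)
                continue
            gene, _tx, chrom, strand = parts[0], parts[1], parts[2], parts[3]
            try:
                tx_start, tx_end = int(parts[4]), int(parts[5])
            except ValueError:
                logger.warning("refFlat line %d malformed; skipped", lineno)
                continue
            if strand not in "+-":
                logger.warning("refFlat line %d bad strand; skipped", lineno)
                continue
            tss = tx_start if strand == "+" else tx_end - 1
            key = (chrom, tss)
            if key in seen:
                continue
            start = tss - PROMOTER_FLANK
            end = tss + PROMOTER_FLANK
            clipped = False
            if start < 0:
                start, clipped = 0, True
            if layout is not None and chrom in layout.chrom_sizes:
                size = layout.chrom_sizes[chrom]
                if end > size:
                    end, clipped = size, True
            # keep gene symbol as the id; disambiguate repeated symbols
            n = name_counts.get(gene, 0)
            name_counts[gene] = n + 1
            pid = gene if n == 0 else f"{gene}:{chrom}:{tss}"
            seen[key] = Promoter(pid, chrom, strand, tss, start, end, clipped)
    promoters = list(seen.values())
    logger.info("loaded %d promoters from %s", len(promoters), path)
    return promoters


# ---------------------------------------------------------------------------
# tiling and filtering


def _gc_and_ambiguous(seq: str) -> tuple[float, bool]:
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    gc = sum(s.count(b) for b in "GC")
    ambiguous = acgt < len(s)
    frac = gc / acgt if acgt else float("nan")
    return frac, ambiguous


def tile_genome(
    layout: GenomeLayout,
    sequences: dict[str, str] | None = None,
    window_size: int = WINDOW_SIZE,
):
    """Yield non-overlapping windows on the fixed tiling grid.

    Windows start at position 0 of each chromosome; a trailing partial
    window is dropped. When ``sequences`` is given, the GC fraction and
    ambiguous-base flag are computed from the sequence.
    """
    for chrom, size in layout.chrom_sizes.items():
        seq = sequences.get(chrom) if sequences else None
        for start in range(0, size - window_size + 1, window_size):
            end = start + window_size
            if seq is not None:
                gc, amb = _gc_and_ambiguous(seq[start:end])
            else:
                gc, amb = float("nan"), False
            yield Window(chrom, start, end, gc, amb)


def _exclusion_trees(
    promoters: list[Promoter],
    cpg_islands: dict[str, list[tuple[int, int]]] | None,
    gaps: dict[str, list[tuple[int, int]]] | None,
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}

    def add(chrom: str, start: int, end: int) -> None:
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)

    for p in promoters:
        add(p.chrom, p.start, p.end)
    for src in (cpg_islands, gaps):
        if src:
            for chrom, ivs in src.items():
                for start, end in ivs:
                    add(chrom, start, end)
    return trees


def filter_windows(
    windows,
    promoters: list[Promoter],
    cpg_islands: dict[str, list[tuple[int, int]]] | None = None,
    gaps: dict[str, list[tuple[int, int]]] | None = None,
) -> list[Window]:
    """Filtering step: any >=1 bp overlap with a promoter, CpG island or
    gap excludes a window, as does an ambiguous base in its sequence."""
    trees = _exclusion_trees(promoters, cpg_islands, gaps)
    eligible = []
    for w in windows:
        if w.has_ambiguous_base:
            continue
        tree = trees.get(w.chrom)
        if tree is not None and tree.overlaps(w.start, w.end):
            continue
        eligible.append(w)
    return eligible


def construct_candidates(
    promoter: Promoter,
    eligible_windows: list[Window],
    n_candidates: int = N_CANDIDATES,
    gc_cutoff: float = GC_CUTOFF,
) -> tuple[list[Window], list[str]]:
    """Construction step: the ``n_candidates`` low-GC windows closest to
    the TSS (midpoint distance; ties broken by lower coordinate).

    Returns the candidate list and any flags ("short_candidates" when
    fewer than requested exist, "no_background" when none do).
    """
    flags: list[str] = []
    pool = [
        w
        for w in eligible_windows
        if w.chrom == promoter.chrom
        and np.isfinite(w.gc_fraction)
        and w.gc_fraction < gc_cutoff
    ]
    if not pool:
        return [], ["no_background"]
    pool.sort(key=lambda w: (abs(w.midpoint - promoter.tss), w.start))
    if len(pool) < n_candidates:
        flags.append("short_candidates")
    return pool[:n_candidates], flags


def compute_tpm(
    counts, read_length: float, fragment_length: float = 100.0
) -> np.ndarray:
    """Transcripts-per-million-style normalization of window counts.

    TPM_g = (r_g * r_l * 1e6) / (fl_g * sum_G r_g * r_l / fl_g), where
    r_g is the read count of window g, r_l the read length and fl_g the
    fragment length (100 bp windows here). Values over the normalizing
    set sum to 1e6. ``counts`` may be 1-D (one sample) or 2-D
    (windows x samples, normalized per column).
    """
    arr = np.asarray(counts, dtype=float)
    if np.all(arr == 0):
        raise ValueError("cannot compute TPM: all window counts are zero")
    rate = arr * read_length / fragment_length
    denom = rate.sum(axis=0)
    return np.asarray(rate * 1e6 / denom)


def finalize_background(
    promoter: Promoter,
    candidates: list[Window],
    tpm: dict[str, float] | pd.Series,
    n_final: int = N_FINAL,
) -> tuple[list[Window], list[str]]:
    """Finalization step: the ``n_final`` candidates with the lowest mean
    TPM (ties by TSS proximity, then coordinate)."""
    flags: list[str] = []
    if not candidates:
        return [], ["no_background"]
    ordered = sorted(
        candidates,
        key=lambda w: (tpm[w.id], abs(w.midpoint - promoter.tss), w.start),
    )
    if len(ordered) < n_final:
        flags.append("short_final")
    return ordered[:n_final], flags


def build_background(
    layout: GenomeLayout,
    promoters: list[Promoter],
    window_counts: pd.DataFrame,
    read_length: float,
    sequences: dict[str, str] | None = None,
    windows: list[Window] | None = None,
) -> BackgroundAnnotation:
    """Run the full filter/construct/finalize pipeline for all promoters.

    ``window_counts`` is a windows x samples frame indexed by window id;
    the mean TPM across the provided samples drives finalization.
    """
    if windows is None:
        windows = list(tile_genome(layout, sequences))
    eligible = filter_windows(windows, promoters, layout.cpg_islands, layout.gaps)
    eligible_ids = [w.id for w in eligible if w.id in window_counts.index]
    id_set = set(eligible_ids)
    eligible = [w for w in eligible if w.id in id_set]
    if not eligible:
        raise ValueError("no eligible windows with counts available")
    tpm = compute_tpm(window_counts.loc[eligible_ids].to_numpy(), read_length)
    tpm_mean = pd.Series(np.atleast_2d(tpm.T).mean(axis=0), index=eligible_ids)

    by_chrom: dict[str, list[Window]] = {}
    for w in eligible:
        by_chrom.setdefault(w.chrom, []).append(w)

    final: dict[str, list[Window]] = {}
    cand: dict[str, list[Window]] = {}
    flags: dict[str, list[str]] = {}
    for p in promoters:
        c, f1 = construct_candidates(p, by_chrom.get(p.chrom, []))
        w, f2 = finalize_background(p, c, tpm_mean)
        cand[p.id] = c
        final[p.id] = w
        flg = sorted(set(f1) | set(f2))
        if flg:
            flags[p.id] = flg
    return BackgroundAnnotation(final, cand, flags)
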