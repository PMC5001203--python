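"""Read counting over promoter / background intervals and count matrices.

Reads arrive as BED6 records of mapped positions; a read is assigned to
an interval iff its 5' end (strand-aware) lies inside it, so a read is
counted at most once per annotation set even where 100 bp windows tile
contiguously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import BackgroundAnnotation

__all__ = [
    "CountMatrix",
    "read_bed_reads",
    "count_reads",
    "background_counts_per_promoter",
    "size_factors",
]

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Non-negative integer counts, rows = features, columns = samples."""

    data: pd.DataFrame
    conditions: pd.Series  # sample id -> condition label

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("row and sample ids must be unique")
        self.conditions = pd.Series(self.conditions)
        missing = [s for s in self.data.columns if s not in self.conditions.index]
        if missing:
            raise ValueError(f"samples without condition labels: {missing}")
        self.conditions = self.conditions.loc[self.data.columns]

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def condition_samples(self, label: str) -> list[str]:
        return list(self.conditions.index[self.conditions == label])

    def to_tsv(self, counts_path, conditions_path=None) -> None:
        self.data.to_csv(counts_path, sep="\t", index_label="id")
        if conditions_path is not None:
            self.conditions.rename("condition").to_csv(
                conditions_path, sep="\t", index_label="sample"
            )

    @classmethod
    def from_tsv(cls, counts_path, conditions_path) -> "CountMatrix":
        data = pd.read_csv(counts_path, sep="\t", index_col=0)
        cond = pd.read_csv(conditions_path, sep="\t", index_col=0)["condition"]
        return cls(data, cond)


def read_bed_reads(path):
    """Yield (chrom, five_prime_position) for each BED6 read record.

    The 5' end is ``start`` for + strand reads and ``end - 1`` for -
    strand; records without a strand column are treated as + strand.
    """
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            strand = parts[5] if len(parts) > 5 else "+"
            yield chrom, (start if strand != "-" else end - 1)


def count_reads(reads, intervals) -> pd.Series:
    """Count reads per interval under the 5'-end assignment rule.

    Parameters
    ----------
    reads
        Iterable of ``(chrom, five_prime_position)`` pairs (see
        :func:`read_bed_reads`) or a path to a BED file.
    intervals
        Iterable of ``(chrom, start, end, id)`` tuples; intervals must
        be non-overlapping within the set.

    Reads on chromosomes absent from the interval set are skipped and
    tallied in a log summary.
    """
    if isinstance(reads, (str, Path)):
        reads = read_bed_reads(reads)
    intervals = list(intervals)
    ids = [iv[3] for iv in intervals]
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for row, (chrom, start, end, _id) in enumerate(intervals):
        by_chrom.setdefault(chrom, []).append((start, end, row))
    index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = np.array([i[0] for i in ivs])
        ends = np.array([i[1] for i in ivs])
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping intervals on {chrom}")
        index[chrom] = (starts, ends, np.array([i[2] for i in ivs]))

    counts = np.zeros(len(intervals), dtype=np.int64)
    skipped = 0
    for chrom, pos in reads:
        idx = index.get(chrom)
        if idx is None:
            skipped += 1
            continue
        starts, ends, rows = idx
        k = np.searchsorted(starts, pos, side="right") - 1
        if k >= 0 and pos < ends[k]:
            counts[rows[k]] += 1
    if skipped:
        logger.info("skipped %d reads on chromosomes outside the annotation", skipped)
    return pd.Series(counts, index=ids)


def background_counts_per_promoter(
    window_counts: CountMatrix, annotation: BackgroundAnnotation
) -> CountMatrix:
    """Sum finalized-window counts per promoter and sample.

    Promoters flagged "no_background" are omitted; a finalized window
    missing from ``window_counts`` is an error naming the window.
    """
    rows = {}
    for pid, windows in annotation.windows.items():
        if pid in annotation.no_background or not windows:
            continue
        wids = [w.id for w in windows]
        missing = [w for w in wids if w not in window_counts.data.index]
        if missing:
            raise KeyError(
                f"background window(s) missing from counts for {pid}: {missing[0]}"
            )
        rows[pid] = window_counts.data.loc[wids].sum(axis=0)
    if not rows:
        raise ValueError("no promoters with background windows")
    data = pd.DataFrame(rows).T
    data.index.name = "id"
    return CountMatrix(data, window_counts.conditions)


def size_factors(matrix: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors (geometric-mean reference).

    Falls back to total-count scaling (normalized to geometric mean 1)
    when no row has all-positive counts.
    """
    data = matrix.data if isinstance(matrix, CountMatrix) else matrix
    arr = data.to_numpy(dtype=float)
    positive = np.all(arr > 0, axis=1)
    if positive.any():
        logref = np.mean(np.log(arr[positive]), axis=1)
        factors = np.exp(
            np.median(np.log(arr[positive]) - logref[:, None], axis=0)
        )
    else:
        logger.warning(
            "no feature with all-positive counts; using total-count scaling"
        )
        totals = arr.sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError("sample with zero total counts")
        factors = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(factors, index=data.columns, name="size_factor")
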