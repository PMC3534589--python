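"""Genome-segment partitioning and segment-variance accounting.

A segment is a fixed-size, non-overlapping window of consecutive markers
that never spans a chromosome boundary. The variance a segment explains in
one MCMC draw is the across-individual sample variance of the partial
genetic values ``W_s g_s``; the estimated segment variance is the posterior
mean of that quantity over post-burn-in draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MarkerMap

__all__ = [
    "SegmentPartition",
    "SegmentVarianceProfile",
    "partition",
    "segment_variances_of_draw",
    "SegmentVarianceAccumulator",
    "accumulate_segment_variances",
    "correlate_profiles",
    "intervals_to_segments",
]

CHROMOSOME = "chromosome"


@dataclass(frozen=True)
class SegmentPartition:
    """Disjoint, contiguous half-open marker-index ranges tiling 0..m-1."""

    boundaries: tuple  # of (start, end)
    segment_size: object  # int or "chromosome"
    map: MarkerMap

    def __post_init__(self):
        b = tuple((int(s), int(e)) for s, e in self.boundaries)
        m = len(self.map)
        if not b or b[0][0] != 0 or b[-1][1] != m:
            raise ValueError("partition does not tile 0..m-1")
        for (s0, e0), (s1, e1) in zip(b, b[1:]):
            if e0 != s1 or s0 >= e0:
                raise ValueError("partition ranges must be contiguous and non-empty")
        if b[-1][0] >= b[-1][1]:
            raise ValueError("partition ranges must be non-empty")
        object.__setattr__(self, "boundaries", b)

    @property
    def n_segments(self) -> int:
        return len(self.boundaries)

    def sizes(self) -> np.ndarray:
        return np.array([e - s for s, e in self.boundaries])

    def segment_of_marker(self) -> np.ndarray:
        """Length-m vector mapping marker index -> segment index."""
        seg = np.empty(len(self.map), dtype=np.int64)
        for k, (s, e) in enumerate(self.boundaries):
            seg[s:e] = k
        return seg

    def coords(self) -> pd.DataFrame:
        """Segment coordinates: chrom, start_bp of first and pos_bp of last marker."""
        rows = []
        for s, e in self.boundaries:
            rows.append(
                (self.map.chrom[s], int(self.map.pos_bp[s]), int(self.map.pos_bp[e - 1]))
            )
        return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp"])

    def same_layout(self, other: "SegmentPartition") -> bool:
        return (
            self.boundaries == other.boundaries
            and list(self.map.marker_id) == list(other.map.marker_id)
        )


@dataclass
class SegmentVarianceProfile:
    """Posterior-mean variance per segment and its share of the summed total."""

    variances: np.ndarray
    n_draws: int

    def __post_init__(self):
        self.variances = np.asarray(self.variances, dtype=float)
        if np.any(self.variances < 0):
            raise ValueError("segment variances must be non-negative")

    @property
    def proportions(self) -> np.ndarray:
        total = self.variances.sum()
        if total == 0:
            return np.zeros_like(self.variances)
        return self.variances / total

    def to_frame(self, part: SegmentPartition) -> pd.DataFrame:
        df = part.coords()
        df.insert(0, "segment_index", np.arange(part.n_segments))
        df["variance"] = self.variances
        df["prop_var"] = self.proportions
        return df


def partition(mmap: MarkerMap, segment_size) -> SegmentPartition:
    """Split markers into consecutive windows of ``segment_size`` markers.

    Windows never cross chromosome boundaries; a shorter remainder window
    closes each chromosome. ``segment_size="chromosome"`` yields one segment
    per chromosome.
    """
    chrom = mmap.chrom
    # contiguous chromosome blocks
    blocks: list[tuple[int, int]] = []
    start = 0
    for j in range(1, len(mmap) + 1):
        if j == len(mmap) or chrom[j] != chrom[start]:
            blocks.append((start, j))
            start = j
    if segment_size == CHROMOSOME:
        return SegmentPartition(tuple(blocks), CHROMOSOME, mmap)
    size = int(segment_size)
    if size < 1:
        raise ValueError("segment_size must be >= 1 or 'chromosome'")
    if all(size > (e - s) for s, e in blocks):
        warnings.warn(
            "segment_size exceeds every chromosome's marker count; "
            "falling back to one segment per chromosome",
            stacklevel=2,
        )
        return SegmentPartition(tuple(blocks), CHROMOSOME, mmap)
    bounds = []
    for s, e in blocks:
        for a in range(s, e, size):
            bounds.append((a, min(a + size, e)))
    return SegmentPartition(tuple(bounds), size, mmap)


def segment_variances_of_draw(W, g, part: SegmentPartition) -> np.ndarray:
    """Sample variance (ddof=1) across individuals of each segment's W_s g_s.

    ``W`` may be a StandardizedGenotypes or a raw (n x m) array. Exploits the
    sparsity of ``g``: segments whose effects are all zero contribute exactly
    zero variance.
    """
    Wm = W.W if hasattr(W, "W") else np.asarray(W)
    g = np.asarray(g, dtype=float)
    n, m = Wm.shape
    if g.shape != (m,):
        raise ValueError("effect vector length does not match marker count")
    if n < 2:
        raise ValueError("need at least 2 individuals for a sample variance")
    out = np.zeros(part.n_segments)
    nz = np.flatnonzero(g)
    if nz.size == 0:
        return out
    seg_of = part.segment_of_marker()
    for k in np.unique(seg_of[nz]):
        idx = nz[seg_of[nz] == k]
        u = Wm[:, idx] @ g[idx]
        out[k] = u.var(ddof=1)
    return out


class SegmentVarianceAccumulator:
    """Streaming (running-mean) accumulation of per-draw segment variances."""

    def __init__(self, part: SegmentPartition):
        self.part = part
        self._sum = np.zeros(part.n_segments)
        self.n_draws = 0

    def add(self, variances: np.ndarray) -> None:
        self._sum += variances
        self.n_draws += 1

    def add_draw(self, W, g) -> None:
        self.add(segment_variances_of_draw(W, g, self.part))

    def profile(self) -> SegmentVarianceProfile:
        if self.n_draws == 0:
            raise ValueError("no draws accumulated")
        return SegmentVarianceProfile(self._sum / self.n_draws, self.n_draws)


def accumulate_segment_variances(draws, W, part: SegmentPartition) -> SegmentVarianceProfile:
    """Posterior-mean segment variances over a stream of effect-vector draws."""
    acc = SegmentVarianceAccumulator(part)
    for g in draws:
        acc.add_draw(W, g)
    return acc.profile()


def correlate_profiles(
    v1: SegmentVarianceProfile,
    v2: SegmentVarianceProfile,
    exclude=(),
    part1: SegmentPartition | None = None,
    part2: SegmentPartition | None = None,
) -> float:
    """Pearson correlation of two segment-variance profiles.

    ``exclude`` is a set of segment indices dropped from both profiles before
    correlating — used to remove segments dominated by a known major gene
    (e.g. DGAT1 on bovine chromosome 14), which would otherwise swamp the
    correlation. When partitions are supplied they must have identical
    layout (same marker set and boundaries).
    """
    if part1 is not None and part2 is not None and not part1.same_layout(part2):
        raise ValueError("profiles come from different partitions")
    a = np.asarray(v1.variances, dtype=float)
    b = np.asarray(v2.variances, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles have different segment counts")
    keep = np.setdiff1d(np.arange(a.size), np.fromiter(exclude, dtype=np.int64,
                                                       count=len(set(exclude))))
    if keep.size < 3:
        raise ValueError("fewer than 3 segments retained after exclusion")
    return float(np.corrcoef(a[keep], b[keep])[0, 1])


def intervals_to_segments(part: SegmentPartition, intervals) -> set[int]:
    """Map genomic intervals ("chrom:start-end" strings or tuples) to segment indices.

    A segment is selected when its [start_bp, end_bp] range overlaps the
    interval on the same chromosome.
    """
    parsed = []
    for iv in intervals:
        if isinstance(iv, str):
            chrom, rng = iv.split(":")
            lo, hi = rng.split("-")
            parsed.append((chrom, int(lo), int(hi)))
        else:
            chrom, lo, hi = iv
            parsed.append((str(chrom), int(lo), int(hi)))
    coords = part.coords()
    out = set()
    for k, row in coords.iterrows():
        for chrom, lo, hi in parsed:
            if row["chrom"] == chrom and row["start_bp"] <= hi and row["end_bp"] >= lo:
                out.add(int(k))
    return out
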