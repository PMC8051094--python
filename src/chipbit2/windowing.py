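"""Candidate regions, fixed-length windows, and per-window covariates.

A candidate region is a genomic interval overlapping at least two sample
reads: a promoter interval around a TSS, an enhancer interval around an
annotated center, or (genome-wide mode) a maximal run of read-bearing
windows.  Regions are tiled with non-overlapping fixed-length windows, and
each window carries a depth-normalized sample intensity ``s``, a matched
input intensity ``r``, and — in promoter/enhancer mode — a signed distance
``d`` from its midpoint to the governing feature.

All window starts lie on a global grid of multiples of the window size, so
windows from overlapping promoter intervals coincide exactly and each
genomic tile can be assigned to the single nearest feature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_io import AlignedRead, EnhancerRecord, TssRecord

__all__ = [
    "CandidateRegion",
    "Window",
    "five_prime_positions",
    "find_candidate_regions",
    "partition_windows",
    "compute_intensity",
    "compute_distance",
    "build_windows",
]

DEFAULT_SCALE = 10_000_000  # intensities are reads per 10 million


@dataclass(slots=True)
class CandidateRegion:
    """A genomic interval screened for binding; holds >= 2 sample reads."""

    chrom: str
    start: int
    end: int
    index: int
    read_count: int
    # governing annotation feature, when the mode has one
    feature_id: str | None = None
    feature_pos: int | None = None  # TSS position or enhancer center
    feature_strand: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region start must be < end, got [{self.start}, {self.end})")


@dataclass(slots=True)
class Window:
    """A fixed-length tile of a candidate region.

    ``s``/``r`` are sample/input read intensities; ``d`` the signed distance
    to the governing feature (None genome-wide); ``b`` the current binding
    label and ``posterior`` the binding probability, both filled in by the
    mixture model.
    """

    region_index: int
    window_index: int
    chrom: str
    start: int
    end: int
    s: float = 0.0
    r: float = 0.0
    d: int | None = None
    feature_id: str | None = None
    b: int = 0
    posterior: float = math.nan

    @property
    def midpoint(self) -> int:
        return self.start + (self.end - self.start) // 2


def five_prime_positions(
    reads: Iterable[AlignedRead], extend: int = 0
) -> dict[str, np.ndarray]:
    """Sorted strand-aware 5' positions per chromosome.

    ``extend`` shifts forward-strand positions by +extend/2 and reverse-strand
    positions by -extend/2, a cheap surrogate for fragment-center counting.
    """
    shift = extend // 2
    by_chrom: dict[str, list[int]] = {}
    for read in reads:
        pos = read.five_prime + (shift if read.strand == "+" else -shift)
        by_chrom.setdefault(read.chrom, []).append(pos)
    return {
        chrom: np.sort(np.asarray(positions, dtype=np.int64))
        for chrom, positions in by_chrom.items()
    }


def _count_in(positions: np.ndarray, start: int, end: int) -> int:
    lo, hi = np.searchsorted(positions, [start, end])
    return int(hi - lo)


def _feature_window_span(
    anchor: int, half_span: float, window_size: int
) -> tuple[int, int]:
    """First window start and one-past-last window start on the global grid
    whose midpoints fall within ``anchor ± half_span``."""
    # midpoint of window starting at g*w is g*w + w//2
    half_w = window_size // 2
    lo_mid = anchor - half_span
    hi_mid = anchor + half_span
    first = math.ceil((lo_mid - half_w) / window_size) * window_size
    last = math.floor((hi_mid - half_w) / window_size) * window_size
    return first, last + window_size


def find_candidate_regions(
    sample_reads: Sequence[AlignedRead] | Mapping[str, np.ndarray],
    mode: str,
    tss: Sequence[TssRecord] | None = None,
    enhancers: Sequence[EnhancerRecord] | None = None,
    window_size: int = 50,
    d_P: int = 20_000,
    d_E: int = 2_000,
    extend: int = 0,
) -> list[CandidateRegion]:
    """Identify candidate regions holding at least two sample reads.

    Promoter mode screens one interval of length ``d_P`` per TSS, enhancer
    mode one interval of length ``d_E`` per enhancer center; genome-wide
    mode takes maximal runs of read-bearing grid windows.  Intervals are
    snapped to the window grid so their window midpoints stay within half
    the configured span of the feature.
    """
    if mode not in ("promoter", "enhancer", "wg"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(sample_reads, Mapping):
        positions = sample_reads
    else:
        positions = five_prime_positions(sample_reads, extend=extend)

    regions: list[CandidateRegion] = []
    if mode == "promoter":
        if not tss:
            raise ValueError("promoter mode requires a TSS annotation")
        for rec in sorted(tss, key=lambda t: (t.chrom, t.tss, t.gene_id)):
            start, end = _feature_window_span(rec.tss, d_P / 2, window_size)
            if start < 0:
                start = 0
            if start >= end:
                continue
            count = _count_in(positions.get(rec.chrom, np.empty(0)), start, end)
            if count >= 2:
                regions.append(
                    CandidateRegion(
                        chrom=rec.chrom,
                        start=start,
                        end=end,
                        index=len(regions),
                        read_count=count,
                        feature_id=rec.gene_id,
                        feature_pos=rec.tss,
                        feature_strand=rec.strand,
                    )
                )
    elif mode == "enhancer":
        if not enhancers:
            raise ValueError("enhancer mode requires an enhancer annotation")
        for k, rec in enumerate(sorted(enhancers, key=lambda e: (e.chrom, e.start))):
            start, end = _feature_window_span(rec.center, d_E / 2, window_size)
            if start < 0:
                start = 0
            if start >= end:
                continue
            count = _count_in(positions.get(rec.chrom, np.empty(0)), start, end)
            if count >= 2:
                regions.append(
                    CandidateRegion(
                        chrom=rec.chrom,
                        start=start,
                        end=end,
                        index=len(regions),
                        read_count=count,
                        feature_id=f"enh_{rec.chrom}_{rec.start}_{rec.end}",
                        feature_pos=rec.center,
                    )
                )
    else:  # wg
        for chrom in sorted(positions):
            pos = positions[chrom]
            if pos.size == 0:
                continue
            win_idx = pos // window_size
            uniq, counts = np.unique(win_idx, return_counts=True)
            # maximal runs of consecutive read-bearing windows
            breaks = np.flatnonzero(np.diff(uniq) > 1)
            run_starts = np.concatenate(([0], breaks + 1))
            run_ends = np.concatenate((breaks, [uniq.size - 1]))
            for lo, hi in zip(run_starts, run_ends):
                total = int(counts[lo : hi + 1].sum())
                if total < 2:
                    continue
                regions.append(
                    CandidateRegion(
                        chrom=chrom,
                        start=int(uniq[lo]) * window_size,
                        end=(int(uniq[hi]) + 1) * window_size,
                        index=len(regions),
                        read_count=total,
                    )
                )
    return regions


def partition_windows(region: CandidateRegion, window_size: int) -> list[Window]:
    """Tile a region with adjacent non-overlapping windows.

    Promoter/enhancer regions are multiples of the window size by
    construction; a genome-wide region shorter than one window yields a
    single window spanning it.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    windows: list[Window] = []
    length = region.end - region.start
    if length <= window_size:
        return [
            Window(
                region_index=region.index,
                window_index=0,
                chrom=region.chrom,
                start=region.start,
                end=region.end,
                feature_id=region.feature_id,
            )
        ]
    w = 0
    for start in range(region.start, region.end, window_size):
        end = min(start + window_size, region.end)
        windows.append(
            Window(
                region_index=region.index,
                window_index=w,
                chrom=region.chrom,
                start=start,
                end=end,
                feature_id=region.feature_id,
            )
        )
        w += 1
    return windows


def compute_intensity(
    positions: Mapping[str, np.ndarray] | np.ndarray,
    window: Window,
    library_size: int,
    scale_to: int = DEFAULT_SCALE,
) -> float:
    """Depth-normalized read count in a window: count * scale_to / library_size."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if isinstance(positions, Mapping):
        positions = positions.get(window.chrom, np.empty(0))
    return _count_in(positions, window.start, window.end) * scale_to / library_size


def compute_distance(
    window: Window,
    mode: str,
    feature: TssRecord | EnhancerRecord | None = None,
) -> int | None:
    """Signed distance from window midpoint to the governing feature.

    Promoter mode orients by gene strand so negative means upstream of the
    TSS; enhancer mode measures from the enhancer center; genome-wide mode
    carries no distance.
    """
    if mode == "wg":
        return None
    mid = window.midpoint
    if mode == "promoter":
        assert isinstance(feature, TssRecord)
        d = mid - feature.tss
        return d if feature.strand == "+" else -d
    if mode == "enhancer":
        assert isinstance(feature, EnhancerRecord)
        return mid - feature.center
    raise ValueError(f"unknown mode {mode!r}")


def _nearest_feature_filter(
    regions: Sequence[CandidateRegion],
    windows_by_region: list[list[Window]],
) -> list[list[Window]]:
    """Keep each grid window only in the region of its nearest feature.

    When promoter (or enhancer) intervals of nearby features overlap, the
    same grid tile appears in several regions; it is retained only where
    |midpoint - feature| is smallest, ties broken by lexicographically
    smaller feature id, so every tile is modeled exactly once.
    """
    anchors: dict[str, list[tuple[int, str]]] = {}
    for region in regions:
        anchors.setdefault(region.chrom, []).append(
            (region.feature_pos, region.feature_id)
        )
    arr = {
        chrom: (
            np.asarray([a for a, _ in sorted(vals)], dtype=np.int64),
            [fid for _, fid in sorted(vals)],
        )
        for chrom, vals in anchors.items()
    }
    kept: list[list[Window]] = []
    for region, windows in zip(regions, windows_by_region):
        pos_arr, ids = arr[region.chrom]
        keep: list[Window] = []
        for win in windows:
            mid = win.midpoint
            j = int(np.searchsorted(pos_arr, mid))
            best: tuple[int, str] | None = None
            for k in (j - 1, j, j + 1):
                if 0 <= k < pos_arr.size:
                    cand = (abs(mid - int(pos_arr[k])), ids[k])
                    if best is None or cand < best:
                        best = cand
            # handle exact-distance ties across non-adjacent duplicates
            if best is not None and (
                best[0] == abs(mid - region.feature_pos)
                and best[1] == region.feature_id
            ):
                keep.append(win)
        kept.append(keep)
    return kept


def build_windows(
    regions: Sequence[CandidateRegion],
    sample_positions: Mapping[str, np.ndarray],
    input_positions: Mapping[str, np.ndarray],
    sample_library: int,
    input_library: int,
    mode: str,
    window_size: int,
    tss: Sequence[TssRecord] | None = None,
    enhancers: Sequence[EnhancerRecord] | None = None,
    scale_to: int = DEFAULT_SCALE,
) -> list[Window]:
    """Partition all regions and fill in (s, r, d) for every window."""
    feature_lookup: dict[str, TssRecord | EnhancerRecord] = {}
    if mode == "promoter" and tss:
        feature_lookup = {t.gene_id: t for t in tss}
    elif mode == "enhancer" and enhancers:
        feature_lookup = {
            f"enh_{e.chrom}_{e.start}_{e.end}": e for e in enhancers
        }

    windows_by_region = [partition_windows(region, window_size) for region in regions]
    if mode in ("promoter", "enhancer") and regions:
        windows_by_region = _nearest_feature_filter(regions, windows_by_region)

    out: list[Window] = []
    for region, windows in zip(regions, windows_by_region):
        feature = feature_lookup.get(region.feature_id)
        for win in windows:
            win.s = compute_intensity(sample_positions, win, sample_library, scale_to)
            win.r = compute_intensity(input_positions, win, input_library, scale_to)
            win.d = compute_distance(win, mode, feature)
            out.append(win)
    return out
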