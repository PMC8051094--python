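"""Merge above-threshold windows into peaks and evaluate calls.

Consecutive windows of one candidate region whose posterior exceeds the
reporting threshold (default 0.9) are combined into a single peak scored by
the maximum posterior of the run.  Peaks never span two candidate regions.
In promoter mode each peak inherits the gene whose TSS governs its region,
which is the target-gene prediction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_io import Peak, TssRecord
from .windowing import Window

__all__ = [
    "call_peaks",
    "assign_target_genes",
    "evaluate_f1",
    "TruthRegion",
    "read_truth_bed",
]


def call_peaks(
    windows: Sequence[Window],
    threshold: float = 0.9,
    mode: str = "wg",
    score: str = "max",
    max_gap: int = 0,
) -> list[Peak]:
    """Combine runs of consecutive above-threshold windows into peaks.

    A run is maximal within its region; by default a single sub-threshold
    window breaks it (``max_gap`` windows may be bridged).  ``score`` is the
    run's maximum posterior ("max") or its mean over above-threshold
    windows ("mean").
    """
    if score not in ("max", "mean"):
        raise ValueError("score must be 'max' or 'mean'")
    by_region: dict[int, list[Window]] = {}
    for w in windows:
        by_region.setdefault(w.region_index, []).append(w)

    peaks: list[Peak] = []
    for region_index in sorted(by_region):
        ws = sorted(by_region[region_index], key=lambda w: w.window_index)
        run: list[Window] = []
        gap = 0

        def flush() -> None:
            if not run:
                return
            posts = [w.posterior for w in run]
            peaks.append(
                Peak(
                    chrom=run[0].chrom,
                    start=run[0].start,
                    end=run[-1].end,
                    score=max(posts) if score == "max" else float(np.mean(posts)),
                    mode=mode,
                    n_windows=len(run),
                    feature_id=run[0].feature_id,
                )
            )
            run.clear()

        prev_index: int | None = None
        for w in ws:
            above = w.posterior > threshold
            adjacent = prev_index is not None and w.window_index == prev_index + 1
            if run and not adjacent:
                flush()
                gap = 0
            if above:
                if run and gap > 0:
                    # bridged windows stay inside the peak span but only
                    # above-threshold windows count toward n_windows
                    pass
                run.append(w)
                gap = 0
            elif run:
                gap += 1
                if gap > max_gap:
                    flush()
                    gap = 0
            prev_index = w.window_index
        flush()
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return peaks


def assign_target_genes(
    peaks: Sequence[Peak], tss_records: Sequence[TssRecord]
) -> list[Peak]:
    """Set each promoter-mode peak's target gene from its governing TSS."""
    known = {t.gene_id for t in tss_records}
    for peak in peaks:
        if peak.mode != "promoter":
            raise ValueError("target-gene assignment applies to promoter mode only")
        if peak.feature_id is None or peak.feature_id not in known:
            raise ValueError(
                f"peak at {peak.chrom}:{peak.start}-{peak.end} has no governing TSS"
            )
        peak.target_gene = peak.feature_id
    return list(peaks)


@dataclass(frozen=True, slots=True)
class TruthRegion:
    """A labeled benchmark interval: peak evidence or annotated background."""

    chrom: str
    start: int
    end: int
    label: str  # peak | peakStart | peakEnd | noPeak

    @property
    def is_peak(self) -> bool:
        return self.label in ("peak", "peakStart", "peakEnd")


def read_truth_bed(path: str | os.PathLike) -> list[TruthRegion]:
    """Read benchmark-style labels: BED with a 4th column label."""
    regions: list[TruthRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns (chrom start end label)")
            label = fields[3]
            if label not in ("peak", "peakStart", "peakEnd", "noPeak"):
                # truth BEDs from the simulator carry class names; treat any
                # non-background label as peak evidence
                label = "peak"
            regions.append(TruthRegion(fields[0], int(fields[1]), int(fields[2]), label))
    return regions


def _overlaps_any(
    chrom: str, start: int, end: int, by_chrom: dict[str, tuple[np.ndarray, np.ndarray]]
) -> bool:
    if chrom not in by_chrom:
        return False
    starts, ends = by_chrom[chrom]
    # intervals sorted by start; overlap iff some interval has start < end
    # and its own end > start
    j = int(np.searchsorted(starts, end))
    return bool(np.any(ends[:j] > start))


def evaluate_f1(
    called_peaks: Sequence[Peak],
    truth_regions: Sequence[TruthRegion] | Sequence[tuple[str, int, int]],
) -> tuple[float, float, float]:
    """Precision, recall, and F1 of called peaks against labeled truth.

    A truth peak is recalled if any called peak overlaps it by >= 1 bp; a
    called peak is a true positive if it overlaps any truth peak.  F1 is
    the harmonic mean 2·P·R/(P+R).  With no calls and no truth peaks all
    three are defined as 1; calls absent but truth present gives 0.
    """
    truth_peaks: list[tuple[str, int, int]] = []
    for t in truth_regions:
        if isinstance(t, TruthRegion):
            if t.is_peak:
                truth_peaks.append((t.chrom, t.start, t.end))
        else:
            truth_peaks.append(tuple(t))

    def index(intervals: Sequence[tuple[str, int, int]]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        by: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            by.setdefault(chrom, []).append((start, end))
        out = {}
        for chrom, pairs in by.items():
            pairs.sort()
            starts = np.asarray([p[0] for p in pairs], dtype=np.int64)
            ends = np.maximum.accumulate(np.asarray([p[1] for p in pairs], dtype=np.int64))
            out[chrom] = (starts, ends)
        return out

    truth_idx = index(truth_peaks)
    call_idx = index([(p.chrom, p.start, p.end) for p in called_peaks])

    if not called_peaks and not truth_peaks:
        return 1.0, 1.0, 1.0
    if not called_peaks:
        return 0.0, 0.0, 0.0
    if not truth_peaks:
        return 0.0, 1.0, 0.0

    tp_calls = sum(
        _overlaps_any(p.chrom, p.start, p.end, truth_idx) for p in called_peaks
    )
    recalled = sum(
        _overlaps_any(chrom, start, end, call_idx) for chrom, start, end in truth_peaks
    )
    precision = tp_calls / len(called_peaks)
    recall = recalled / len(truth_peaks)
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1
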