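"""Input/output for alignments, annotations, and peak calls.

Coordinate conventions
----------------------
Everything in memory is 0-based, half-open.  SAM positions (1-based) are
converted once at ingest; BED output is written 0-based half-open.  These
conventions follow the SAM and BED standards and are never revisited
downstream.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
import pysam

__all__ = [
    "AlignedRead",
    "TssRecord",
    "EnhancerRecord",
    "Peak",
    "read_sam",
    "read_tss",
    "read_enhancers",
    "write_peaks_bed",
    "read_peaks_bed",
]


@dataclass(frozen=True, slots=True)
class AlignedRead:
    """One mapped single-end read.

    ``start`` is the 0-based leftmost aligned base.  The strand-aware 5'
    position (the quantity windows count) is ``start`` on the forward strand
    and ``start + length - 1`` on the reverse strand.
    """

    chrom: str
    start: int
    strand: str
    length: int
    mapq: int = 0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"read start must be >= 0, got {self.start}")
        if self.length <= 0:
            raise ValueError(f"read length must be > 0, got {self.length}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.start + self.length - 1


@dataclass(frozen=True, slots=True)
class TssRecord:
    """A transcription start site with its gene identifier."""

    chrom: str
    tss: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"TSS position must be >= 0, got {self.tss}")
        if not self.gene_id:
            raise ValueError("gene_id must be nonempty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True, slots=True)
class EnhancerRecord:
    """An annotated enhancer interval; its center anchors distance computation."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"enhancer start must be < end, got [{self.start}, {self.end})"
            )

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(slots=True)
class Peak:
    """A merged run of above-threshold windows.

    ``score`` is the posterior binding probability assigned to the peak
    (by default the maximum over its windows); ``n_windows`` the number of
    windows merged into it.
    """

    chrom: str
    start: int
    end: int
    score: float
    mode: str = "wg"
    target_gene: str | None = None
    n_windows: int = 1
    feature_id: str | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak start must be < end, got [{self.start}, {self.end})")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"peak score must lie in [0, 1], got {self.score}")


def _opener(path: str | os.PathLike, mode: str = "rt") -> io.TextIOBase:
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_sam(
    path: str | os.PathLike,
    min_mapq: int = 10,
    dedup: bool = False,
) -> list[AlignedRead]:
    """Read mapped single-end reads from a SAM file.

    Unmapped, secondary, and supplementary records are excluded; remaining
    records are filtered at ``mapq >= min_mapq``.  SAM 1-based POS becomes
    a 0-based ``start``.  With ``dedup=True`` reads identical in
    (chrom, start, strand) are collapsed to one.

    Raises
    ------
    ValueError
        If a record cannot be parsed (the failing record index is named),
        or if the file yields zero mapped reads ("empty profile").
    """
    reads: list[AlignedRead] = []
    n_records = 0
    with pysam.AlignmentFile(os.fspath(path), "r", check_sq=False) as fh:
        iterator = fh.fetch(until_eof=True)
        while True:
            try:
                rec = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:  # malformed record
                raise ValueError(
                    f"unparseable SAM record at alignment #{n_records + 1} "
                    f"in {path}: {exc}"
                ) from exc
            n_records += 1
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            length = rec.query_length or rec.infer_query_length() or rec.reference_length
            if not length:
                raise ValueError(
                    f"cannot determine read length at alignment #{n_records} in {path}"
                )
            reads.append(
                AlignedRead(
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    length=int(length),
                    mapq=rec.mapping_quality,
                )
            )
    if not reads:
        raise ValueError(f"empty profile: no mapped reads with mapq >= {min_mapq} in {path}")
    if dedup:
        seen: set[tuple[str, int, str]] = set()
        unique: list[AlignedRead] = []
        for read in reads:
            key = (read.chrom, read.start, read.strand)
            if key not in seen:
                seen.add(key)
                unique.append(read)
        reads = unique
    return reads


def read_tss(path: str | os.PathLike) -> list[TssRecord]:
    """Read a 4-column TSS annotation (chrom, position, strand, gene_id).

    Records come back sorted by (chrom, tss); exact duplicates of
    (chrom, tss, gene_id) are collapsed.  A file without a strand column is
    rejected because the signed promoter distance needs gene orientation.
    """
    with _opener(path) as fh:
        df = pd.read_csv(
            fh,
            sep="\t",
            header=None,
            comment="#",
            dtype=str,
        )
    if df.shape[1] < 4:
        raise ValueError(
            f"TSS annotation {path} needs 4 tab-separated columns "
            "(chrom, position, strand, gene_id); the strand column is required "
            "for signed distances"
        )
    df = df.iloc[:, :4]
    df.columns = ["chrom", "tss", "strand", "gene_id"]
    if not df["strand"].isin(["+", "-"]).all():
        bad = df.loc[~df["strand"].isin(["+", "-"]), "strand"].iloc[0]
        raise ValueError(f"invalid strand value {bad!r} in {path}")
    df["tss"] = df["tss"].astype(int)
    df = df.drop_duplicates(subset=["chrom", "tss", "gene_id"])
    df = df.sort_values(["chrom", "tss"], kind="mergesort")
    return [
        TssRecord(row.chrom, int(row.tss), row.strand, row.gene_id)
        for row in df.itertuples(index=False)
    ]


def read_enhancers(path: str | os.PathLike) -> list[EnhancerRecord]:
    """Read a BED3+ enhancer annotation; returns records sorted by (chrom, start)."""
    records: list[EnhancerRecord] = []
    with _opener(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: enhancer start must be < end, got {start} >= {end}"
                )
            records.append(EnhancerRecord(chrom, start, end))
    records.sort(key=lambda rec: (rec.chrom, rec.start))
    return records


_BED_HEADER = "# chrom\tstart\tend\tname\tscore\tstrand"


def write_peaks_bed(peaks: Sequence[Peak], path: str | os.PathLike) -> None:
    """Write peaks as BED6.

    The name column carries the target gene in promoter mode and ``peak_k``
    otherwise; the score column is ``round(1000 * posterior)``.  Peaks must
    be sorted and non-overlapping per chromosome — overlap means the
    upstream merging contract was violated, so it is a hard error.
    """
    last: dict[str, int] = {}
    order: tuple[str, int] | None = None
    for peak in peaks:
        key = (peak.chrom, peak.start)
        if order is not None and key < order:
            raise ValueError("peaks must be sorted by (chrom, start) before writing")
        order = key
        if peak.chrom in last and peak.start < last[peak.chrom]:
            raise ValueError(
                f"overlapping peaks on {peak.chrom} at {peak.start}: "
                "window merging must produce disjoint peaks"
            )
        last[peak.chrom] = peak.end
    with _opener(path, "wt") as fh:
        fh.write(_BED_HEADER + "\n")
        for k, peak in enumerate(peaks, start=1):
            name = peak.target_gene if peak.target_gene else f"peak_{k}"
            fh.write(
                f"{peak.chrom}\t{peak.start}\t{peak.end}\t{name}\t"
                f"{round(1000 * peak.score)}\t.\n"
            )


def read_peaks_bed(path: str | os.PathLike, mode: str = "wg") -> list[Peak]:
    """Re-parse a BED6 peak file written by :func:`write_peaks_bed`."""
    peaks: list[Peak] = []
    with _opener(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, start, end, name, score, _strand = line.split("\t")[:6]
            target = None if name.startswith("peak_") else name
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    score=int(score) / 1000.0,
                    mode=mode,
                    target_gene=target,
                )
            )
    return peaks
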