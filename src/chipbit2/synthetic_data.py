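"""Synthetic ChIP-seq profiles with planted strong and weak peaks.

The generator writes a matched sample/input SAM pair plus annotations and a
full truth list, so the whole pipeline can be exercised end to end without
any external data.  It emulates the structure peak callers must cope with:

* a genome-wide Poisson background present in BOTH profiles (amplified
  background DNA), depth-scaled between sample and input;
* peak reads added to the sample only, with the count for each peak drawn
  as Poisson(fold × expected background mass of the peak interval) — so a
  10× "strong" peak carries ten background-masses of extra reads and a
  2.5× "weak" peak only 2.5;
* narrow (TF-like, fixed width) or broad (histone-like, variable width)
  peak shapes;
* a fraction of peaks anchored to gene TSSs with an exponentially
  distributed offset, mirroring the distance decay of true binding toward
  promoters; the remainder are distal and receive enhancer annotations.

Reads are single-end, fixed length, uniform within their interval, strand
Bernoulli(0.5), MAPQ 60, sequence all-N: peak calling never inspects
sequence content, so no error model is simulated.  Output is byte-identical
for a fixed seed.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .windowing import Window

__all__ = [
    "SimConfig",
    "PlantedPeak",
    "SyntheticTruth",
    "SimPaths",
    "simulate",
    "truth_to_labels",
    "simulate_windows",
]


@dataclass(slots=True)
class SimConfig:
    """Study conditions for the simulator.

    Defaults plant 200 strong (10×) and 200 weak (2.5×) narrow peaks on a
    10 Mb toy chromosome with one million reads in each profile.  Half of
    the peaks sit at promoters, offset from their TSS by Exp(lambda_true)
    with random sign; the rest are distal and get enhancer annotations.
    """

    genome: list[tuple[str, int]] = field(default_factory=lambda: [("chr1", 10_000_000)])
    n_strong: int = 200
    n_weak: int = 200
    strong_fold: float = 10.0
    weak_fold: float = 2.5
    peak_width: str | int = "narrow"  # "narrow": fixed 200 bp; "broad": U(1000, 5000)
    background_rate: float | None = None  # input reads per bp; default input_depth/genome
    sample_depth: int = 1_000_000
    input_depth: int = 1_000_000
    read_length: int = 50
    promoter_fraction: float = 0.5
    lambda_true: float = 5e-4
    n_decoy_genes: int = 200
    n_decoy_enhancers: int = 200
    enhancer_width: int = 2_000
    overdispersion: float = 0.0  # gamma CV^2; 0 keeps plain Poisson counts
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_strong < 0 or self.n_weak < 0:
            raise ValueError("peak counts must be >= 0")
        if self.strong_fold <= 1 or self.weak_fold <= 1:
            raise ValueError("enrichment folds must exceed 1")
        if not (0.0 <= self.promoter_fraction <= 1.0):
            raise ValueError("promoter_fraction must lie in [0, 1]")

    @property
    def genome_length(self) -> int:
        return sum(length for _, length in self.genome)

    @property
    def input_rate(self) -> float:
        if self.background_rate is not None:
            return self.background_rate
        return self.input_depth / self.genome_length


@dataclass(frozen=True, slots=True)
class PlantedPeak:
    chrom: str
    start: int
    end: int
    peak_class: str  # strong | weak
    gene_id: str | None  # set when anchored to a promoter


@dataclass(slots=True)
class SyntheticTruth:
    peaks: list[PlantedPeak]
    n_sample_background: int
    n_sample_peak: int
    n_input: int


@dataclass(frozen=True, slots=True)
class SimPaths:
    sample_sam: Path
    input_sam: Path
    truth_bed: Path
    tss_tsv: Path
    enhancer_bed: Path


def _draw_width(config: SimConfig, rng: np.random.Generator) -> int:
    if isinstance(config.peak_width, int):
        return config.peak_width
    if config.peak_width == "narrow":
        return 200
    if config.peak_width == "broad":
        return int(rng.integers(1_000, 5_001))
    raise ValueError(f"unknown peak_width spec {config.peak_width!r}")


def _place_nonoverlapping(
    occupied: list[tuple[int, int]], start: int, end: int
) -> bool:
    """True and record if [start, end) is free; intervals kept sorted."""
    import bisect

    i = bisect.bisect_left(occupied, (start, end))
    if i > 0 and occupied[i - 1][1] > start:
        return False
    if i < len(occupied) and occupied[i][0] < end:
        return False
    occupied.insert(i, (start, end))
    return True


def simulate(
    config: SimConfig, outdir: str | os.PathLike
) -> tuple[SimPaths, SyntheticTruth]:
    """Generate sample/input SAM files, annotations, and the truth list.

    Everything is deterministic given ``config.seed``.  Peaks that would
    overlap an existing one are re-drawn up to 100 times before erroring.
    """
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    chroms = [c for c, _ in config.genome]
    lengths = dict(config.genome)
    weights = np.asarray([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    # --- plant peaks, genes, enhancers -------------------------------------
    margin = 20_000  # keep features away from chromosome edges
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    peaks: list[PlantedPeak] = []
    tss_rows: list[tuple[str, int, str, str]] = []
    enhancer_rows: list[tuple[str, int, int]] = []

    classes = ["strong"] * config.n_strong + ["weak"] * config.n_weak
    n_promoter = round(len(classes) * config.promoter_fraction)
    gene_counter = 0
    for k, peak_class in enumerate(classes):
        at_promoter = k < n_promoter
        width = _draw_width(config, rng)
        placed = False
        for _attempt in range(100):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            chrom_len = lengths[chrom]
            if chrom_len <= 2 * margin + width:
                continue
            if at_promoter:
                tss = int(rng.integers(margin, chrom_len - margin))
                strand = "+" if rng.random() < 0.5 else "-"
                offset = rng.exponential(1.0 / config.lambda_true)
                offset = min(offset, 9_000.0)  # stay inside a +-10 kb promoter
                sign = 1.0 if rng.random() < 0.5 else -1.0
                center = int(tss + sign * offset)
            else:
                center = int(rng.integers(margin, chrom_len - margin))
            start = max(center - width // 2, 0)
            end = min(start + width, chrom_len)
            if _place_nonoverlapping(occupied[chrom], start, end):
                placed = True
                break
        if not placed:
            raise RuntimeError("could not place a non-overlapping peak in 100 attempts")
        gene_id = None
        if at_promoter:
            gene_counter += 1
            gene_id = f"gene_{gene_counter:05d}"
            tss_rows.append((chrom, tss, strand, gene_id))
        else:
            half = config.enhancer_width // 2
            enhancer_rows.append((chrom, max(center - half, 0), center + half))
        peaks.append(PlantedPeak(chrom, start, end, peak_class, gene_id))

    # decoy annotations: features with no planted peak, so annotation-driven
    # modes see genuine background regions too
    for _ in range(config.n_decoy_genes):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        tss = int(rng.integers(margin, lengths[chrom] - margin))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_counter += 1
        tss_rows.append((chrom, tss, strand, f"gene_{gene_counter:05d}"))
    for _ in range(config.n_decoy_enhancers):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        center = int(rng.integers(margin, lengths[chrom] - margin))
        half = config.enhancer_width // 2
        enhancer_rows.append((chrom, max(center - half, 0), center + half))

    # --- draw reads ---------------------------------------------------------
    input_rate = config.input_rate
    sample_rate = input_rate * config.sample_depth / config.input_depth

    def background_reads(rate: float) -> list[tuple[str, int, str]]:
        out: list[tuple[str, int, str]] = []
        for chrom in chroms:
            chrom_len = lengths[chrom]
            n = int(rng.poisson(rate * chrom_len))
            starts = rng.integers(0, max(chrom_len - config.read_length, 1), size=n)
            strands = rng.random(n) < 0.5
            out.extend(
                (chrom, int(p), "+" if fwd else "-")
                for p, fwd in zip(starts, strands)
            )
        return out

    input_reads = background_reads(input_rate)
    sample_reads = background_reads(sample_rate)
    n_sample_background = len(sample_reads)

    n_peak_reads = 0
    for peak in peaks:
        fold = config.strong_fold if peak.peak_class == "strong" else config.weak_fold
        mean = fold * sample_rate * (peak.end - peak.start)
        if config.overdispersion > 0:
            shape = 1.0 / config.overdispersion
            mean = rng.gamma(shape, mean / shape)
        n = int(rng.poisson(mean))
        n_peak_reads += n
        hi = max(peak.end - config.read_length, peak.start + 1)
        starts = rng.integers(peak.start, hi, size=n)
        strands = rng.random(n) < 0.5
        sample_reads.extend(
            (peak.chrom, int(p), "+" if fwd else "-")
            for p, fwd in zip(starts, strands)
        )

    # --- write outputs ------------------------------------------------------
    paths = SimPaths(
        sample_sam=outdir / "sample.sam",
        input_sam=outdir / "input.sam",
        truth_bed=outdir / "truth.bed",
        tss_tsv=outdir / "tss.tsv",
        enhancer_bed=outdir / "enhancers.bed",
    )
    _write_sam(paths.sample_sam, sample_reads, config)
    _write_sam(paths.input_sam, input_reads, config)

    with open(paths.truth_bed, "w") as fh:
        for peak in sorted(peaks, key=lambda p: (p.chrom, p.start)):
            gene = peak.gene_id if peak.gene_id else "."
            fh.write(f"{peak.chrom}\t{peak.start}\t{peak.end}\t{peak.peak_class}\t{gene}\n")
    with open(paths.tss_tsv, "w") as fh:
        for chrom, tss, strand, gene_id in sorted(tss_rows, key=lambda r: (r[0], r[1])):
            fh.write(f"{chrom}\t{tss}\t{strand}\t{gene_id}\n")
    with open(paths.enhancer_bed, "w") as fh:
        for chrom, start, end in sorted(enhancer_rows):
            fh.write(f"{chrom}\t{start}\t{end}\n")

    truth = SyntheticTruth(
        peaks=peaks,
        n_sample_background=n_sample_background,
        n_sample_peak=n_peak_reads,
        n_input=len(input_reads),
    )
    return paths, truth


def _write_sam(
    path: Path, reads: list[tuple[str, int, str]], config: SimConfig
) -> None:
    """Write coordinate-sorted single-end SAM with @SQ headers."""
    reads = sorted(reads)
    seq = "N" * config.read_length
    cigar = f"{config.read_length}M"
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom, length in config.genome:
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for i, (chrom, start, strand) in enumerate(reads, start=1):
            flag = 0 if strand == "+" else 16
            fh.write(
                f"read_{i}\t{flag}\t{chrom}\t{start + 1}\t60\t{cigar}\t*\t0\t0\t{seq}\t*\n"
            )


def truth_to_labels(
    truth: SyntheticTruth | Sequence[PlantedPeak],
    genome: Sequence[tuple[str, int]],
    window_size: int = 1,
) -> list[tuple[str, int, int, str]]:
    """Label the whole genome as alternating noPeak / peak intervals.

    The labels partition each chromosome exactly; ``window_size`` is kept in
    the signature for symmetry with the caller's resolution but boundaries
    are emitted at base-pair precision.
    """
    peaks = truth.peaks if isinstance(truth, SyntheticTruth) else list(truth)
    by_chrom: dict[str, list[PlantedPeak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    labels: list[tuple[str, int, int, str]] = []
    for chrom, length in genome:
        cursor = 0
        for p in sorted(by_chrom.get(chrom, []), key=lambda q: q.start):
            if p.start > cursor:
                labels.append((chrom, cursor, p.start, "noPeak"))
            labels.append((chrom, p.start, p.end, "peak"))
            cursor = p.end
        if cursor < length:
            labels.append((chrom, cursor, length, "noPeak"))
    return labels


def simulate_windows(
    n_windows: int = 5_000,
    frac_bound: float = 0.2,
    mu1: float = 8.0,
    sigma1_sq: float = 4.0,
    r_mean: float = 2.0,
    r_sd: float = 0.5,
    lambda_true: float = 5e-4,
    d_P: float = 20_000.0,
    seed: int = 1,
) -> tuple[list[Window], np.ndarray]:
    """Draw promoter-mode windows directly from the generative model.

    Bound windows get s ~ Normal(mu1, sigma1_sq) and |d| ~ Exp(lambda_true);
    background windows get s ~ Normal(r, var(r)) and d uniform over the
    promoter.  Used for parameter-recovery checks where read-level
    simulation would only add noise around the quantity under test.
    Returns the windows and the true binding labels.
    """
    rng = np.random.default_rng(seed)
    n_bound = int(round(n_windows * frac_bound))
    labels = np.zeros(n_windows, dtype=int)
    labels[:n_bound] = 1
    rng.shuffle(labels)

    r = rng.normal(r_mean, r_sd, size=n_windows)
    sigma0_sq = r_sd**2
    s = np.where(
        labels == 1,
        rng.normal(mu1, math.sqrt(sigma1_sq), size=n_windows),
        rng.normal(r, math.sqrt(sigma0_sq)),
    )
    half = d_P / 2
    d_bound = np.minimum(rng.exponential(1.0 / lambda_true, size=n_windows), half - 1)
    d_bound *= np.where(rng.random(n_windows) < 0.5, 1, -1)
    d_uniform = rng.uniform(-half, half, size=n_windows)
    d = np.where(labels == 1, d_bound, d_uniform).astype(int)

    windows = [
        Window(
            region_index=i,
            window_index=0,
            chrom="chrSim",
            start=i * 50,
            end=(i + 1) * 50,
            s=float(s[i]),
            r=float(max(r[i], 0.0)),
            d=int(d[i]),
            b=int(labels[i]),
        )
        for i in range(n_windows)
    ]
    return windows, labels
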