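"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the library's own code paths: plain loops and
plain arithmetic only, so they can serve as a second opinion.
"""

from __future__ import annotations

import math


def plain_posterior(
    s: float,
    r: float,
    d: float | None,
    mode: str,
    mu1: float,
    sigma1_sq: float,
    sigma0_sq: float,
    lambda_: float,
    d_P: float,
    d_E: float,
    prior_b1: float = 0.5,
) -> float:
    """Two-term Bayes rule evaluated directly, no logs."""

    def normal_pdf(x: float, mean: float, var: float) -> float:
        return math.exp(-((x - mean) ** 2) / (2 * var)) / math.sqrt(2 * math.pi * var)

    l1 = normal_pdf(s, mu1, sigma1_sq)
    l0 = normal_pdf(s, r, sigma0_sq)
    if mode == "promoter":
        l1 *= lambda_ * math.exp(-lambda_ * abs(d))
        l0 *= 1.0 / d_P
    elif mode == "enhancer":
        l1 *= 1.0 / d_E
        l0 *= 1.0 / d_E
    num = l1 * prior_b1
    den = num + l0 * (1.0 - prior_b1)
    return num / den


def brute_force_window_counts(
    positions: list[int], n_windows: int, window_size: int
) -> list[int]:
    """Per-window 5' position counts by exhaustive scan."""
    counts = [0] * n_windows
    for pos in positions:
        for w in range(n_windows):
            if w * window_size <= pos < (w + 1) * window_size:
                counts[w] += 1
    return counts


def brute_force_wg_regions(
    positions: list[int], chrom_length: int, window_size: int
) -> list[tuple[int, int, int]]:
    """Genome-wide candidate regions as (start, end, read_count).

    Maximal runs of read-bearing windows, kept when they hold >= 2 reads.
    """
    n_windows = (chrom_length + window_size - 1) // window_size
    counts = brute_force_window_counts(positions, n_windows, window_size)
    regions = []
    w = 0
    while w < n_windows:
        if counts[w] > 0:
            start = w
            total = 0
            while w < n_windows and counts[w] > 0:
                total += counts[w]
                w += 1
            if total >= 2:
                regions.append((start * window_size, w * window_size, total))
        else:
            w += 1
    return regions


def brute_force_nearest_tss(
    midpoint: int, tss_list: list[tuple[int, str, str]]
) -> tuple[int, str]:
    """Signed distance and gene of the nearest TSS.

    ``tss_list`` holds (position, strand, gene_id); ties break toward the
    lexicographically smaller gene id.  Negative distance means upstream of
    the gene.
    """
    best = None
    for pos, strand, gene in tss_list:
        key = (abs(midpoint - pos), gene)
        if best is None or key < best[0]:
            d = midpoint - pos if strand == "+" else pos - midpoint
            best = (key, d, gene)
    return best[1], best[2]
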