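"""End-to-end peak calling: SAM pair in, scored BED peaks out."""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Sequence

from . import genome_io, mixture_model, peak_assembly, windowing
from .genome_io import Peak
from .mixture_model import EmTrace, MixtureParams
from .windowing import Window

__all__ = ["PeakCallingResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class PeakCallingResult:
    peaks: list[Peak]
    params: MixtureParams
    trace: EmTrace
    windows: Sequence[Window]
    n_regions: int
    sample_library: int
    input_library: int


def run_pipeline(
    sample_sam: str | os.PathLike,
    input_sam: str | os.PathLike,
    mode: str,
    tss_path: str | os.PathLike | None = None,
    enhancer_path: str | os.PathLike | None = None,
    window_size: int = 50,
    d_P: int = 20_000,
    d_E: int = 2_000,
    threshold: float = 0.9,
    min_mapq: int = 10,
    dedup: bool = False,
    extend: int = 0,
    tol: float = 0.05,
    max_iter: int = 100,
    soft: bool = False,
    score: str = "max",
    max_gap: int = 0,
    relabel_threshold: float = 0.9,
    sigma0_depth_calibration: bool = True,
) -> PeakCallingResult:
    """Run ingest → candidate regions → windows → EM → peak assembly.

    ``mode`` is one of promoter / enhancer / wg; the first two require the
    corresponding annotation path.  Returns peaks plus the fitted model and
    EM trace for diagnostics.

    The background variance fed to the model is the input-window variance
    scaled by (1 + input_library / sample_library): the background
    component's mean is the window's own input intensity, itself a noisy
    estimate, so the residual s - r carries counting variance from both
    profiles.  Under Poisson sampling that factor is exact; disable with
    ``sigma0_depth_calibration=False`` to use the raw input variance.
    """
    if mode == "promoter" and tss_path is None:
        raise ValueError("promoter mode requires a TSS annotation file")
    if mode == "enhancer" and enhancer_path is None:
        raise ValueError("enhancer mode requires an enhancer annotation file")

    sample_reads = genome_io.read_sam(sample_sam, min_mapq=min_mapq, dedup=dedup)
    input_reads = genome_io.read_sam(input_sam, min_mapq=min_mapq, dedup=dedup)
    tss = genome_io.read_tss(tss_path) if tss_path else None
    enhancers = genome_io.read_enhancers(enhancer_path) if enhancer_path else None

    sample_pos = windowing.five_prime_positions(sample_reads, extend=extend)
    input_pos = windowing.five_prime_positions(input_reads, extend=extend)

    regions = windowing.find_candidate_regions(
        sample_pos,
        mode,
        tss=tss,
        enhancers=enhancers,
        window_size=window_size,
        d_P=d_P,
        d_E=d_E,
    )
    logger.info("%d candidate regions", len(regions))
    windows = windowing.build_windows(
        regions,
        sample_pos,
        input_pos,
        sample_library=len(sample_reads),
        input_library=len(input_reads),
        mode=mode,
        window_size=window_size,
        tss=tss,
        enhancers=enhancers,
    )
    logger.info("%d windows", len(windows))

    sigma0_sq = mixture_model.estimate_sigma0([w.r for w in windows])
    if sigma0_depth_calibration:
        sigma0_sq *= 1.0 + len(input_reads) / len(sample_reads)
    params0 = mixture_model.init_params(
        windows, mode, sigma0_sq=sigma0_sq, d_P=float(d_P), d_E=float(d_E)
    )
    params, trace, windows = mixture_model.em_fit(
        windows,
        mode,
        params0=params0,
        tol=tol,
        max_iter=max_iter,
        soft=soft,
        relabel_threshold=relabel_threshold,
    )
    for it in trace.iterations:
        logger.info(
            "EM iter %d: mu1=%.4g sigma1_sq=%.4g lambda=%.4g n_bound=%d max_rel_change=%.4g",
            it.iteration, it.mu1, it.sigma1_sq, it.lambda_, it.n_bound, it.max_rel_change,
        )
    if not trace.converged:
        logger.warning(
            "EM did not converge within %d iterations; reporting peaks from the last iteration",
            max_iter,
        )

    peaks = peak_assembly.call_peaks(
        windows, threshold=threshold, mode=mode, score=score, max_gap=max_gap
    )
    if mode == "promoter" and tss:
        peaks = peak_assembly.assign_target_genes(peaks, tss)
    logger.info("%d peaks above posterior %.2f", len(peaks), threshold)
    return PeakCallingResult(
        peaks=peaks,
        params=params,
        trace=trace,
        windows=windows,
        n_regions=len(regions),
        sample_library=len(sample_reads),
        input_library=len(input_reads),
    )
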