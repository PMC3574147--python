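"""RPKM quantification and enrichment scoring of peaks.

Each peak is quantified in the pull-down (IP) and mock-control samples as
reads per kilobase per million mapped reads (RPKM); the IP/control RPKM
ratio is the enrichment score.  A read counts toward a peak if its interval
overlaps the peak by at least one base -- reads (~35 nt) are short relative
to peaks (>=50 nt), and any-overlap counting is monotone and simple.  When
the control has zero reads in a peak the control count is floored at
``control_pseudocount`` so the ratio stays finite.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .model import Peak, PipelineConfig, ReadSet, ValidationError


def rpkm(count: int, length: int, total_mapped: int) -> float:
    """Reads per kilobase of interval per million mapped reads.

    rpkm = count * 1e9 / (length * total_mapped)
    """
    if length <= 0:
        raise ValidationError("rpkm: interval length must be positive")
    if total_mapped <= 0:
        raise ValidationError("rpkm: total_mapped must be positive")
    return count * 1e9 / (length * total_mapped)


def count_reads_in_peak(reads: ReadSet, peak: Peak) -> int:
    """Number of reads overlapping [peak.start, peak.end] by >= 1 bp."""
    return int(
        count_reads_in_intervals(
            reads, np.array([peak.start]), np.array([peak.end])
        )[0]
    )


def count_reads_in_intervals(
    reads: ReadSet, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Vectorized any-overlap read counts for many intervals.

    A read [s, e] overlaps interval [S, E] iff s <= E and e >= S.
    """
    read_starts = np.sort(reads.starts)
    read_ends = np.sort(reads.ends)
    # reads starting at or before each interval end ...
    n_start_ok = np.searchsorted(read_starts, ends, side="right")
    # ... minus those that already ended before the interval start
    n_ended_before = np.searchsorted(read_ends, starts, side="left")
    return n_start_ok - n_ended_before


def score_peak(
    peak: Peak, ip: ReadSet, ctrl: ReadSet, config: PipelineConfig
) -> Peak:
    """Fill counts, RPKM values and the RPKM ratio of one peak (in place)."""
    score_peaks([peak], ip, ctrl, config)
    return peak


def score_peaks(
    peaks: Sequence[Peak], ip: ReadSet, ctrl: ReadSet, config: PipelineConfig
) -> list[Peak]:
    """Quantify every peak in both samples and compute enrichment ratios.

    rpkm_ratio = rpkm_ip / rpkm(max(count_ctrl, pseudocount), length, ctrl total);
    the ratio is finite for every peak, and zero when the peak has no IP reads.
    """
    if not peaks:
        return []
    starts = np.array([p.start for p in peaks])
    ends = np.array([p.end for p in peaks])
    counts_ip = count_reads_in_intervals(ip, starts, ends)
    counts_ctrl = count_reads_in_intervals(ctrl, starts, ends)
    for p, c_ip, c_ctrl in zip(peaks, counts_ip, counts_ctrl):
        p.count_ip = int(c_ip)
        p.count_ctrl = int(c_ctrl)
        p.rpkm_ip = rpkm(p.count_ip, p.length, ip.total_mapped)
        p.rpkm_ctrl = rpkm(p.count_ctrl, p.length, ctrl.total_mapped)
        denom = rpkm(
            max(p.count_ctrl, config.control_pseudocount),
            p.length,
            ctrl.total_mapped,
        )
        p.rpkm_ratio = p.rpkm_ip / denom
    return list(peaks)


def filter_enriched(
    peaks: Sequence[Peak], config: PipelineConfig
) -> tuple[list[Peak], list[Peak]]:
    """Partition scored peaks into (enriched, background).

    A peak is enriched when rpkm_ratio >= ratio_threshold (the boundary value
    counts as enriched, keeping the partition exhaustive).
    """
    enriched, background = [], []
    for p in peaks:
        if p.rpkm_ratio is None:
            raise ValidationError(f"peak {p.id} has not been scored")
        (enriched if p.rpkm_ratio >= config.ratio_threshold else background).append(p)
    return enriched, background
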