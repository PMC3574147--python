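"""Run-length peak calling on a coverage track.

A peak is a maximal run of consecutive positions whose depth is at least
``min_depth`` (inclusive: depth exactly at the threshold qualifies), kept
only if the run spans at least ``min_run`` positions.  Sub-threshold gaps of
any size split peaks; no gap merging and no boundary extension beyond the
threshold run is performed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .model import CoverageTrack, Peak, PipelineConfig


def call_peaks(track: CoverageTrack, config: PipelineConfig) -> list[Peak]:
    """Return maximal >=min_depth runs of length >=min_run, sorted by start.

    Peak ids are assigned sequentially in genomic order.
    """
    mask = (track.depth >= config.min_depth).astype(np.int8)
    edges = np.diff(mask, prepend=0, append=0)
    run_starts = np.flatnonzero(edges == 1)  # 0-based
    run_ends = np.flatnonzero(edges == -1) - 1
    peaks: list[Peak] = []
    for s, e in zip(run_starts, run_ends):
        if e - s + 1 >= config.min_run:
            peaks.append(Peak(id=f"peak_{len(peaks) + 1:04d}", start=int(s) + 1, end=int(e) + 1))
    return peaks


def peak_length(peak: Peak) -> int:
    """Length in bp of a 1-based inclusive peak interval (end - start + 1)."""
    return peak.end - peak.start + 1


def union_peaks(*peak_lists: Sequence[Peak]) -> list[Peak]:
    """Merge peak intervals called in any input list into their union.

    Overlapping or bookended intervals collapse into one; ids are reassigned
    in genomic order.  Used to quantify the union of intervals called in
    either sample.
    """
    intervals = sorted((p.start, p.end) for peaks in peak_lists for p in peaks)
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [
        Peak(id=f"peak_{i + 1:04d}", start=s, end=e)
        for i, (s, e) in enumerate(merged)
    ]
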