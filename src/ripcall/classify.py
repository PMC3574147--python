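"""Strand inference from TSS evidence and functional classification of peaks.

The sequencing library is unstranded, so a peak's strand is inferred from an
independently mapped transcription-start-site (TSS) table: a TSS "votes" for
a strand when it is oriented into the peak and lies within ``tss_window`` of
it.  Classification then assigns exactly one category per peak, with
housekeeping RNAs (tRNA/rRNA) taking priority, then annotated sRNAs, then 5'
leader regions (TSS-to-start-codon intervals), then the four ORF overlap
classes, and ``unknown`` for everything else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .model import (
    AMBIGUOUS,
    Feature,
    FeatureKind,
    GenomeAnnotation,
    MINUS,
    PLUS,
    Peak,
    PeakCategory,
    PipelineConfig,
    TssRecord,
)

logger = logging.getLogger(__name__)


def infer_strand(
    peak: Peak, tss: Sequence[TssRecord], config: PipelineConfig
) -> str:
    """Infer a peak's strand from nearby, inward-oriented TSS.

    A ``+`` TSS supports the peak when it lies in
    ``[start - tss_window, end]``; a ``-`` TSS when it lies in
    ``[start, end + tss_window]``.  If exactly one strand has support that
    strand is returned, otherwise ``"ambiguous"``.
    """
    w = config.tss_window
    plus_hit = any(
        t.strand == PLUS and peak.start - w <= t.position <= peak.end for t in tss
    )
    minus_hit = any(
        t.strand == MINUS and peak.start <= t.position <= peak.end + w for t in tss
    )
    if plus_hit and not minus_hit:
        return PLUS
    if minus_hit and not plus_hit:
        return MINUS
    return AMBIGUOUS


@dataclass
class _FeatureIndex:
    tree: IntervalTree

    @classmethod
    def build(cls, annotation: GenomeAnnotation) -> "_FeatureIndex":
        tree = IntervalTree()
        for f in annotation.features:
            tree[f.start : f.end + 1] = f  # half-open internally
        return cls(tree)

    def overlapping(self, start: int, end: int) -> list[Feature]:
        return sorted(
            (iv.data for iv in self.tree.overlap(start, end + 1)),
            key=lambda f: (f.start, f.id),
        )


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and a_end >= b_start


def _codon_intervals(cds: Feature) -> tuple[tuple[int, int], tuple[int, int]]:
    """(start codon, stop codon) intervals: the terminal 3 coding bases in
    strand orientation."""
    left = (cds.start, cds.start + 2)
    right = (cds.end - 2, cds.end)
    return (left, right) if cds.strand == PLUS else (right, left)


def _is_leader(
    peak: Peak,
    strand: str,
    annotation: GenomeAnnotation,
    tss: Sequence[TssRecord],
    config: PipelineConfig,
) -> bool:
    """Peak lies between a same-strand TSS and its downstream CDS start."""
    cds = annotation.features_of(FeatureKind.CDS)
    for t in tss:
        if t.strand != strand:
            continue
        if strand == PLUS:
            if t.position > peak.start:
                continue
            for f in cds:
                if f.strand != PLUS:
                    continue
                dist = f.start - t.position
                if 0 < dist <= config.leader_max_length and f.start > peak.end:
                    if t.position <= peak.start and peak.end <= f.start - 1:
                        return True
        else:
            if t.position < peak.end:
                continue
            for f in cds:
                if f.strand != MINUS:
                    continue
                dist = t.position - f.end
                if 0 < dist <= config.leader_max_length and f.end < peak.start:
                    if peak.start >= f.end + 1 and peak.end <= t.position:
                        return True
    return False


def classify_peak(
    peak: Peak,
    annotation: GenomeAnnotation,
    strand: str,
    config: PipelineConfig,
    tss: Sequence[TssRecord] = (),
    index: "_FeatureIndex | None" = None,
) -> PeakCategory:
    """Assign one category to a peak; the first matching rule wins.

    Priority: tRNA/rRNA overlap > sRNA overlap > 5' leader > ORF classes >
    unknown.  ORF classes are evaluated against strand-compatible overlapping
    CDS features (any strand when the peak strand is ambiguous): a peak
    containing the whole CDS is ``orf_full``; overlapping the start codon but
    not the stop codon is ``orf_start``; the stop but not the start is
    ``orf_stop``; touching neither codon while inside the CDS is
    ``orf_internal``.  A peak overlapping both codons without containing the
    CDS falls through to ``unknown``.
    """
    if index is None:
        index = _FeatureIndex.build(annotation)
    overlapping = index.overlapping(peak.start, peak.end)

    if any(f.kind in (FeatureKind.TRNA, FeatureKind.RRNA) for f in overlapping):
        return PeakCategory.TRNA_RRNA
    if any(f.kind is FeatureKind.SRNA for f in overlapping):
        return PeakCategory.SRNA
    if strand in (PLUS, MINUS) and _is_leader(peak, strand, annotation, tss, config):
        return PeakCategory.LEADER

    candidates = [
        f
        for f in overlapping
        if f.kind is FeatureKind.CDS and (strand == AMBIGUOUS or f.strand == strand)
    ]
    for rule in ("full", "start", "stop", "internal"):
        for f in candidates:
            start_codon, stop_codon = _codon_intervals(f)
            hits_start = _overlaps(peak.start, peak.end, *start_codon)
            hits_stop = _overlaps(peak.start, peak.end, *stop_codon)
            contains = peak.start <= f.start and peak.end >= f.end
            inside = peak.start >= f.start and peak.end <= f.end
            if rule == "full" and contains:
                return PeakCategory.ORF_FULL
            if rule == "start" and hits_start and not hits_stop:
                return PeakCategory.ORF_START
            if rule == "stop" and hits_stop and not hits_start:
                return PeakCategory.ORF_STOP
            if rule == "internal" and inside and not hits_start and not hits_stop:
                return PeakCategory.ORF_INTERNAL
    if candidates:
        logger.debug(
            "peak %s overlaps CDS %s but matches no ORF rule; classified unknown",
            peak.id,
            [f.id for f in candidates],
        )
    return PeakCategory.UNKNOWN


def classify_peaks(
    peaks: Sequence[Peak],
    annotation: GenomeAnnotation,
    tss: Sequence[TssRecord],
    config: PipelineConfig,
) -> list[Peak]:
    """Infer strand and classify every peak (in place)."""
    index = _FeatureIndex.build(annotation)
    for p in peaks:
        p.strand = infer_strand(p, tss, config)
        p.category = classify_peak(p, annotation, p.strand, config, tss, index)
    return list(peaks)


@dataclass
class CategorySummary:
    """Per-category peak statistics plus overall partition medians."""

    by_category: pd.DataFrame
    enriched_median_ratio: float | None = None
    background_median_ratio: float | None = None


def summarize_categories(
    peaks: Sequence[Peak], config: PipelineConfig | None = None
) -> CategorySummary:
    """Count, proportion, length stats and median ratio per category.

    Proportions sum to 1 over non-empty input; an empty peak list yields an
    empty table.  When a config is given, overall median ratios are also
    reported separately for the enriched and background partitions.
    """
    columns = [
        "category",
        "count",
        "proportion",
        "min_length",
        "max_length",
        "mean_length",
        "median_rpkm_ratio",
    ]
    if not peaks:
        return CategorySummary(pd.DataFrame(columns=columns))
    df = pd.DataFrame(
        {
            "category": [
                p.category.value if p.category else "" for p in peaks
            ],
            "length": [p.length for p in peaks],
            "rpkm_ratio": [p.rpkm_ratio for p in peaks],
        }
    )
    grouped = (
        df.groupby("category", sort=True)
        .agg(
            count=("length", "size"),
            min_length=("length", "min"),
            max_length=("length", "max"),
            mean_length=("length", "mean"),
            median_rpkm_ratio=("rpkm_ratio", "median"),
        )
        .reset_index()
    )
    grouped.insert(2, "proportion", grouped["count"] / len(peaks))
    summary = CategorySummary(grouped[columns])
    if config is not None and df["rpkm_ratio"].notna().all():
        enriched = df.loc[df["rpkm_ratio"] >= config.ratio_threshold, "rpkm_ratio"]
        background = df.loc[df["rpkm_ratio"] < config.ratio_threshold, "rpkm_ratio"]
        summary.enriched_median_ratio = (
            float(enriched.median()) if len(enriched) else None
        )
        summary.background_median_ratio = (
            float(background.median()) if len(background) else None
        )
    return summary
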