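"""Core data model for the coIP-seq enrichment pipeline.

Coordinates are 1-based inclusive throughout the package; BED and bedGraph
files are converted at the I/O boundary.  A single circular bacterial
chromosome is treated as a linear sequence (no origin-spanning intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

import numpy as np

PLUS = "+"
MINUS = "-"
AMBIGUOUS = "ambiguous"


class ValidationError(ValueError):
    """An object violates one of the model invariants."""


class ParseError(ValueError):
    """An input file could not be parsed."""


class UsageError(ValueError):
    """Invalid combination of arguments or file dialects."""


class ConfigurationError(ValueError):
    """A configuration is internally inconsistent or infeasible."""


class FeatureKind(str, Enum):
    CDS = "CDS"
    TRNA = "tRNA"
    RRNA = "rRNA"
    SRNA = "sRNA"


class PeakCategory(str, Enum):
    """Functional classes assigned to called peaks.

    ``trna_rrna`` covers the abundant housekeeping RNAs that dominate both
    libraries but are not enriched by the pull-down.  The four ``orf_*``
    classes subdivide peaks overlapping protein-coding genes by their
    position relative to the start and stop codons.
    """

    TRNA_RRNA = "trna_rrna"
    SRNA = "srna"
    LEADER = "leader"
    ORF_FULL = "orf_full"
    ORF_START = "orf_start"
    ORF_STOP = "orf_stop"
    ORF_INTERNAL = "orf_internal"
    UNKNOWN = "unknown"


def _check_strand(strand: str) -> None:
    if strand not in (PLUS, MINUS):
        raise ValidationError(f"strand must be '+' or '-', got {strand!r}")


@dataclass(frozen=True)
class Feature:
    """A genomic feature with 1-based inclusive coordinates."""

    id: str
    kind: FeatureKind
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"feature {self.id}: invalid interval {self.start}-{self.end}"
            )
        _check_strand(self.strand)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAnnotation:
    """Typed features of a single-replicon genome."""

    genome_id: str
    genome_length: int
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValidationError("genome_length must be positive")
        seen: set[str] = set()
        for f in self.features:
            if f.end > self.genome_length:
                raise ValidationError(
                    f"feature {f.id} extends past genome end "
                    f"({f.end} > {self.genome_length})"
                )
            if f.id in seen:
                raise ValidationError(f"duplicate feature id {f.id!r}")
            seen.add(f.id)

    def features_of(self, *kinds: FeatureKind) -> list[Feature]:
        return [f for f in self.features if f.kind in kinds]


@dataclass(frozen=True)
class TssRecord:
    """An experimentally mapped transcription start site."""

    position: int
    strand: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError("TSS position must be >= 1")
        _check_strand(self.strand)


@dataclass(frozen=True)
class ReadAlignment:
    """A mapped read interval, 1-based inclusive."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(f"invalid read interval {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ReadSet:
    """Uniquely mapped reads of one sample.

    Reads are held as parallel numpy arrays of start/end coordinates for
    speed; :attr:`reads` materializes :class:`ReadAlignment` objects.
    ``total_mapped`` is the denominator used for RPKM normalization and
    equals the number of retained reads when nothing was filtered.
    """

    sample_label: str
    starts: np.ndarray
    ends: np.ndarray
    total_mapped: int

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if self.starts.shape != self.ends.shape:
            raise ValidationError("starts and ends must have equal length")
        if self.starts.size and (
            (self.starts < 1).any() or (self.ends < self.starts).any()
        ):
            bad = int(np.flatnonzero((self.starts < 1) | (self.ends < self.starts))[0])
            raise ValidationError(
                f"read {bad} has invalid interval "
                f"{int(self.starts[bad])}-{int(self.ends[bad])}"
            )
        if self.total_mapped < len(self.starts):
            raise ValidationError(
                "total_mapped cannot be smaller than the number of retained reads"
            )
        if self.total_mapped < 1:
            raise ValidationError("total_mapped must be positive")

    @classmethod
    def from_intervals(
        cls,
        sample_label: str,
        intervals: Iterable[tuple[int, int]],
        total_mapped: int | None = None,
    ) -> "ReadSet":
        pairs = list(intervals)
        starts = np.array([p[0] for p in pairs], dtype=np.int64)
        ends = np.array([p[1] for p in pairs], dtype=np.int64)
        return cls(sample_label, starts, ends, total_mapped or max(len(pairs), 1))

    def __len__(self) -> int:
        return int(self.starts.size)

    def __iter__(self) -> Iterator[ReadAlignment]:
        return iter(self.reads)

    @property
    def reads(self) -> list[ReadAlignment]:
        return [
            ReadAlignment(int(s), int(e)) for s, e in zip(self.starts, self.ends)
        ]

    @property
    def read_lengths(self) -> np.ndarray:
        return self.ends - self.starts + 1


@dataclass
class CoverageTrack:
    """Strand-collapsed per-base read depth.

    ``depth[i]`` is the number of reads covering 1-based position ``i + 1``.
    """

    genome_length: int
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.shape != (self.genome_length,):
            raise ValidationError("depth array length must equal genome_length")

    @classmethod
    def zeros(cls, genome_length: int) -> "CoverageTrack":
        return cls(genome_length, np.zeros(genome_length, dtype=np.int64))

    def depth_at(self, position: int) -> int:
        """Depth at a 1-based genomic position."""
        return int(self.depth[position - 1])

    def __add__(self, other: "CoverageTrack") -> "CoverageTrack":
        if other.genome_length != self.genome_length:
            raise ValidationError("cannot add tracks of different genome lengths")
        return CoverageTrack(self.genome_length, self.depth + other.depth)


@dataclass
class Peak:
    """A called coverage peak, possibly scored and classified."""

    id: str
    start: int
    end: int
    strand: str = AMBIGUOUS
    count_ip: int | None = None
    count_ctrl: int | None = None
    rpkm_ip: float | None = None
    rpkm_ctrl: float | None = None
    rpkm_ratio: float | None = None
    category: PeakCategory | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"peak {self.id}: invalid interval {self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PipelineConfig:
    """Tunable analysis parameters.

    min_depth / min_run define a peak as at least ``min_depth`` reads over at
    least ``min_run`` consecutive positions.  ``ratio_threshold`` is the
    RPKM-ratio enrichment cutoff (inclusive).  ``control_pseudocount``
    regularizes the control denominator so ratios stay finite.
    ``leader_max_length`` bounds the TSS-to-start-codon distance when calling
    a peak a 5' leader; ``tss_window`` is how far upstream of a peak a TSS may
    sit and still vote for that peak's strand.
    """

    min_depth: int = 5
    min_run: int = 50
    ratio_threshold: float = 2.0
    control_pseudocount: int = 1
    leader_max_length: int = 500
    tss_window: int = 500

    def __post_init__(self) -> None:
        for name in (
            "min_depth",
            "min_run",
            "ratio_threshold",
            "control_pseudocount",
            "leader_max_length",
            "tss_window",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
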