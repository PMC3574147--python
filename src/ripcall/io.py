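"""Readers and writers for the external file formats the pipeline touches.

Conventions
-----------
* internal coordinates: 1-based inclusive
* GFF3, SAM, TSS table, peak table: 1-based inclusive
* BED, bedGraph: 0-based half-open, converted at this boundary

Only single-replicon genomes are supported; SAM input with more than one
reference sequence is rejected.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .model import (
    AMBIGUOUS,
    CoverageTrack,
    Feature,
    FeatureKind,
    GenomeAnnotation,
    ParseError,
    Peak,
    PeakCategory,
    ReadSet,
    TssRecord,
    UsageError,
    ValidationError,
)

logger = logging.getLogger(__name__)

_KNOWN_KINDS = {k.value: k for k in FeatureKind}

PEAK_TABLE_COLUMNS = [
    "id",
    "start",
    "end",
    "length",
    "strand",
    "category",
    "count_ip",
    "count_ctrl",
    "rpkm_ip",
    "rpkm_ctrl",
    "rpkm_ratio",
]


# ---------------------------------------------------------------------------
# GFF3 annotation
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> GenomeAnnotation:
    """Read a GFF3 file into a :class:`GenomeAnnotation`.

    Features of unknown type are skipped with a logged warning.  The genome
    length is taken from a ``##sequence-region`` directive when present,
    otherwise from the rightmost feature end.
    """
    path = Path(path)
    genome_id: str | None = None
    genome_length: int | None = None
    features: list[Feature] = []
    auto_id = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    genome_id = parts[1]
                    try:
                        genome_length = int(parts[3])
                    except ValueError as exc:
                        raise ParseError(
                            f"{path}: line {lineno}: bad sequence-region length"
                        ) from exc
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            if genome_id is None:
                genome_id = seqid
            if ftype not in _KNOWN_KINDS:
                logger.warning(
                    "%s: line %d: skipping feature of unknown type %r",
                    path,
                    lineno,
                    ftype,
                )
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if end < start:
                raise ValidationError(
                    f"{path}: line {lineno}: end < start ({end} < {start})"
                )
            fid = None
            for field in attrs.split(";"):
                key, _, value = field.partition("=")
                if key.strip() in ("ID", "Name") and value:
                    fid = value.strip()
                    break
            if fid is None:
                auto_id += 1
                fid = f"feature_{auto_id}"
            features.append(Feature(fid, _KNOWN_KINDS[ftype], start, end, strand))
    if genome_id is None:
        genome_id = "genome"
    if genome_length is None:
        genome_length = max((f.end for f in features), default=1)
        logger.warning(
            "%s: no ##sequence-region directive; using genome_length=%d",
            path,
            genome_length,
        )
    return GenomeAnnotation(genome_id, genome_length, features)


def write_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write an annotation as GFF3 (round-trips with :func:`read_annotation`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(
            f"##sequence-region {annotation.genome_id} 1 "
            f"{annotation.genome_length}\n"
        )
        for f in annotation.features:
            fh.write(
                f"{annotation.genome_id}\tripcall\t{f.kind.value}\t{f.start}\t"
                f"{f.end}\t.\t{f.strand}\t.\tID={f.id}\n"
            )


# ---------------------------------------------------------------------------
# TSS table
# ---------------------------------------------------------------------------

def read_tss(path: str | Path) -> list[TssRecord]:
    """Read a two-column TSV of transcription start sites (position, strand)."""
    path = Path(path)
    records: list[TssRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ParseError(f"{path}: line {lineno}: expected position<TAB>strand")
            try:
                position = int(cols[0])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer TSS position"
                ) from exc
            records.append(TssRecord(position, cols[1]))
    return records


def write_tss(records: Sequence[TssRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.position}\t{r.strand}\n")


# ---------------------------------------------------------------------------
# Read alignments (SAM / BED)
# ---------------------------------------------------------------------------

def read_reads(
    path: str | Path,
    sample_label: str,
    dialect: str | None = None,
) -> ReadSet:
    """Load mapped reads from SAM (1-based) or 3-column BED (0-based half-open).

    The dialect is inferred from the ``.sam`` / ``.bed`` extension unless
    given explicitly.  SAM records that are unmapped or have mapping quality
    zero (multi-mapped under bwa conventions) are excluded; ``total_mapped``
    is the number of retained reads.
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower().lstrip(".")
        if suffix in ("sam", "bed"):
            dialect = suffix
        else:
            raise UsageError(
                f"cannot infer read format from extension {path.suffix!r}; "
                "pass dialect='sam' or dialect='bed'"
            )
    if dialect == "sam":
        return _read_sam(path, sample_label)
    if dialect == "bed":
        return _read_bed(path, sample_label)
    raise UsageError(f"unknown read dialect {dialect!r}")


def _read_sam(path: Path, sample_label: str) -> ReadSet:
    starts: list[int] = []
    ends: list[int] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        if sam.header.nreferences > 1:
            raise ValidationError(
                f"{path}: {sam.header.nreferences} reference sequences; "
                "only single-replicon genomes are supported"
            )
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.mapping_quality == 0:
                continue
            ref_end = aln.reference_end
            if ref_end is None:
                continue
            starts.append(aln.reference_start + 1)
            ends.append(ref_end)
    return ReadSet(
        sample_label,
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        max(len(starts), 1),
    )


def _read_bed(path: Path, sample_label: str) -> ReadSet:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame({"chrom": [], "start": [], "end": []})
    if df["chrom"].nunique() > 1:
        raise ValidationError(
            f"{path}: multiple chromosomes; only single-replicon genomes "
            "are supported"
        )
    starts = df["start"].to_numpy(dtype=np.int64) + 1  # 0-based -> 1-based
    ends = df["end"].to_numpy(dtype=np.int64)  # half-open end == inclusive end
    return ReadSet(sample_label, starts, ends, max(len(starts), 1))


def write_reads_sam(
    reads: ReadSet,
    path: str | Path,
    genome_id: str,
    genome_length: int,
) -> None:
    """Write reads as unpaired, forward-flag SAM records (MAPQ 60, ``nM``)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": genome_id, "LN": int(genome_length)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, (s, e) in enumerate(zip(reads.starts, reads.ends)):
            aln = pysam.AlignedSegment(out.header)
            aln.query_name = f"{reads.sample_label}_{i}"
            aln.flag = 0
            aln.reference_id = 0
            aln.reference_start = int(s) - 1
            aln.mapping_quality = 60
            aln.cigar = [(0, int(e - s + 1))]
            out.write(aln)


def write_reads_bed(reads: ReadSet, path: str | Path, genome_id: str) -> None:
    with open(path, "w") as fh:
        for s, e in zip(reads.starts, reads.ends):
            fh.write(f"{genome_id}\t{int(s) - 1}\t{int(e)}\n")


# ---------------------------------------------------------------------------
# Peak table
# ---------------------------------------------------------------------------

def _format_float(x: float | None, sig: str) -> str:
    return "" if x is None else format(x, sig)


def peaks_to_frame(peaks: Sequence[Peak]) -> pd.DataFrame:
    """Tabulate peaks with the standard column set (coordinates 1-based)."""
    rows = []
    for p in peaks:
        rows.append(
            {
                "id": p.id,
                "start": p.start,
                "end": p.end,
                "length": p.length,
                "strand": p.strand,
                "category": p.category.value if p.category else "",
                "count_ip": p.count_ip,
                "count_ctrl": p.count_ctrl,
                "rpkm_ip": p.rpkm_ip,
                "rpkm_ctrl": p.rpkm_ctrl,
                "rpkm_ratio": p.rpkm_ratio,
            }
        )
    return pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS)


def write_peak_table(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write the peak TSV; rpkm_ratio is printed to 3 significant figures."""
    with open(path, "w") as fh:
        fh.write("\t".join(PEAK_TABLE_COLUMNS) + "\n")
        for p in peaks:
            fields = [
                p.id,
                str(p.start),
                str(p.end),
                str(p.length),
                p.strand,
                p.category.value if p.category else "",
                "" if p.count_ip is None else str(p.count_ip),
                "" if p.count_ctrl is None else str(p.count_ctrl),
                _format_float(p.rpkm_ip, ".6g"),
                _format_float(p.rpkm_ctrl, ".6g"),
                _format_float(p.rpkm_ratio, ".3g"),
            ]
            fh.write("\t".join(fields) + "\n")


def read_peak_table(path: str | Path) -> list[Peak]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = set(PEAK_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing peak-table columns {sorted(missing)}")
    peaks = []
    for row in df.itertuples(index=False):
        category = None
        if isinstance(row.category, str) and row.category:
            category = PeakCategory(row.category)
        peaks.append(
            Peak(
                id=row.id,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand if isinstance(row.strand, str) else AMBIGUOUS,
                count_ip=None if pd.isna(row.count_ip) else int(row.count_ip),
                count_ctrl=None if pd.isna(row.count_ctrl) else int(row.count_ctrl),
                rpkm_ip=None if pd.isna(row.rpkm_ip) else float(row.rpkm_ip),
                rpkm_ctrl=None if pd.isna(row.rpkm_ctrl) else float(row.rpkm_ctrl),
                rpkm_ratio=None if pd.isna(row.rpkm_ratio) else float(row.rpkm_ratio),
                category=category,
            )
        )
    return peaks


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(
    track: CoverageTrack,
    path: str | Path,
    genome_id: str = "genome",
) -> None:
    """Write coverage as bedGraph (0-based half-open), omitting zero runs.

    Consecutive positions of equal depth are collapsed into one interval,
    so sum(interval length x depth) over the file equals sum(track depth).
    """
    depth = np.asarray(track.depth)
    with open(path, "w") as fh:
        if depth.size == 0:
            return
        change = np.flatnonzero(np.diff(depth)) + 1
        bounds = np.concatenate(([0], change, [depth.size]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            d = depth[lo]
            if d != 0:
                fh.write(f"{genome_id}\t{lo}\t{hi}\t{d}\n")


# ---------------------------------------------------------------------------
# Truth BED (simulator ground truth)
# ---------------------------------------------------------------------------

def write_truth_bed(truth, path: str | Path, genome_id: str = "genome") -> None:
    """Write ground-truth regions as BED6 with the fold in the score column."""
    with open(path, "w") as fh:
        for r in truth.regions:
            fh.write(
                f"{genome_id}\t{r.start - 1}\t{r.end}\t{r.category}\t"
                f"{format(r.fold, 'g')}\t{r.strand}\n"
            )
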