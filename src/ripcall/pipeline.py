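"""End-to-end orchestration: simulate/load -> coverage -> call -> score ->
classify -> summarize, with a JSON run manifest.

Runs are deterministic for a fixed seed and fixed inputs; the manifest
records the configuration snapshot, sha256 digests of every input file, and
record counts at each stage so reruns can be audited.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io
from ._version import __version__
from .classify import classify_peaks, summarize_categories
from .coverage import compute_coverage
from .enrichment import filter_enriched, score_peaks
from .model import GenomeAnnotation, Peak, PipelineConfig, ReadSet, UsageError
from .peaks import call_peaks, union_peaks
from .simulate import SimulationConfig, generate_annotation, simulate_reads

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    tool_version: str
    seed: int | None
    config: dict
    inputs: dict[str, str]  # file name -> sha256
    counts: dict
    medians: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineResult:
    annotation: GenomeAnnotation
    peaks: list[Peak]
    enriched: list[Peak]
    background: list[Peak]
    manifest: RunManifest
    out_dir: Path


def run_pipeline(
    out_dir: str | Path,
    sim_config: SimulationConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
    annotation_path: str | Path | None = None,
    tss_path: str | Path | None = None,
    ip_path: str | Path | None = None,
    ctrl_path: str | Path | None = None,
    genome_length: int | None = None,
    ip_only: bool = False,
    read_format: str = "sam",
) -> PipelineResult:
    """Run all stages and write outputs into ``out_dir``.

    Either ``sim_config`` is given (inputs are synthesized and also written
    to ``out_dir``) or paths to annotation, TSS table and both read files
    are given.  ``ip_only`` restricts quantification to IP-called intervals;
    by default the union of intervals called in either sample is scored in
    both.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = pipeline_config or PipelineConfig()
    input_digests: dict[str, str] = {}

    if sim_config is not None:
        annotation, tss, truth = generate_annotation(sim_config)
        ip, ctrl = simulate_reads(annotation, truth, sim_config)
        io.write_annotation(annotation, out_dir / "annotation.gff3")
        io.write_tss(tss, out_dir / "tss.tsv")
        io.write_truth_bed(truth, out_dir / "truth.bed", annotation.genome_id)
        if read_format == "sam":
            io.write_reads_sam(
                ip, out_dir / "ip.sam", annotation.genome_id, annotation.genome_length
            )
            io.write_reads_sam(
                ctrl,
                out_dir / "ctrl.sam",
                annotation.genome_id,
                annotation.genome_length,
            )
        else:
            io.write_reads_bed(ip, out_dir / "ip.bed", annotation.genome_id)
            io.write_reads_bed(ctrl, out_dir / "ctrl.bed", annotation.genome_id)
        seed = sim_config.seed
    else:
        if not (annotation_path and tss_path and ip_path and ctrl_path):
            raise UsageError(
                "without a simulation config, annotation, TSS and both read "
                "files are required"
            )
        for p in (annotation_path, tss_path, ip_path, ctrl_path):
            p = Path(p)
            if not p.exists():
                raise UsageError(f"input file not found: {p}")
            input_digests[p.name] = _sha256(p)
        annotation = io.read_annotation(annotation_path)
        if genome_length:
            annotation.genome_length = genome_length
        tss = io.read_tss(tss_path)
        ip = io.read_reads(ip_path, "ip")
        ctrl = io.read_reads(ctrl_path, "ctrl")
        seed = None

    logger.info("reads: ip=%d ctrl=%d", len(ip), len(ctrl))
    ip_track = compute_coverage(ip, annotation.genome_length)
    ctrl_track = compute_coverage(ctrl, annotation.genome_length)
    io.write_bedgraph(ip_track, out_dir / "ip.bedgraph", annotation.genome_id)
    io.write_bedgraph(ctrl_track, out_dir / "ctrl.bedgraph", annotation.genome_id)

    ip_peaks = call_peaks(ip_track, config)
    if ip_only:
        peaks = union_peaks(ip_peaks)
    else:
        ctrl_peaks = call_peaks(ctrl_track, config)
        peaks = union_peaks(ip_peaks, ctrl_peaks)
    logger.info("peaks called: %d", len(peaks))

    score_peaks(peaks, ip, ctrl, config)
    enriched, background = filter_enriched(peaks, config)
    classify_peaks(peaks, annotation, tss, config)
    logger.info("peaks enriched: %d", len(enriched))

    io.write_peak_table(peaks, out_dir / "peaks.tsv")
    summary = summarize_categories(enriched, config)
    summary.by_category.to_csv(out_dir / "summary.tsv", sep="\t", index=False)

    all_summary = summarize_categories(peaks, config)
    category_counts = {
        row.category: int(row.count)
        for row in summary.by_category.itertuples(index=False)
    }
    manifest = RunManifest(
        tool_version=__version__,
        seed=seed,
        config={
            "pipeline": dataclasses.asdict(config),
            "simulation": dataclasses.asdict(sim_config) if sim_config else None,
        },
        inputs=input_digests,
        counts={
            "reads_ip": len(ip),
            "reads_ctrl": len(ctrl),
            "peaks_called": len(peaks),
            "peaks_enriched": len(enriched),
            "enriched_categories": category_counts,
        },
        medians={
            "enriched_rpkm_ratio": all_summary.enriched_median_ratio,
            "background_rpkm_ratio": all_summary.background_median_ratio,
        },
    )
    assert manifest.counts["peaks_enriched"] <= manifest.counts["peaks_called"]
    (out_dir / "manifest.json").write_text(manifest.to_json() + "\n")
    return PipelineResult(annotation, peaks, enriched, background, manifest, out_dir)
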