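"""Synthetic coIP-seq data with known ground truth.

The generator emulates the statistical structure of a bacterial pull-down
experiment on a desk-scale genome: a 200 kb single replicon carrying
non-overlapping CDS, tRNA, rRNA and sRNA features; a TSS at the 5' end of
every CDS and sRNA; a designated subset of CDSs preceded by a 200-400 nt 5'
leader whose TSS sits upstream of the start codon (only the structured 5'
portion of the leader is enriched by the pull-down -- the expression
platform before the start codon carries baseline signal); and two unstranded,
~35 nt single-end read libraries of very unequal size (the pull-down library
is several times deeper than the mock control, mirroring the order-of-
magnitude asymmetry of real libraries at 1/100 scale).

Reads are drawn per transcribed region with Poisson counts.  Region rates
are relative expression masses (reads/kb class weights x region length)
normalized to library composition; in the IP sample each ground-truth
enriched region's mass is multiplied by its fold, and the composition is
re-normalized so the expected library size stays fixed -- sequencing depth
is set by the instrument, enrichment only shifts composition.  Housekeeping
RNAs (tRNA/rRNA) carry most of both libraries and have fold 1, so they show
high coverage in both samples with an RPKM ratio near 1.  A uniform
genome-wide noise floor (default 1% of each library) is added to both
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    ConfigurationError,
    Feature,
    FeatureKind,
    GenomeAnnotation,
    MINUS,
    PLUS,
    ReadSet,
    TssRecord,
)

TRNA_LENGTH = 76
RRNA_LENGTH = 2900


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Library sizes default to 1/100 of the real mapped libraries (1e5 IP vs
    1.5e4 control reads) so the full pipeline runs in seconds.  Expression
    densities are relative reads-per-kilobase class weights; housekeeping
    RNAs dominate so that enriched regions make up a small fraction of the
    control library, as in a real mock pull-down.
    """

    genome_length: int = 200_000
    n_cds: int = 32
    n_trna: int = 10
    n_rrna: int = 3
    n_srna: int = 12
    n_leaders: int = 8
    read_length_mean: float = 35.0
    read_length_sd: float = 5.0
    min_read_length: int = 20
    ip_library_size: int = 100_000
    ctrl_library_size: int = 15_000
    noise_fraction: float = 0.01
    enrichment_folds: tuple[float, ...] = (5.0, 20.0, 100.0)
    hk_expression: float = 600.0  # tRNA/rRNA, reads/kb class weight
    mrna_expression: float = 10.0
    srna_expression: float = 20.0
    leader_expression: float = 25.0
    min_spacing: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cds", "n_trna", "n_rrna", "n_srna", "n_leaders"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.ip_library_size <= 0 or self.ctrl_library_size <= 0:
            raise ConfigurationError("library sizes must be positive")
        if any(f <= 0 for f in self.enrichment_folds):
            raise ConfigurationError("enrichment folds must be positive")
        if not 0 <= self.noise_fraction < 1:
            raise ConfigurationError("noise_fraction must be in [0, 1)")


@dataclass(frozen=True)
class TruthRegion:
    """A ground-truth transcribed region with its expected category."""

    start: int
    end: int
    strand: str
    fold: float
    category: str  # "trna_rrna", "srna" or "leader"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SyntheticTruth:
    regions: list[TruthRegion] = field(default_factory=list)

    def enriched(self) -> list[TruthRegion]:
        """Regions designated for pull-down enrichment (sRNAs and leaders)."""
        return [r for r in self.regions if r.category in ("srna", "leader")]


def generate_annotation(
    config: SimulationConfig,
) -> tuple[GenomeAnnotation, list[TssRecord], SyntheticTruth]:
    """Place non-overlapping features on random strands and emit ground truth.

    Each CDS and sRNA receives a TSS at its 5' end; leader CDSs instead get
    their TSS 150-400 bp upstream and the TSS-to-start-codon interval is
    recorded in the truth as a ``leader`` region.  sRNA features and leader
    intervals are the enrichment candidates; folds from
    ``config.enrichment_folds`` are assigned to them cyclically in genomic
    order.  tRNA/rRNA regions enter the truth with fold 1.
    """
    rng = np.random.default_rng(config.seed)

    units: list[dict] = []
    for _ in range(config.n_trna):
        units.append({"kind": "trna", "length": TRNA_LENGTH})
    for _ in range(config.n_rrna):
        units.append({"kind": "rrna", "length": RRNA_LENGTH})
    for _ in range(config.n_cds):
        units.append({"kind": "cds", "length": 3 * int(rng.integers(50, 201))})
    for _ in range(config.n_srna):
        units.append({"kind": "srna", "length": int(rng.integers(100, 301))})
    for _ in range(config.n_leaders):
        # the 5' leader splits into a structured (aptamer-like) domain that
        # is pulled down and an expression platform before the start codon
        # that carries only baseline mRNA signal
        leader_len = int(rng.integers(200, 401))
        platform_len = int(rng.integers(50, 81))
        cds_len = 3 * int(rng.integers(50, 201))
        units.append(
            {
                "kind": "leader_cds",
                "length": leader_len + cds_len,
                "leader_len": leader_len,
                "platform_len": platform_len,
                "cds_len": cds_len,
            }
        )
    rng.shuffle(units)

    n = len(units)
    occupied = sum(u["length"] for u in units)
    needed = occupied + (n + 1) * config.min_spacing
    if needed > config.genome_length:
        raise ConfigurationError(
            f"features need {needed} bp (incl. {config.min_spacing} bp spacing) "
            f"but genome_length is {config.genome_length}"
        )
    slack = config.genome_length - needed
    extra = (
        rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        if n
        else np.array([slack])
    )

    features: list[Feature] = []
    tss: list[TssRecord] = []
    truth_regions: list[TruthRegion] = []
    counters = {"cds": 0, "trna": 0, "rrna": 0, "srna": 0}
    pos = 1
    for i, unit in enumerate(units):
        pos += config.min_spacing + int(extra[i])
        start = pos
        strand = PLUS if rng.integers(2) == 0 else MINUS
        if unit["kind"] == "leader_cds":
            leader_len, cds_len = unit["leader_len"], unit["cds_len"]
            aptamer_len = leader_len - unit["platform_len"]
            if strand == PLUS:
                aptamer = (start, start + aptamer_len - 1)
                cds = (start + leader_len, start + leader_len + cds_len - 1)
                tss.append(TssRecord(start, PLUS))
            else:
                cds = (start, start + cds_len - 1)
                unit_end = start + cds_len + leader_len - 1
                aptamer = (unit_end - aptamer_len + 1, unit_end)
                tss.append(TssRecord(unit_end, MINUS))
            counters["cds"] += 1
            features.append(
                Feature(
                    f"cds_{counters['cds']:03d}", FeatureKind.CDS, *cds, strand
                )
            )
            truth_regions.append(TruthRegion(*aptamer, strand, 1.0, "leader"))
        else:
            kind_map = {
                "cds": FeatureKind.CDS,
                "trna": FeatureKind.TRNA,
                "rrna": FeatureKind.RRNA,
                "srna": FeatureKind.SRNA,
            }
            key = unit["kind"]
            counters[key] += 1
            end = start + unit["length"] - 1
            features.append(
                Feature(f"{key}_{counters[key]:03d}", kind_map[key], start, end, strand)
            )
            if key in ("cds", "srna"):
                five_prime = start if strand == PLUS else end
                tss.append(TssRecord(five_prime, strand))
            if key == "srna":
                truth_regions.append(TruthRegion(start, end, strand, 1.0, "srna"))
            elif key in ("trna", "rrna"):
                truth_regions.append(
                    TruthRegion(start, end, strand, 1.0, "trna_rrna")
                )
        pos += unit["length"]

    # assign folds cyclically to enrichment candidates in genomic order
    truth_regions.sort(key=lambda r: r.start)
    folds = config.enrichment_folds or (1.0,)
    assigned: list[TruthRegion] = []
    k = 0
    for r in truth_regions:
        if r.category in ("srna", "leader"):
            assigned.append(
                TruthRegion(r.start, r.end, r.strand, float(folds[k % len(folds)]), r.category)
            )
            k += 1
        else:
            assigned.append(r)

    features.sort(key=lambda f: f.start)
    tss.sort(key=lambda t: t.position)
    annotation = GenomeAnnotation("synthetic", config.genome_length, features)
    return annotation, tss, SyntheticTruth(assigned)


def _transcribed_regions(
    annotation: GenomeAnnotation, truth: SyntheticTruth, config: SimulationConfig
) -> pd.DataFrame:
    """All transcribed regions with expression mass and enrichment fold."""
    fold_by_interval = {
        (r.start, r.end): r.fold for r in truth.regions
    }
    density = {
        FeatureKind.TRNA: config.hk_expression,
        FeatureKind.RRNA: config.hk_expression,
        FeatureKind.CDS: config.mrna_expression,
        FeatureKind.SRNA: config.srna_expression,
    }
    rows = []
    for f in annotation.features:
        rows.append(
            {
                "start": f.start,
                "end": f.end,
                "density": density[f.kind],
                "fold": fold_by_interval.get((f.start, f.end), 1.0),
            }
        )
    cds = [f for f in annotation.features if f.kind is FeatureKind.CDS]
    for r in truth.regions:
        if r.category != "leader":
            continue
        rows.append(
            {
                "start": r.start,
                "end": r.end,
                "density": config.leader_expression,
                "fold": r.fold,
            }
        )
        # expression platform between the structured domain and the start
        # codon: transcribed at baseline mRNA level, never enriched
        if r.strand == PLUS:
            downstream = [f for f in cds if f.strand == PLUS and f.start > r.end]
            if downstream:
                nxt = min(downstream, key=lambda f: f.start)
                if nxt.start - r.end - 1 > 0:
                    rows.append(
                        {
                            "start": r.end + 1,
                            "end": nxt.start - 1,
                            "density": config.mrna_expression,
                            "fold": 1.0,
                        }
                    )
        else:
            upstream = [f for f in cds if f.strand == MINUS and f.end < r.start]
            if upstream:
                nxt = max(upstream, key=lambda f: f.end)
                if r.start - nxt.end - 1 > 0:
                    rows.append(
                        {
                            "start": nxt.end + 1,
                            "end": r.start - 1,
                            "density": config.mrna_expression,
                            "fold": 1.0,
                        }
                    )
    df = pd.DataFrame(rows, columns=["start", "end", "density", "fold"])
    if len(df):
        df = df.sort_values("start", ignore_index=True)
        df["mass"] = df["density"] * (df["end"] - df["start"] + 1) / 1000.0
    else:
        df["mass"] = pd.Series(dtype=float)
    return df


def expected_region_counts(
    annotation: GenomeAnnotation, truth: SyntheticTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Expected (Poisson mean) read counts per region in each sample.

    Exposes the generative rates so tests can check realized counts against
    their distribution.
    """
    df = _transcribed_regions(annotation, truth, config)
    if not len(df):
        df["lambda_ip"] = pd.Series(dtype=float)
        df["lambda_ctrl"] = pd.Series(dtype=float)
        return df
    mass_ctrl = df["mass"].to_numpy()
    mass_ip = mass_ctrl * df["fold"].to_numpy()
    usable = 1.0 - config.noise_fraction
    df["lambda_ctrl"] = (
        mass_ctrl / mass_ctrl.sum() * usable * config.ctrl_library_size
    )
    df["lambda_ip"] = mass_ip / mass_ip.sum() * usable * config.ip_library_size
    return df


def _draw_region_reads(
    rng: np.random.Generator,
    region_start: np.ndarray,
    region_end: np.ndarray,
    counts: np.ndarray,
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    starts_out, ends_out = [], []
    for s, e, c in zip(region_start, region_end, counts):
        if c == 0:
            continue
        starts = rng.integers(s, e + 1, size=c)
        lengths = np.maximum(
            np.rint(rng.normal(config.read_length_mean, config.read_length_sd, c)),
            config.min_read_length,
        ).astype(np.int64)
        ends = np.minimum(starts + lengths - 1, e)  # clip to region
        starts_out.append(starts)
        ends_out.append(ends)
    if not starts_out:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(starts_out), np.concatenate(ends_out)


def simulate_reads(
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> tuple[ReadSet, ReadSet]:
    """Draw matched IP and mock-control read sets.

    Per-region counts are Poisson with the composition-normalized rates of
    :func:`expected_region_counts`; read starts are uniform within the
    region, lengths truncated-normal and clipped to the region.  A uniform
    genome-wide noise floor of ``noise_fraction`` of each library is added.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rates = expected_region_counts(annotation, truth, config)
    region_start = rates["start"].to_numpy(dtype=np.int64)
    region_end = rates["end"].to_numpy(dtype=np.int64)

    def one_sample(label: str, lam: np.ndarray, library_size: int) -> ReadSet:
        counts = rng.poisson(lam) if lam.size else np.empty(0, dtype=np.int64)
        starts, ends = _draw_region_reads(
            rng, region_start, region_end, counts, config
        )
        n_noise = rng.poisson(config.noise_fraction * library_size)
        if n_noise:
            ns = rng.integers(1, config.genome_length + 1, size=n_noise)
            nl = np.maximum(
                np.rint(
                    rng.normal(
                        config.read_length_mean, config.read_length_sd, n_noise
                    )
                ),
                config.min_read_length,
            ).astype(np.int64)
            ne = np.minimum(ns + nl - 1, config.genome_length)
            starts = np.concatenate([starts, ns])
            ends = np.concatenate([ends, ne])
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        return ReadSet(label, starts, ends, max(len(starts), 1))

    ip = one_sample(
        "ip", rates["lambda_ip"].to_numpy(), config.ip_library_size
    )
    ctrl = one_sample(
        "ctrl", rates["lambda_ctrl"].to_numpy(), config.ctrl_library_size
    )
    return ip, ctrl
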