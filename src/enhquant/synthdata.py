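"""Synthetic fixtures with planted ground truth for every pipeline stage.

The generator emulates a degron ChIP-Rx study design: a set of enhancer loci
on one target chromosome, each with a designated nearest-TSS gene; ChIP read
sets mixing target-genome reads (uniform background plus Poisson enrichment
at loci) with exogenous spike-in reads at the 1:4 cell-mixing design ratio; a
treatment condition in which a planted "sensitive" subset of loci loses a
stated fraction of its enrichment; a differential-expression table in which
the genes of those sensitive loci are planted as downregulated; and peak sets
covering a stated fraction of loci.  Every quantity a pipeline stage should
recover is recorded as ground truth.

Determinism: all randomness flows through numpy PCG64 generators seeded from
``SimConfig.seed`` plus fixed per-stage stream ids (and CRC32 of sample ids),
so identical configs yield identical fixtures on any platform.  Coordinates
live on integer grids.

Per-sample sequencing-depth / IP-efficiency variation is modelled as a single
multiplier drawn uniformly from ``1 +/- depth_jitter`` that scales *both*
expected target and expected spike counts — the cell-mixing ratio is fixed by
the experimental design, so spike counts track library scale.  This is
exactly the situation spike-in downsampling corrects: target reads per spike
read is depth-invariant up to Poisson noise.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .regions import EnhancerLocus, GenomicInterval, TSSRecord
from .sensitivity import DETable
from .spikenorm import ReadSet
from .peaks import PeakRecord
from .stats import DoseGrid

import pandas as pd

__all__ = [
    "SimConfig",
    "Annotation",
    "GroundTruth",
    "generate_annotation",
    "simulate_reads",
    "simulate_de_table",
    "simulate_peaks",
    "simulate_dose_grid",
    "write_dataset",
]

# fixed RNG stream ids so stages draw independent, reproducible streams
_STREAM_ANNOTATION = 0
_STREAM_READS = 1
_STREAM_DE = 2
_STREAM_PEAKS = 3
_STREAM_DOSE = 4


def _crc(text: str) -> int:
    return zlib.crc32(text.encode())


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic degron ChIP-Rx experiment.

    Defaults mirror the emulated study: ~300 enhancer loci of 300-1200 bp
    (some below the 600 bp floor, so extension is exercised), 10x ChIP
    enrichment over background, a 10% sensitive subset losing half its
    enrichment upon treatment, spike-in mixed at the 1:4 design ratio
    (expected spike:target read ratio 0.25) with +/-20% per-sample depth
    jitter, and DE effects of log2fc ~ N(-1.5, 0.3) at sensitive genes
    against a N(0, 0.2) null.
    """

    seed: int = 1
    n_enhancers: int = 300
    locus_width_min: int = 300
    locus_width_max: int = 1200
    target_chrom: str = "chr1"
    target_chrom_length: int = 60_000_000
    spike_chrom: str = "dm6_chr2L"
    spike_chrom_length: int = 1_000_000
    background_density: float = 20.0  # reads per kb of target chromosome
    enrichment: float = 10.0  # fold over background at enhancer loci
    sensitive_fraction: float = 0.1
    depletion: float = 0.5  # enrichment multiplier at sensitive loci, treatment
    spike_ratio: float = 0.25  # expected spike:target read ratio (1:4 mix)
    depth_jitter: float = 0.2  # per-sample uniform depth multiplier half-width
    read_length: int = 75
    tss_offset_min: int = 5_000
    tss_offset_max: int = 50_000
    decoy_offset_min: int = 60_000
    decoy_offset_max: int = 90_000
    n_null_genes: int = 400  # DE-table genes with no enhancer at all

    def __post_init__(self) -> None:
        for name in ("sensitive_fraction", "depletion", "spike_ratio", "depth_jitter"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.background_density <= 0 or self.enrichment <= 0:
            raise ValueError("densities and enrichment must be positive")
        if self.locus_width_min > self.locus_width_max:
            raise ValueError("locus width min > max")
        if self.tss_offset_min < 1 or self.tss_offset_min > self.tss_offset_max:
            raise ValueError("bad TSS offset range")
        if self.decoy_offset_min <= self.tss_offset_max:
            raise ValueError("decoy TSSs must be farther than designated TSSs")

    @property
    def block_size(self) -> int:
        return self.target_chrom_length // self.n_enhancers

    @property
    def n_sensitive(self) -> int:
        return int(round(self.n_enhancers * self.sensitive_fraction))


@dataclass
class Annotation:
    """Generated loci/TSS annotation plus chromosome sizes."""

    loci: list[EnhancerLocus]
    tss: list[TSSRecord]
    chrom_sizes: dict[str, int]


@dataclass
class GroundTruth:
    """What the pipeline should recover from the generated fixtures."""

    gene_map: dict[str, str]  # locus id -> designated gene
    sensitive_enhancers: list[str]
    sensitive_genes: list[str]
    enrichment_control: dict[str, float]  # locus id -> fold over background
    enrichment_treatment: dict[str, float]
    depth_multipliers: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _check_packing(cfg: SimConfig) -> None:
    half_block = cfg.block_size // 2
    need = max(cfg.decoy_offset_max, cfg.locus_width_max) + cfg.read_length + 100
    if half_block <= need:
        raise ValueError(
            f"infeasible packing: {cfg.n_enhancers} loci on a "
            f"{cfg.target_chrom_length} bp chromosome leaves blocks of "
            f"{cfg.block_size} bp; need > {2 * need} bp per locus"
        )
    # designated TSS must always out-compete the neighbouring block's TSS
    if cfg.block_size - cfg.tss_offset_max <= cfg.tss_offset_max:
        raise ValueError("infeasible packing: TSS offsets can cross block midlines")


def generate_annotation(cfg: SimConfig) -> tuple[Annotation, GroundTruth]:
    """Generate non-overlapping loci, TSS annotation and ground truth.

    Loci sit at the centers of equal blocks tiling the target chromosome.
    Each locus's designated gene gets one TSS 5-50 kb from the anchor (the
    nearest TSS to that anchor by construction); each block also carries one
    decoy TSS 60-90 kb out, which can never win nearest-TSS linkage.
    """
    _check_packing(cfg)
    rng = np.random.default_rng([cfg.seed, _STREAM_ANNOTATION])
    n = cfg.n_enhancers
    widths = rng.integers(cfg.locus_width_min, cfg.locus_width_max + 1, size=n)
    anchors = np.arange(n, dtype=np.int64) * cfg.block_size + cfg.block_size // 2

    loci: list[EnhancerLocus] = []
    tss: list[TSSRecord] = []
    gene_map: dict[str, str] = {}
    for i in range(n):
        w = int(widths[i])
        anchor = int(anchors[i])
        start = anchor - w // 2
        locus_id = f"ENH{i:04d}"
        gene_id = f"GENE{i:04d}"
        loci.append(
            EnhancerLocus(
                id=locus_id,
                interval=GenomicInterval(cfg.target_chrom, start, start + w),
                anchor=anchor,
            )
        )
        gene_map[locus_id] = gene_id

    offsets = rng.integers(cfg.tss_offset_min, cfg.tss_offset_max + 1, size=n)
    signs = rng.choice([-1, 1], size=n)
    strands = rng.choice(["+", "-"], size=n)
    decoy_offsets = rng.integers(cfg.decoy_offset_min, cfg.decoy_offset_max + 1, size=n)
    decoy_signs = rng.choice([-1, 1], size=n)
    for i in range(n):
        pos = int(anchors[i] + signs[i] * offsets[i])
        tss.append(
            TSSRecord(f"GENE{i:04d}", cfg.target_chrom, pos, str(strands[i]))
        )
        dpos = int(anchors[i] + decoy_signs[i] * decoy_offsets[i])
        dpos = min(max(dpos, 0), cfg.target_chrom_length - 1)
        tss.append(TSSRecord(f"DECOY{i:04d}", cfg.target_chrom, dpos, "+"))

    sensitive_idx = np.sort(rng.choice(n, size=cfg.n_sensitive, replace=False))
    sensitive_enh = [f"ENH{i:04d}" for i in sensitive_idx]
    sensitive_genes = [f"GENE{i:04d}" for i in sensitive_idx]
    sens_set = set(sensitive_enh)
    gt = GroundTruth(
        gene_map=gene_map,
        sensitive_enhancers=sensitive_enh,
        sensitive_genes=sensitive_genes,
        enrichment_control={loc.id: cfg.enrichment for loc in loci},
        enrichment_treatment={
            loc.id: cfg.enrichment * (cfg.depletion if loc.id in sens_set else 1.0)
            for loc in loci
        },
    )
    ann = Annotation(
        loci=loci,
        tss=tss,
        chrom_sizes={
            cfg.target_chrom: cfg.target_chrom_length,
            cfg.spike_chrom: cfg.spike_chrom_length,
        },
    )
    return ann, gt


def depth_multiplier(cfg: SimConfig, condition: str, sample_id: str) -> float:
    """The per-sample library-depth multiplier (reproducible ground truth)."""
    rng = np.random.default_rng(
        [cfg.seed, _STREAM_READS, _crc(condition), _crc(sample_id)]
    )
    return float(1.0 + cfg.depth_jitter * (2.0 * rng.random() - 1.0))


def simulate_reads(
    cfg: SimConfig,
    ann: Annotation,
    gt: GroundTruth,
    condition: str,
    sample_id: str,
) -> ReadSet:
    """Simulate one sample's mixed target + spike read set.

    Target reads: a uniform background at ``background_density`` reads/kb
    plus Poisson-distributed extra reads at each locus bringing its expected
    coverage to ``enrichment`` (times ``depletion`` at sensitive loci under
    treatment) fold over background.  Spike reads: Poisson with mean
    ``spike_ratio`` times the expected target total, placed uniformly on the
    spike chromosome.  Everything scales by the sample's depth multiplier.
    """
    if condition not in ("control", "treatment"):
        raise ValueError(f"condition must be control|treatment, got {condition!r}")
    rng = np.random.default_rng(
        [cfg.seed, _STREAM_READS, _crc(condition), _crc(sample_id)]
    )
    d_mult = 1.0 + cfg.depth_jitter * (2.0 * rng.random() - 1.0)
    rl = cfg.read_length
    L = cfg.target_chrom_length

    bg_lam = cfg.background_density * (L / 1000.0) * d_mult
    n_bg = int(rng.poisson(bg_lam))
    bg_starts = rng.integers(0, L - rl, size=n_bg)

    enrich = gt.enrichment_treatment if condition == "treatment" else gt.enrichment_control
    widths = np.array([loc.width for loc in ann.loci], dtype=float)
    folds = np.array([enrich[loc.id] for loc in ann.loci], dtype=float)
    lams = cfg.background_density * (widths / 1000.0) * np.maximum(folds - 1.0, 0.0) * d_mult
    counts = rng.poisson(lams)
    locus_starts_lo = np.array(
        [max(loc.interval.start - rl + 1, 0) for loc in ann.loci], dtype=np.int64
    )
    locus_starts_hi = np.array(
        [loc.interval.end - 1 for loc in ann.loci], dtype=np.int64
    )
    rep = np.repeat(np.arange(len(ann.loci)), counts)
    extra_starts = rng.integers(locus_starts_lo[rep], locus_starts_hi[rep] + 1)

    # spike chromatin per cell is condition-independent: scale by the
    # untreated expected target total, so signal loss never shrinks the spike
    ref_lams = cfg.background_density * (widths / 1000.0) * np.maximum(
        np.array([gt.enrichment_control[loc.id] for loc in ann.loci]) - 1.0, 0.0
    ) * d_mult
    spike_lam = cfg.spike_ratio * (bg_lam + ref_lams.sum())
    n_spike = int(rng.poisson(spike_lam))
    spike_starts = rng.integers(0, cfg.spike_chrom_length - rl, size=n_spike)

    n_target = n_bg + len(extra_starts)
    chroms = np.empty(n_target + n_spike, dtype=object)
    chroms[:n_target] = cfg.target_chrom
    chroms[n_target:] = cfg.spike_chrom
    starts = np.concatenate([bg_starts, extra_starts, spike_starts]).astype(np.int64)
    is_spike = np.zeros(n_target + n_spike, dtype=bool)
    is_spike[n_target:] = True
    return ReadSet(
        sample_id=sample_id,
        chroms=chroms,
        starts=starts,
        ends=starts + rl,
        is_spike=is_spike,
    )


def simulate_de_table(cfg: SimConfig, gt: GroundTruth) -> DETable:
    """Differential-expression table with the sensitive genes planted.

    Sensitive genes: log2fc ~ Normal(-1.5, 0.3), padj = 10^-Uniform(3, 8).
    All other genes (non-sensitive enhancer genes, decoys, and pure nulls):
    log2fc ~ Normal(0, 0.2), padj ~ Uniform(0.2, 1) — never callable at the
    -0.5 / 0.05 thresholds.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_DE])
    genes: list[str] = sorted(set(gt.gene_map.values()))
    genes += [f"DECOY{i:04d}" for i in range(cfg.n_enhancers)]
    genes += [f"NULL{i:04d}" for i in range(cfg.n_null_genes)]
    sens = set(gt.sensitive_genes)
    lfc = np.empty(len(genes))
    padj = np.empty(len(genes))
    for i, gene in enumerate(genes):
        if gene in sens:
            lfc[i] = rng.normal(-1.5, 0.3)
            padj[i] = 10.0 ** (-rng.uniform(3.0, 8.0))
        else:
            lfc[i] = rng.normal(0.0, 0.2)
            padj[i] = rng.uniform(0.2, 1.0)
    frame = pd.DataFrame(
        {"log2fc": lfc, "padj": padj}, index=pd.Index(genes, name="gene")
    )
    return DETable(frame=frame)


def simulate_peaks(
    cfg: SimConfig,
    ann: Annotation,
    factor: str,
    coverage_fraction: float,
) -> tuple[list[PeakRecord], list[str]]:
    """Peak calls covering a planted fraction of loci, plus decoy peaks.

    A uniformly chosen ``round(coverage_fraction * n)`` loci each receive one
    peak strictly inside the locus interval; decoy peaks land near block
    starts, guaranteed clear of every locus.  Returns (peaks, covered locus
    ids).
    """
    if not 0.0 <= coverage_fraction <= 1.0:
        raise ValueError("coverage_fraction must be in [0, 1]")
    rng = np.random.default_rng([cfg.seed, _STREAM_PEAKS, _crc(factor)])
    n = len(ann.loci)
    n_cov = int(round(coverage_fraction * n))
    chosen = np.sort(rng.choice(n, size=n_cov, replace=False))
    peaks: list[PeakRecord] = []
    covered: list[str] = []
    for rank, i in enumerate(chosen):
        locus = ann.loci[int(i)]
        half = min(100, locus.width // 2)
        start = locus.anchor - half
        end = max(locus.anchor + half, start + 1)
        peaks.append(
            PeakRecord(
                interval=GenomicInterval(locus.chrom, start, end),
                name=f"{factor}_peak_{rank}",
                score=int(rng.integers(100, 1000)),
                signal_value=float(rng.uniform(5.0, 50.0)),
                pvalue=float(rng.uniform(5.0, 100.0)),
                qvalue=float(rng.uniform(2.0, 50.0)),
                summit_offset=(end - start) // 2,
            )
        )
        covered.append(locus.id)
    n_decoy = max(n // 2, 1)
    decoy_blocks = rng.choice(n, size=min(n_decoy, n), replace=False)
    for rank, b in enumerate(np.sort(decoy_blocks)):
        start = int(b) * cfg.block_size + 1000  # far from the block-center locus
        peaks.append(
            PeakRecord(
                interval=GenomicInterval(cfg.target_chrom, start, start + 300),
                name=f"{factor}_decoy_{rank}",
                score=int(rng.integers(100, 1000)),
                signal_value=float(rng.uniform(5.0, 50.0)),
                pvalue=float(rng.uniform(5.0, 100.0)),
                qvalue=float(rng.uniform(2.0, 50.0)),
                summit_offset=150,
            )
        )
    return peaks, covered


def simulate_dose_grid(
    doses_a: Sequence[float] = (0.0, 0.25, 0.5, 1.0, 2.0),
    doses_b: Sequence[float] = (0.0, 0.25, 0.5, 1.0, 2.0),
    seed: int = 1,
    excess: float = 0.0,
    noise_sd: float = 0.0,
    ic50_a: float = 1.0,
    ic50_b: float = 1.0,
) -> DoseGrid:
    """Dose-response grid whose combinations deviate from Bliss independence
    by exactly ``excess`` (plus optional Gaussian noise).

    Single-agent inhibition follows a unit-slope Hill curve d / (d + IC50).
    """
    rng = np.random.default_rng([seed, _STREAM_DOSE])
    a = np.asarray(doses_a, dtype=float)
    b = np.asarray(doses_b, dtype=float)
    e_a = a / (a + ic50_a)
    e_b = b / (b + ic50_b)
    grid = e_a[:, None] + e_b[None, :] - e_a[:, None] * e_b[None, :]
    combo = (a[:, None] > 0) & (b[None, :] > 0)
    grid = grid + np.where(combo, excess, 0.0)
    if noise_sd > 0:
        grid = grid + np.where(combo, rng.normal(0.0, noise_sd, grid.shape), 0.0)
    if np.any(grid < 0) or np.any(grid > 1):
        raise ValueError("requested excess/noise pushes inhibition outside [0, 1]")
    return DoseGrid(values=pd.DataFrame(grid, index=a, columns=b))


def write_dataset(
    cfg: SimConfig,
    outdir: str | Path,
    samples: Sequence[tuple[str, str]] = (
        ("control", "ctrl_rep1"),
        ("treatment", "treat_rep1"),
    ),
    peak_factors: Sequence[tuple[str, float]] = (("factor_a", 0.86), ("factor_b", 0.94)),
    write_sam: bool = False,
) -> dict[str, Path]:
    """Emit the full fixture set as plain-text files; returns emitted paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann, gt = generate_annotation(cfg)
    paths: dict[str, Path] = {}

    loci_bed = outdir / "loci.bed"
    with open(loci_bed, "w") as fh:
        for loc in ann.loci:
            iv = loc.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{loc.id}\n")
    paths["loci"] = loci_bed

    tss_bed = outdir / "tss.bed"
    with open(tss_bed, "w") as fh:
        for rec in ann.tss:
            # 1 bp feature: start is the TSS on +, end-1 is the TSS on -
            fh.write(
                f"{rec.chrom}\t{rec.tss}\t{rec.tss + 1}\t{rec.gene_id}\t0\t{rec.strand}\n"
            )
    paths["tss"] = tss_bed

    sizes = outdir / "chrom.sizes"
    with open(sizes, "w") as fh:
        for chrom, length in ann.chrom_sizes.items():
            fh.write(f"{chrom}\t{length}\n")
    paths["chrom_sizes"] = sizes

    for condition, sample_id in samples:
        rs = simulate_reads(cfg, ann, gt, condition, sample_id)
        bed = outdir / f"reads_{sample_id}.bed"
        rs.to_bed(bed)
        paths[f"reads_{sample_id}"] = bed
        if write_sam:
            sam = outdir / f"reads_{sample_id}.sam"
            _write_sam(rs, sam, ann.chrom_sizes)
            paths[f"sam_{sample_id}"] = sam
        gt.depth_multipliers[sample_id] = depth_multiplier(cfg, condition, sample_id)

    de = simulate_de_table(cfg, gt)
    de_path = outdir / "de_table.tsv"
    de.to_tsv(de_path)
    paths["de_table"] = de_path

    from .peaks import write_narrowpeak

    for factor, coverage in peak_factors:
        pk, _ = simulate_peaks(cfg, ann, factor, coverage)
        pk_path = outdir / f"peaks_{factor}.narrowPeak"
        write_narrowpeak(pk, pk_path)
        paths[f"peaks_{factor}"] = pk_path

    grid = simulate_dose_grid(seed=cfg.seed)
    grid_path = outdir / "dose_grid.tsv"
    grid.to_tsv(grid_path)
    paths["dose_grid"] = grid_path

    gt_path = outdir / "ground_truth.json"
    gt.to_json(gt_path)
    paths["ground_truth"] = gt_path
    return paths


def _write_sam(readset: ReadSet, path: str | Path, chrom_sizes: dict[str, int]) -> None:
    """Write reads as minimal single-end SAM (mapped, primary, MAPQ 60)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom, length in chrom_sizes.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for i, (c, s, e) in enumerate(
            zip(readset.chroms, readset.starts, readset.ends)
        ):
            fh.write(f"r{i}\t0\t{c}\t{s + 1}\t60\t{e - s}M\t*\t0\t0\t*\t*\n")
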