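"""End-to-end pipeline orchestration for one control/treatment comparison.

Stages run in a fixed order — normalize, quantify, filter, fold-change,
classify, peak overlap/correlation, group tests — and every output table
embeds the config hash, seed and package version so identical configs
reproduce identical bytes.  A stage failure aborts with a stage-named error.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._io import write_tsv
from .config import RunConfig
from .peaks import overlap_fraction, read_narrowpeak
from .quant import build_signal_table, fold_change, signal_matrix
from .regions import (
    extend_to_min_width,
    link_to_nearest_tss,
    read_bed,
    read_chrom_sizes,
    read_tss_bed,
    write_linked_bed,
)
from .sensitivity import call_downregulated, call_sensitive, read_de_table
from .spikenorm import compute_norm_factors, read_reads_bed, read_sam
from .stats import mann_whitney_u

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return decorator


def _read_reads(path: str, sample_id: str, spike_prefix: str):
    if path.endswith((".sam", ".bam")):
        return read_sam(path, sample_id, spike_prefix)
    return read_reads_bed(path, sample_id, spike_prefix)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all configured stages; returns the run summary dict."""
    cfg.validate_paths()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config": cfg.hash(), "seed": cfg.seed, "version": __version__}
    summary: dict = dict(meta)

    # --- regions ---
    loci = _load_regions(cfg, outdir)
    summary["n_loci"] = len(loci)

    # --- normalize ---
    samples, factors = _normalize(cfg, outdir, meta)
    summary["normalization"] = cfg.normalization

    # --- quantify / filter / fold change ---
    table = build_signal_table(
        samples, loci, factors, cfg.assay, cfg.seed
    )
    table.metadata.update(meta)
    table.to_tsv(outdir / "signal_table.tsv")
    fc = fold_change(
        table, cfg.control_id, cfg.treatment_id, cfg.pseudocount, cfg.rpk_threshold
    )
    write_tsv(
        fc.reset_index(),
        outdir / "fold_change.tsv",
        {**meta, "pseudocount": cfg.pseudocount, "rpk_threshold": cfg.rpk_threshold},
    )
    summary["n_loci_passing_filter"] = int(fc["passed_filter"].sum())

    # --- tornado matrix for the treatment sample ---
    matrix = signal_matrix(
        samples[1] if factors is None else samples[1], loci, cfg.window, cfg.bin
    )
    matrix.to_tsv(outdir / "tornado_treatment.tsv")

    # --- classify ---
    if cfg.de_table and cfg.tss:
        summary.update(_classify(cfg, outdir, loci, fc, meta))

    # --- peaks ---
    if cfg.peaks:
        summary.update(_peaks(cfg, outdir, loci, meta))

    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


@_stage("regions")
def _load_regions(cfg: RunConfig, outdir: Path):
    sizes = read_chrom_sizes(cfg.chrom_sizes) if cfg.chrom_sizes else None
    loci = extend_to_min_width(read_bed(cfg.loci, sizes), cfg.min_width, sizes)
    if cfg.tss:
        loci = link_to_nearest_tss(loci, read_tss_bed(cfg.tss))
    write_linked_bed(loci, outdir / "loci_prepared.bed")
    return loci


@_stage("normalize")
def _normalize(cfg: RunConfig, outdir: Path, meta: dict):
    control = _read_reads(cfg.control_reads, cfg.control_id, cfg.spike_prefix)
    treatment = _read_reads(cfg.treatment_reads, cfg.treatment_id, cfg.spike_prefix)
    samples = [control, treatment]
    factors = None
    if cfg.normalization != "none":
        factors = compute_norm_factors(samples, cfg.normalization, cfg.spike_prefix)
        factors.to_tsv(outdir / "norm_factors.tsv")
    return samples, factors


@_stage("classify")
def _classify(cfg: RunConfig, outdir: Path, loci, fc: pd.DataFrame, meta: dict) -> dict:
    de = read_de_table(cfg.de_table)
    down = call_downregulated(de, cfg.lfc, cfg.fdr)
    call = call_sensitive(loci, down, cfg.system)
    write_tsv(
        pd.DataFrame({"gene": sorted(call.sensitive_genes)}),
        outdir / "sensitive_genes.tsv",
        meta,
    )
    write_tsv(
        pd.DataFrame({"locus": sorted(call.sensitive_enhancers)}),
        outdir / "sensitive_enhancers.tsv",
        meta,
    )
    out = call.summary()
    # group test: fold change at sensitive vs all other filtered loci
    passed = fc[fc["passed_filter"]]
    sens_mask = passed.index.isin(call.sensitive_enhancers)
    if 0 < sens_mask.sum() < len(passed):
        test = mann_whitney_u(
            passed["log2fc"][sens_mask], passed["log2fc"][~sens_mask]
        )
        out["log2fc_sensitive_vs_other_p"] = test.p_value
        out["log2fc_sensitive_vs_other_U"] = test.statistic
    return out


@_stage("peaks")
def _peaks(cfg: RunConfig, outdir: Path, loci, meta: dict) -> dict:
    peaks = read_narrowpeak(cfg.peaks)
    summary, flags = overlap_fraction(loci, peaks, cfg.peaks_factor)
    write_tsv(
        pd.DataFrame(
            {
                "factor": [summary.factor],
                "n_enhancers": [summary.n_enhancers],
                "n_overlapped": [summary.n_overlapped],
                "fraction": [summary.fraction],
            }
        ),
        outdir / "peak_overlap.tsv",
        meta,
    )
    return {
        "peak_overlap_fraction": summary.fraction,
        "peak_n_overlapped": summary.n_overlapped,
    }
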