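"""Signal quantification over enhancer loci.

ChIP and eRNA signal are summarized per locus as rpk — reads overlapping the
locus divided by locus width in kilobases — computed on normalized
(downsampled) read sets.  Comparisons between a control and a treated sample
first exclude loci where *both* samples sit below an assay-specific rpk floor
(30 rpk for ChIP, 10 rpk for eRNA, where low signal is expected), then report
per-locus log2 fold changes with a pseudocount.  A binned signal matrix over a
fixed window around each locus anchor ("tornado" matrix) supports occupancy
heatmaps.

Overlap counting is strand-agnostic and counts any alignment sharing >= 1 bp
with the half-open locus interval, via sorted-array rank arithmetic:
``overlaps = #(start < locus_end) - #(end <= locus_start)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import EnhancerLocus
from .spikenorm import NormFactors, ReadSet, downsample, per_10M_scale

logger = logging.getLogger(__name__)

__all__ = [
    "SignalTable",
    "SignalMatrix",
    "DEFAULT_RPK_THRESHOLDS",
    "count_overlaps",
    "rpk",
    "build_signal_table",
    "filter_low_signal",
    "fold_change",
    "signal_matrix",
]

DEFAULT_RPK_THRESHOLDS: Mapping[str, float] = {"chip": 30.0, "rna": 10.0}


class _ReadIndex:
    """Per-chromosome sorted start/end arrays of target-genome reads."""

    def __init__(self, readset: ReadSet) -> None:
        target = readset.target_reads()
        self.n_target = len(target)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if self.n_target == 0:
            return
        order = np.argsort(target.chroms, kind="stable")
        chroms = target.chroms[order]
        starts = target.starts[order]
        ends = target.ends[order]
        boundaries = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
        for chunk_start, chunk_end in zip(
            np.r_[0, boundaries], np.r_[boundaries, len(chroms)]
        ):
            chrom = str(chroms[chunk_start])
            self._by_chrom[chrom] = (
                np.sort(starts[chunk_start:chunk_end]),
                np.sort(ends[chunk_start:chunk_end]),
            )

    def count(self, chrom: str, start, end) -> np.ndarray | int:
        """Reads overlapping [start, end); accepts scalars or arrays."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return np.zeros_like(np.asarray(start)) if np.ndim(start) else 0
        sorted_starts, sorted_ends = entry
        n_before_end = np.searchsorted(sorted_starts, end, side="left")
        n_ended_before = np.searchsorted(sorted_ends, start, side="right")
        return n_before_end - n_ended_before


def count_overlaps(reads: ReadSet, locus: EnhancerLocus) -> int:
    """Number of target-genome reads overlapping the locus by >= 1 bp."""
    idx = _ReadIndex(reads)
    return int(idx.count(locus.chrom, locus.interval.start, locus.interval.end))


def rpk(count: int, locus_width: int) -> float:
    """Reads per kilobase of locus."""
    if locus_width <= 0:
        raise ValueError(f"locus width must be positive, got {locus_width}")
    return count / (locus_width / 1000.0)


@dataclass
class SignalTable:
    """Locus x sample matrix of rpk values with provenance metadata."""

    values: pd.DataFrame  # index: locus ids, columns: sample ids
    assay: str = "chip"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.assay not in ("chip", "rna"):
            raise ValueError(f"assay must be 'chip' or 'rna', got {self.assay!r}")
        if (self.values.values < 0).any():
            raise ValueError("rpk values must be non-negative")

    @property
    def loci(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def sample_column(self, sample_id: str) -> pd.Series:
        if sample_id not in self.values.columns:
            raise KeyError(f"unknown sample id {sample_id!r}")
        return self.values[sample_id]

    def to_tsv(self, path: str | Path) -> None:
        from ._io import write_tsv

        write_tsv(
            self.values.reset_index(names="locus"),
            path,
            {"assay": self.assay, **self.metadata},
        )


def build_signal_table(
    samples: Sequence[ReadSet],
    loci: Sequence[EnhancerLocus],
    norm: NormFactors | None = None,
    assay: str = "chip",
    seed: int = 1,
) -> SignalTable:
    """Quantify rpk at every locus for every sample.

    When ``norm`` is given, each sample is first downsampled by its fraction
    (seeded deterministically per sample from ``seed``); otherwise samples are
    assumed already normalized.
    """
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample ids: {ids}")
    locus_ids = [loc.id for loc in loci]
    if len(set(locus_ids)) != len(locus_ids):
        raise ValueError("duplicate locus ids")
    columns = {}
    for i, sample in enumerate(samples):
        if norm is not None:
            sample = downsample(sample, norm.fraction(sample.sample_id), seed + i)
        idx = _ReadIndex(sample)
        col = np.empty(len(loci), dtype=float)
        for j, locus in enumerate(loci):
            count = int(idx.count(locus.chrom, locus.interval.start, locus.interval.end))
            col[j] = rpk(count, locus.width)
        columns[sample.sample_id] = col
    values = pd.DataFrame(columns, index=pd.Index(locus_ids, name="locus"))
    meta = {"normalization": norm.mode if norm is not None else "none", "seed": seed}
    return SignalTable(values=values, assay=assay, metadata=meta)


def _resolve_threshold(table: SignalTable, threshold: float | None) -> float:
    if threshold is not None:
        return float(threshold)
    return DEFAULT_RPK_THRESHOLDS[table.assay]


def filter_low_signal(
    table: SignalTable,
    control: str,
    treatment: str,
    threshold: float | None = None,
) -> SignalTable:
    """Drop loci where both control and treatment rpk are below the floor.

    A locus is retained iff control >= threshold OR treatment >= threshold;
    retained loci keep their raw values.  The default floor comes from the
    assay: 30 rpk for ChIP, 10 rpk for eRNA.
    """
    thr = _resolve_threshold(table, threshold)
    c = table.sample_column(control)
    t = table.sample_column(treatment)
    keep = (c >= thr) | (t >= thr)
    excluded = list(table.values.index[~keep])
    if excluded:
        logger.info(
            "low-signal filter (< %g rpk in both %s and %s): excluded %d/%d loci",
            thr, control, treatment, len(excluded), len(table.values),
        )
    meta = dict(table.metadata)
    meta.update({"rpk_threshold": thr, "excluded_loci": excluded})
    return SignalTable(values=table.values.loc[keep], assay=table.assay, metadata=meta)


def fold_change(
    table: SignalTable,
    control: str,
    treatment: str,
    pseudocount: float = 1.0,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Per-locus log2 fold change of treatment over control rpk.

    Applies the low-signal floor internally: loci failing it are reported with
    ``passed_filter=False`` and NaN log2fc rather than dropped, so callers can
    see the full locus universe.  log2fc = log2((t + pc) / (c + pc)).
    """
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be non-negative, got {pseudocount}")
    thr = _resolve_threshold(table, threshold)
    c = table.sample_column(control).to_numpy(dtype=float)
    t = table.sample_column(treatment).to_numpy(dtype=float)
    passed = (c >= thr) | (t >= thr)
    log2fc = np.full(len(c), np.nan)
    log2fc[passed] = np.log2((t[passed] + pseudocount) / (c[passed] + pseudocount))
    return pd.DataFrame(
        {
            "locus_id": table.values.index,
            "rpk_control": c,
            "rpk_treatment": t,
            "log2fc": log2fc,
            "passed_filter": passed,
        }
    ).set_index("locus_id")


@dataclass
class SignalMatrix:
    """Loci x bins matrix of per-10M read counts around each locus anchor."""

    values: pd.DataFrame  # index: locus ids, columns: bin-start offsets
    window: int
    bin_size: int

    def ordered_by_sum(self) -> pd.DataFrame:
        """Rows sorted by total signal, descending — tornado display order."""
        order = self.values.sum(axis=1).sort_values(ascending=False, kind="stable")
        return self.values.loc[order.index]

    def to_tsv(self, path: str | Path) -> None:
        from ._io import write_tsv

        write_tsv(
            self.values.reset_index(names="locus"),
            path,
            {"window": self.window, "bin_size": self.bin_size},
        )


def signal_matrix(
    reads: ReadSet,
    loci: Sequence[EnhancerLocus],
    window: int = 3000,
    bin_size: int = 50,
) -> SignalMatrix:
    """Binned per-10M read counts over +/- ``window`` around each anchor.

    Bin k of locus i covers [anchor_i - window + k*bin_size, ... + bin_size);
    counts are reads overlapping the bin, scaled to reads per 10 million total
    target reads.  Bins extending past the chromosome start hold zeros.
    """
    if window <= 0 or bin_size <= 0:
        raise ValueError("window and bin_size must be positive")
    if window % bin_size != 0:
        raise ValueError(f"window {window} not divisible by bin size {bin_size}")
    n_bins = 2 * window // bin_size
    idx = _ReadIndex(reads)
    total = idx.n_target
    offsets = np.arange(-window, window, bin_size)
    out = np.zeros((len(loci), n_bins), dtype=float)
    for i, locus in enumerate(loci):
        edges = locus.anchor + np.arange(-window, window + bin_size, bin_size)
        counts = idx.count(locus.chrom, edges[:-1], edges[1:])
        if total > 0:
            out[i] = np.asarray(counts, dtype=float) * 1e7 / total
    values = pd.DataFrame(
        out, index=pd.Index([loc.id for loc in loci], name="locus"), columns=offsets
    )
    return SignalMatrix(values=values, window=window, bin_size=bin_size)
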