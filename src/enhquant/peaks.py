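"""narrowPeak ingestion, enhancer-overlap fractions, intensity correlation.

Peak calls arrive in the 10-column ENCODE narrowPeak format (MACS2 output).
Two summaries are computed against an enhancer locus set: the fraction of
loci overlapped by at least one peak of a factor, and the squared Pearson
correlation of per-locus intensities between two factors (log2(x+1)
transformed by default, since ChIP intensities are heavy-tailed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .regions import EnhancerLocus, GenomicInterval
from .quant import SignalTable

__all__ = [
    "PeakRecord",
    "OverlapSummary",
    "read_narrowpeak",
    "write_narrowpeak",
    "overlap_fraction",
    "intensity_correlation",
    "peak_signal_at_loci",
]


@dataclass(frozen=True)
class PeakRecord:
    """One ENCODE narrowPeak record.

    ``pvalue`` and ``qvalue`` are on the -log10 scale; -1 (the format's
    missing marker) maps to None, as does "." in name/strand.  The summit
    offset is relative to the peak start; -1 means no summit was called.
    """

    interval: GenomicInterval
    name: str | None = None
    score: int = 0
    strand: str | None = None
    signal_value: float = 0.0
    pvalue: float | None = None
    qvalue: float | None = None
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.width
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak of width "
                f"{self.interval.width}"
            )

    @property
    def summit(self) -> int | None:
        if self.summit_offset is None:
            return None
        return self.interval.start + self.summit_offset


@dataclass(frozen=True)
class OverlapSummary:
    factor: str
    n_enhancers: int
    n_overlapped: int

    @property
    def fraction(self) -> float:
        return self.n_overlapped / self.n_enhancers if self.n_enhancers else 0.0


def read_narrowpeak(path: str | Path) -> list[PeakRecord]:
    """Read an ENCODE narrowPeak (10-column) file, preserving record order."""
    records: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise ValueError(
                    f"{path}:{lineno}: narrowPeak requires 10 columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                score = int(float(fields[4])) if fields[4] != "." else 0
                signal = float(fields[6]) if fields[6] != "." else 0.0
                pval = float(fields[7])
                qval = float(fields[8])
                summit = int(fields[9])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable field") from exc
            records.append(
                PeakRecord(
                    interval=GenomicInterval(fields[0], start, end),
                    name=None if fields[3] == "." else fields[3],
                    score=score,
                    strand=None if fields[5] == "." else fields[5],
                    signal_value=signal,
                    pvalue=None if pval < 0 else pval,
                    qvalue=None if qval < 0 else qval,
                    summit_offset=None if summit < 0 else summit,
                )
            )
    return records


def write_narrowpeak(peaks: Sequence[PeakRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        p.name or ".",
                        str(p.score),
                        p.strand or ".",
                        f"{p.signal_value:g}",
                        f"{p.pvalue:g}" if p.pvalue is not None else "-1",
                        f"{p.qvalue:g}" if p.qvalue is not None else "-1",
                        str(p.summit_offset) if p.summit_offset is not None else "-1",
                    ]
                )
                + "\n"
            )


def _peak_index(peaks: Sequence[PeakRecord]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {p.interval.chrom for p in peaks}:
        ivs = [p.interval for p in peaks if p.interval.chrom == chrom]
        by_chrom[chrom] = (
            np.sort(np.array([iv.start for iv in ivs], dtype=np.int64)),
            np.sort(np.array([iv.end for iv in ivs], dtype=np.int64)),
        )
    return by_chrom


def overlap_fraction(
    loci: Sequence[EnhancerLocus],
    peaks: Sequence[PeakRecord],
    factor: str = "factor",
) -> tuple[OverlapSummary, pd.Series]:
    """Fraction of loci overlapped (>= 1 bp, half-open) by any peak.

    Uses per-chromosome sorted start/end rank arithmetic, O((n+m) log(n+m)).
    Returns the summary plus a per-locus boolean Series in locus order.
    """
    index = _peak_index(peaks)
    flags = np.zeros(len(loci), dtype=bool)
    for i, locus in enumerate(loci):
        entry = index.get(locus.chrom)
        if entry is None:
            continue
        starts, ends = entry
        n_before_end = np.searchsorted(starts, locus.interval.end, side="left")
        n_ended = np.searchsorted(ends, locus.interval.start, side="right")
        flags[i] = (n_before_end - n_ended) > 0
    series = pd.Series(flags, index=[loc.id for loc in loci], name="overlapped")
    summary = OverlapSummary(
        factor=factor, n_enhancers=len(loci), n_overlapped=int(flags.sum())
    )
    return summary, series


def peak_signal_at_loci(
    loci: Sequence[EnhancerLocus], peaks: Sequence[PeakRecord]
) -> pd.Series:
    """Maximum signalValue among peaks overlapping each locus (0 if none).

    Alternative intensity definition for correlation analyses that prefer the
    peak caller's enrichment estimate over locus rpk.
    """
    out = np.zeros(len(loci), dtype=float)
    for i, locus in enumerate(loci):
        best = 0.0
        for p in peaks:
            if p.interval.overlaps(locus.interval):
                best = max(best, p.signal_value)
        out[i] = best
    return pd.Series(out, index=[loc.id for loc in loci], name="signal_value")


def intensity_correlation(
    table: SignalTable,
    factor_a: str,
    factor_b: str,
    log_transform: bool = True,
) -> tuple[float, pd.DataFrame]:
    """Squared Pearson correlation of per-locus intensities of two factors.

    Values are log2(x+1)-transformed by default.  Returns (R^2, pairs) where
    pairs holds the per-locus values actually correlated.
    """
    x = table.sample_column(factor_a).to_numpy(dtype=float)
    y = table.sample_column(factor_b).to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 loci for a correlation")
    if log_transform:
        x = np.log2(x + 1.0)
        y = np.log2(y + 1.0)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in a column")
    r = _sps.pearsonr(x, y).statistic
    pairs = pd.DataFrame(
        {factor_a: x, factor_b: y}, index=pd.Index(table.loci, name="locus")
    )
    return float(r * r), pairs
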