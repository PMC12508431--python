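"""Exogenous spike-in (ChIP-Rx) normalization by read downsampling.

Samples carry reads from two genomes: the target genome (signal) and an
exogenous spike-in genome (reference chromatin mixed in at a fixed cell ratio
before immunoprecipitation).  Because every sample received the same amount of
spike chromatin per cell, the spike-in read count measures the combined
library-depth / IP-efficiency scale of each sample.  Normalization equalizes
that scale across a comparison group by *downsampling*: each sample keeps the
fraction ``f_s = min_t(S_t) / S_s`` of its target reads, so retained target
depth per spike read is constant across samples and no sample is ever
upsampled.  A depth-only mode (``f_s = min_t(H_t) / H_s``) is available for
samples without spike-in.

Reads are stored as numpy column arrays; spike reads are recognized by a
chromosome-name prefix (default ``dm6_``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReadSet",
    "NormFactors",
    "count_by_genome",
    "compute_norm_factors",
    "downsample",
    "per_10M_scale",
    "read_reads_bed",
    "read_sam",
]

DEFAULT_SPIKE_PREFIX = "dm6_"


@dataclass
class ReadSet:
    """Aligned reads for one sample, partitioned into target and spike genomes.

    Columns are parallel numpy arrays; ``is_spike`` marks reads on the
    exogenous reference.  ``names`` is optional and, when present, keys
    paired-end mates so downsampling keeps or drops them together.
    """

    sample_id: str
    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    is_spike: np.ndarray
    names: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.starts)
        self.chroms = np.asarray(self.chroms)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.is_spike = np.asarray(self.is_spike, dtype=bool)
        for name, arr in [("chroms", self.chroms), ("ends", self.ends),
                          ("is_spike", self.is_spike)]:
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n}")
        if self.names is not None and len(self.names) != n:
            raise ValueError("names length mismatch")
        if n and np.any(self.starts >= self.ends):
            raise ValueError(f"sample {self.sample_id}: read with start >= end")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def n_target(self) -> int:
        return int((~self.is_spike).sum())

    @property
    def n_spike(self) -> int:
        return int(self.is_spike.sum())

    def subset(self, mask: np.ndarray) -> "ReadSet":
        return ReadSet(
            sample_id=self.sample_id,
            chroms=self.chroms[mask],
            starts=self.starts[mask],
            ends=self.ends[mask],
            is_spike=self.is_spike[mask],
            names=None if self.names is None else self.names[mask],
        )

    def target_reads(self) -> "ReadSet":
        return self.subset(~self.is_spike)

    @classmethod
    def from_arrays(
        cls,
        sample_id: str,
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        spike_prefix: str = DEFAULT_SPIKE_PREFIX,
        names: Sequence[str] | None = None,
    ) -> "ReadSet":
        chroms = np.asarray(chroms, dtype=object)
        is_spike = np.array([c.startswith(spike_prefix) for c in chroms], dtype=bool)
        return cls(
            sample_id=sample_id,
            chroms=chroms,
            starts=np.asarray(starts),
            ends=np.asarray(ends),
            is_spike=is_spike,
            names=None if names is None else np.asarray(names, dtype=object),
        )

    def to_bed(self, path: str | Path) -> None:
        """Write reads as a 3-column reads-as-BED file."""
        with open(path, "w") as fh:
            for c, s, e in zip(self.chroms, self.starts, self.ends):
                fh.write(f"{c}\t{s}\t{e}\n")


def read_reads_bed(
    path: str | Path,
    sample_id: str | None = None,
    spike_prefix: str = DEFAULT_SPIKE_PREFIX,
) -> ReadSet:
    """Read the simplified reads-as-BED dialect (chrom, start, end per line)."""
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns")
            try:
                s, e = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if s >= e:
                raise ValueError(f"{path}:{lineno}: start >= end")
            chroms.append(fields[0])
            starts.append(s)
            ends.append(e)
    return ReadSet.from_arrays(
        sample_id or Path(path).stem, chroms, starts, ends, spike_prefix
    )


def read_sam(
    path: str | Path,
    sample_id: str | None = None,
    spike_prefix: str = DEFAULT_SPIKE_PREFIX,
    min_mapq: int = 0,
) -> ReadSet:
    """Read mapped, primary, non-duplicate records from SAM/BAM via pysam."""
    import pysam

    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    names: list[str] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if (
                rec.is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or rec.is_duplicate
                or rec.mapping_quality < min_mapq
            ):
                continue
            chroms.append(rec.reference_name)
            starts.append(rec.reference_start)
            ends.append(rec.reference_end or rec.reference_start + 1)
            names.append(rec.query_name)
    return ReadSet.from_arrays(
        sample_id or Path(path).stem, chroms, starts, ends, spike_prefix, names=names
    )


def count_by_genome(
    readset: ReadSet, spike_prefix: str = DEFAULT_SPIKE_PREFIX
) -> tuple[int, int]:
    """Count (target, spike) reads, recognizing spike by chromosome prefix."""
    if len(readset) == 0:
        return 0, 0
    spike = np.array(
        [str(c).startswith(spike_prefix) for c in readset.chroms], dtype=bool
    )
    s = int(spike.sum())
    return len(readset) - s, s


@dataclass
class NormFactors:
    """Per-sample normalization bookkeeping.

    ``table`` is indexed by sample id with columns H (target reads), S (spike
    reads), gamma (per-million spike scale, 1e6/S) and f (downsampling
    fraction).  ``mode`` records whether factors equalize spike depth
    ("spike") or plain target depth ("depth").
    """

    table: pd.DataFrame
    mode: str

    def fraction(self, sample_id: str) -> float:
        return float(self.table.loc[sample_id, "f"])

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "sample", out.index)
        out["mode"] = self.mode
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NormFactors":
        df = pd.read_csv(path, sep="\t")
        mode = str(df["mode"].iloc[0])
        table = df.set_index("sample")[["H", "S", "gamma", "f"]]
        return cls(table=table, mode=mode)


def compute_norm_factors(
    samples: Sequence[ReadSet],
    mode: str = "spike",
    spike_prefix: str = DEFAULT_SPIKE_PREFIX,
) -> NormFactors:
    """Compute downsampling fractions for a comparison group.

    Spike mode: ``f_s = min_t(S_t) / S_s`` so retained target reads per spike
    read are equal across samples.  Depth mode: ``f_s = min_t(H_t) / H_s``.
    The sample with the smallest denominator keeps all of its reads (f = 1).
    """
    if mode not in ("spike", "depth"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to normalize")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample ids: {ids}")
    counts = {s.sample_id: count_by_genome(s, spike_prefix) for s in samples}
    H = np.array([counts[i][0] for i in ids], dtype=float)
    S = np.array([counts[i][1] for i in ids], dtype=float)
    if mode == "spike":
        if np.any(S == 0):
            bad = [i for i, s in zip(ids, S) if s == 0]
            raise ValueError(f"spike normalization undefined: no spike reads in {bad}")
        f = S.min() / S
    else:
        if np.any(H == 0):
            bad = [i for i, h in zip(ids, H) if h == 0]
            raise ValueError(f"depth normalization undefined: no target reads in {bad}")
        f = H.min() / H
    gamma = np.where(S > 0, 1e6 / np.where(S > 0, S, 1.0), np.nan)
    table = pd.DataFrame({"H": H, "S": S, "gamma": gamma, "f": f}, index=pd.Index(ids, name="sample"))
    return NormFactors(table=table, mode=mode)


def downsample(readset: ReadSet, fraction: float, seed: int) -> ReadSet:
    """Retain each target read independently with probability ``fraction``.

    Spike reads are bookkeeping, not signal, and pass through untouched.  When
    read names are present, mates sharing a name are kept or dropped together
    (one Bernoulli draw per distinct name).  Bit-reproducible for a fixed
    (readset, fraction, seed).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if fraction == 1.0:
        return readset
    rng = np.random.default_rng(seed)
    target = ~readset.is_spike
    if readset.names is not None:
        codes, _ = pd.factorize(readset.names[target])
        n_units = int(codes.max()) + 1 if len(codes) else 0
        keep_unit = rng.random(n_units) < fraction
        keep_target = keep_unit[codes] if len(codes) else np.zeros(0, dtype=bool)
    else:
        keep_target = rng.random(int(target.sum())) < fraction
    keep = np.array(readset.is_spike, dtype=bool, copy=True)
    keep[target] = keep_target
    return readset.subset(keep)


def per_10M_scale(count: int, total_reads: int) -> float:
    """Scale a raw count to reads per 10 million sequenced reads."""
    if count == 0:
        return 0.0
    if total_reads <= 0:
        raise ValueError(f"total_reads must be positive, got {total_reads}")
    return count * 1e7 / total_reads
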