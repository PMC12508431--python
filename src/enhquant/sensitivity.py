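"""Degron-sensitivity classification from differential expression.

A gene is *downregulated* after degrader treatment when its log2 fold change
falls below -0.5 with FDR below 0.05 (both strict).  A gene is *sensitive*
when it is downregulated and linked to at least one enhancer in the locus
set; the enhancers linked to sensitive genes are the *sensitive enhancers*.
Set-overlap summaries compare sensitive sets between degradation systems or
drug treatments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .regions import EnhancerLocus

logger = logging.getLogger(__name__)

__all__ = [
    "DETable",
    "SensitivityCall",
    "SetOverlap",
    "read_de_table",
    "call_downregulated",
    "call_sensitive",
    "set_overlap",
]


@dataclass
class DETable:
    """Per-gene differential expression: log2 fold change and adjusted p.

    ``padj`` may be NaN (e.g. independent-filtering NAs); such genes are
    retained but can never be called significant.
    """

    frame: pd.DataFrame  # index gene_id, columns log2fc, padj

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes[:5])}")
        padj = self.frame["padj"]
        bad = padj.dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValueError("padj values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def genes(self) -> pd.Index:
        return self.frame.index

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.reset_index()
        out.columns = ["gene", "log2FoldChange", "padj"]
        out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_de_table(
    path: str | Path,
    gene_col: str = "gene",
    lfc_col: str = "log2FoldChange",
    padj_col: str = "padj",
) -> DETable:
    """Read a headered differential-expression TSV (column names configurable)."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    for col in (gene_col, lfc_col, padj_col):
        if col not in raw.columns:
            raise ValueError(f"{path}: missing column {col!r} (have {list(raw.columns)})")
    frame = pd.DataFrame(index=pd.Index(raw[gene_col], name="gene"))
    for col, target in ((lfc_col, "log2fc"), (padj_col, "padj")):
        values = pd.to_numeric(raw[col].replace({"NA": None, "": None}), errors="coerce")
        unparseable = values.isna() & raw[col].notna() & ~raw[col].isin(["NA", "NaN", "nan", ""])
        if unparseable.any():
            lineno = int(np.flatnonzero(unparseable)[0]) + 2  # 1-based + header
            raise ValueError(f"{path}:{lineno}: unparseable value in column {col!r}")
        frame[target] = values.to_numpy()
    if frame["log2fc"].isna().any():
        raise ValueError(f"{path}: missing log2 fold change values")
    return DETable(frame=frame)


def call_downregulated(
    de: DETable, lfc_max: float = -0.5, fdr_max: float = 0.05
) -> set[str]:
    """Genes with log2fc < lfc_max and padj < fdr_max, both strict."""
    if not (np.isfinite(lfc_max) and np.isfinite(fdr_max)):
        raise ValueError("thresholds must be finite")
    mask = (de.frame["log2fc"] < lfc_max) & (de.frame["padj"] < fdr_max)
    return set(de.frame.index[mask.fillna(False)])


@dataclass(frozen=True)
class SensitivityCall:
    """Sensitive genes/enhancers for one degradation system."""

    system: str
    down_genes: frozenset[str]
    sensitive_genes: frozenset[str]
    sensitive_enhancers: frozenset[str]

    def __post_init__(self) -> None:
        if not self.sensitive_genes <= self.down_genes:
            raise ValueError("sensitive_genes must be a subset of down_genes")

    def summary(self) -> dict:
        return {
            "system": self.system,
            "n_down_genes": len(self.down_genes),
            "n_sensitive_genes": len(self.sensitive_genes),
            "n_sensitive_enhancers": len(self.sensitive_enhancers),
        }


def call_sensitive(
    loci: Sequence[EnhancerLocus], down_genes: Iterable[str], system: str
) -> SensitivityCall:
    """Intersect downregulated genes with enhancer-linked genes.

    A sensitive gene's enhancers are *all* loci linked to it.  Unlinked loci
    are skipped with a warning.
    """
    down = frozenset(down_genes)
    gene_to_loci: dict[str, set[str]] = {}
    for locus in loci:
        if locus.linked_gene is None:
            logger.warning("locus %s has no linked gene; skipped", locus.id)
            continue
        gene_to_loci.setdefault(locus.linked_gene, set()).add(locus.id)
    sensitive_genes = frozenset(down & gene_to_loci.keys())
    sensitive_enhancers = frozenset(
        locus_id for gene in sensitive_genes for locus_id in gene_to_loci[gene]
    )
    return SensitivityCall(
        system=system,
        down_genes=down,
        sensitive_genes=sensitive_genes,
        sensitive_enhancers=sensitive_enhancers,
    )


class SetOverlap(NamedTuple):
    """Exact overlap between two id sets, with both percentage directions."""

    n_a: int
    n_b: int
    n_intersection: int
    pct_of_a: float
    pct_of_b: float


def set_overlap(a: Iterable[str], b: Iterable[str]) -> SetOverlap:
    sa, sb = set(a), set(b)
    inter = len(sa & sb)
    return SetOverlap(
        n_a=len(sa),
        n_b=len(sb),
        n_intersection=inter,
        pct_of_a=100.0 * inter / len(sa) if sa else 0.0,
        pct_of_b=100.0 * inter / len(sb) if sb else 0.0,
    )
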