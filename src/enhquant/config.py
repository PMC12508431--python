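"""Flat key-value run configuration.

The config file is flat YAML (``key: value`` per line, no nesting).  Unknown
keys are errors — a misspelled threshold must fail loudly, not silently fall
back to a default.  One config describes one control/treatment comparison;
run several configs for several comparison groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from ._io import config_hash

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """All pipeline inputs and the fixed analysis constants in one place.

    Thresholds default to the published analysis settings: 600 bp minimum
    locus width, 30/10 rpk low-signal floors (ChIP/eRNA), log2FC < -0.5 with
    FDR < 0.05 for downregulation, +/-3 kb tornado windows in 50 bp bins,
    1.0 rpk fold-change pseudocount.
    """

    # inputs
    loci: str = ""
    tss: str = ""
    chrom_sizes: str = ""
    control_reads: str = ""
    treatment_reads: str = ""
    control_id: str = "control"
    treatment_id: str = "treatment"
    de_table: str = ""
    peaks: str = ""
    peaks_factor: str = "factor"
    # analysis settings
    assay: str = "chip"
    normalization: str = "spike"
    spike_prefix: str = "dm6_"
    min_width: int = 600
    chip_rpk: float = 30.0
    rna_rpk: float = 10.0
    lfc: float = -0.5
    fdr: float = 0.05
    window: int = 3000
    bin: int = 50
    pseudocount: float = 1.0
    seed: int = 1
    system: str = "degrader"
    outdir: str = "enhquant_out"

    def __post_init__(self) -> None:
        if self.assay not in ("chip", "rna"):
            raise ValueError(f"assay must be chip|rna, got {self.assay!r}")
        if self.normalization not in ("spike", "depth", "none"):
            raise ValueError(
                f"normalization must be spike|depth|none, got {self.normalization!r}"
            )

    @property
    def rpk_threshold(self) -> float:
        return self.chip_rpk if self.assay == "chip" else self.rna_rpk

    def validate_paths(self) -> None:
        for key in ("loci", "control_reads", "treatment_reads"):
            value = getattr(self, key)
            if not value:
                raise ValueError(f"config key {key!r} is required")
            if not Path(value).exists():
                raise FileNotFoundError(f"{key}: no such file {value}")
        for key in ("tss", "chrom_sizes", "de_table", "peaks"):
            value = getattr(self, key)
            if value and not Path(value).exists():
                raise FileNotFoundError(f"{key}: no such file {value}")

    def hash(self) -> str:
        return config_hash({f.name: getattr(self, f.name) for f in fields(self)})


def load_config(path: str | Path) -> RunConfig:
    """Load a flat YAML config; unknown keys raise."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"{path}: unknown config keys {sorted(unknown)}; known keys: {sorted(known)}"
        )
    return RunConfig(**data)
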