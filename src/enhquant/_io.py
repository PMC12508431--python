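"""Shared TSV output helpers: every table carries a provenance header."""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__


def write_tsv(frame: pd.DataFrame, path: str | Path, meta: Mapping | None = None) -> None:
    """Write a TSV with ``# key: value`` provenance comment lines on top.

    Keys are emitted sorted so identical metadata yields identical bytes.
    """
    with open(path, "w") as fh:
        fh.write(f"# enhquant: {__version__}\n")
        for key in sorted(meta or {}):
            value = (meta or {})[key]
            if isinstance(value, (list, tuple, set, frozenset)):
                value = ",".join(str(v) for v in sorted(value)) or "-"
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def config_hash(items: Mapping) -> str:
    """Stable short hash of a flat key-value config."""
    canonical = "\n".join(f"{k}={items[k]}" for k in sorted(items))
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
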