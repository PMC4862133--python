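"""Run provenance: manifest hashing and table headers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__


def manifest_hash(manifest: dict[str, Any]) -> str:
    canonical = json.dumps(manifest, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame, path: str | Path, manifest: dict[str, Any] | None = None
) -> None:
    """Write a TSV with a provenance header (tool version, manifest hash, seed)."""
    seed = (manifest or {}).get("seed", "none")
    digest = manifest_hash(manifest or {})
    header = f"# tecensus {__version__} manifest={digest} seed={seed}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
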