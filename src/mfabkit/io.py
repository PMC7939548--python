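"""Table I/O with provenance headers.

All tables are UTF-8 and tab-separated (CSV accepted by extension for GC-MS
peak tables), one header line, dot decimal separator. Output files carry
'#'-prefixed provenance lines (package version, seed, config hash) above
the header; readers skip them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd


class TableFormatError(ValueError):
    pass


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_table(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a TSV/CSV table, skipping provenance comment lines.

    ``required`` columns are validated; a missing column raises a
    TableFormatError naming the file and column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise TableFormatError(f"{path.name}: missing column(s) {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> Path:
    """Write a table with '#'-prefixed provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = _sep_for(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep=sep, index=False)
    return path


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping (order-insensitive)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
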