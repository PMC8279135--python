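"""CSV table writers and run manifests.

All tables are written as plain RFC-4180-style CSV (UTF-8, header row,
deterministic row order).  Values are serialized at full ``repr``
precision so a round-trip read reproduces them bit-exactly; where a table
has a conventional display precision, rounded companion columns are added
next to the exact ones rather than replacing them.  Each pipeline run also
writes a JSON manifest recording the fully resolved configuration and the
package version, so any output file can be traced back to the exact
invocation that produced it.
"""

from __future__ import annotations

import json
import sys
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

__all__ = ["write_metric_table", "write_manifest", "read_metric_table"]


def write_metric_table(
    rows: pd.DataFrame,
    path: Union[str, Path],
    rounded: Optional[Mapping[str, int]] = None,
) -> Path:
    """Write a metric table as CSV, optionally adding rounded companions.

    ``rounded`` maps a column name to a number of decimals; each named
    column gains a ``<name>_<k>dp`` companion holding the display-rounded
    value, while the original column keeps full precision.  An empty frame
    yields a header-only file.
    """
    path = Path(path)
    out = rows.copy()
    for col, decimals in (rounded or {}).items():
        if col not in out.columns:
            raise KeyError(f"cannot round missing column {col!r}")
        out[f"{col}_{decimals}dp"] = out[col].round(decimals)
    # repr-precision floats so a read round-trips bit-exactly
    out.to_csv(path, index=False, float_format=None, lineterminator="\r\n")
    return path


def read_metric_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_metric_table`."""
    return pd.read_csv(path)


def write_manifest(
    output_dir: Union[str, Path],
    command: str,
    config: Mapping,
    filename: str = "manifest.json",
) -> Path:
    """Record the resolved run configuration next to the outputs."""
    from . import __version__

    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "command": command,
        "config": dict(config),
        "package": "regeval",
        "version": __version__,
        "python": sys.version.split()[0],
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = output_dir / filename
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n", encoding="utf-8")
    return path
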