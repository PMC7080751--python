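"""Readers/writers for the two table formats and run manifests.

Canonical dialect: RFC-4180 CSV, UTF-8, '.' decimal; TSV is accepted on read
(delimiter sniffed from the header line).  Times are stored in days, rates
serialized in /week.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

CLONE_COLUMNS = ["mouse_id", "time_days", "clone_id", "n_basal", "n_suprabasal"]
INTENSITY_COLUMNS = ["mouse_id", "time_days", "fov_id", "cell_id", "intensity", "is_leukocyte"]


class TableValidationError(ValueError):
    """A table is malformed: missing columns or invalid values."""


def _sniff_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def _read(path, required: list, numeric_nonneg: list) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sniff_sep(path))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableValidationError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in numeric_nonneg:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0)
        if bad.any():
            row = int(np.where(bad)[0][0]) + 2  # 1-based, counting the header
            raise TableValidationError(
                f"{path}: invalid (negative or non-numeric) {col} at line {row}"
            )
        df[col] = vals
    return df


def read_clone_table(path) -> pd.DataFrame:
    """Clone table: one record per surviving clone.  Extra columns pass through."""
    df = _read(path, CLONE_COLUMNS, ["time_days", "n_basal", "n_suprabasal"])
    df["n_basal"] = df["n_basal"].astype(np.int64)
    df["n_suprabasal"] = df["n_suprabasal"].astype(np.int64)
    return df


def read_intensity_table(path) -> pd.DataFrame:
    """Intensity table: one record per nucleus."""
    df = _read(path, INTENSITY_COLUMNS, ["time_days", "intensity"])
    df["is_leukocyte"] = df["is_leukocyte"].astype(bool)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_manifest(path, command: str, config: dict, seed, outputs: list, t_start: float) -> None:
    """Machine-readable provenance next to every output artifact."""
    from . import __version__

    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "package_version": __version__,
        "wall_time_s": round(time.time() - t_start, 3),
        "outputs": [str(o) for o in outputs],
    }
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(json.dumps(manifest, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_json(path, payload: dict) -> None:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")
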