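"""Readers and writers for the package's on-disk formats.

Canonical formats: guide count tables and result tables as TSV, flow event
tables as CSV (one row per event, one column per channel), image stacks as
multi-page TIFF (one page per channel) with a JSON sidecar naming the
channels and, for synthetic stacks, holding the planted truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from mitosense.errors import InputError

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_events",
    "write_events",
    "read_image_stack",
    "write_image_stack",
    "write_table",
    "write_run_manifest",
]


def read_count_table(path) -> pd.DataFrame:
    """Read a guide count TSV with header ``guide_id  gene  rep1 rep2 ...``."""
    table = pd.read_csv(path, sep="\t")
    if not {"guide_id", "gene"}.issubset(table.columns):
        raise InputError(f"{path}: count table must have guide_id and gene columns")
    rep_cols = [c for c in table.columns if c not in ("guide_id", "gene")]
    if not rep_cols:
        raise InputError(f"{path}: count table has no replicate columns")
    counts = table[rep_cols]
    if counts.isna().any().any() or (counts < 0).any().any():
        raise InputError(f"{path}: counts must be non-negative integers")
    table[rep_cols] = counts.astype(np.int64)
    return table


def write_count_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_events(path) -> pd.DataFrame:
    """Read a flow event CSV; every non-boolean column is a channel."""
    return pd.read_csv(path)


def write_events(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, lineterminator="\n")


def write_table(table: pd.DataFrame, path) -> None:
    """Write a result table as TSV with a stable float format."""
    table.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def write_image_stack(
    channels: dict[str, np.ndarray], path, sidecar: dict | None = None
) -> None:
    """Write channels as a multi-page TIFF plus a ``<path>.json`` sidecar."""
    path = Path(path)
    names = list(channels)
    stack = np.stack([np.asarray(channels[n], dtype=np.float32) for n in names])
    tifffile.imwrite(path, stack, photometric="minisblack")
    meta = {"channels": names}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2, default=_json_default) + "\n"
    )


def read_image_stack(path) -> tuple[dict[str, np.ndarray], dict]:
    """Read a multi-page TIFF written by :func:`write_image_stack`."""
    path = Path(path)
    pages = tifffile.imread(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise InputError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    names = meta.get("channels")
    if pages.ndim == 2:
        pages = pages[None]
    if names is None or len(names) != pages.shape[0]:
        raise InputError(f"{sidecar_path}: channel names do not match TIFF pages")
    channels = {name: np.asarray(pages[i], dtype=float) for i, name in enumerate(names)}
    return channels, meta


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_run_manifest(out_dir, command: str, params: dict) -> Path:
    """Write a machine-readable manifest of one CLI invocation."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"command": command, "params": params}
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=_json_default) + "\n")
    return path
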