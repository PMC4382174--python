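"""CSV / TIFF / JSON I/O helpers shared by the pipeline and CLI."""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import asdict

import numpy as np
import pandas as pd
import tifffile


def atomic_write_text(path, text: str) -> None:
    """Write text atomically (tmp file + rename) so reruns never tear files."""
    path = os.fspath(path)
    d = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_frame_csv(path, frame: pd.DataFrame) -> None:
    atomic_write_text(path, frame.to_csv(index=False))


def write_json(path, obj) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_mask_tiff(path, mask: np.ndarray) -> None:
    """Write a boolean mask as 8-bit TIFF (0/255)."""
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))


def write_ground_truth(csv_path, json_path, truth) -> None:
    """Ground-truth hairs as CSV plus a JSON sidecar of generator params."""
    write_frame_csv(csv_path, truth.hairs)
    write_json(json_path, {
        "params": asdict(truth.params),
        "analyzed_area_um2": truth.analyzed_area_um2,
    })


def write_positions_csv(path, rows) -> None:
    """Acquisition positions: one row per (wing id, field id, x, y)."""
    frame = pd.DataFrame(rows, columns=["wing_id", "field_id", "x_stage", "y_stage"])
    write_frame_csv(path, frame)
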