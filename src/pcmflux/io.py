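"""Reading and writing movies (TIFF + JSON sidecar) and tables (CSV)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "write_movie",
    "read_movie",
    "write_table",
    "read_table",
]


def write_movie(path, stack: np.ndarray, metadata: dict | None = None) -> None:
    """Write a movie as TIFF (axes T(C)YX) with a JSON metadata sidecar.

    Metadata (pixel_size_nm, frame_interval_s, seed, regime, ...) goes to
    ``<path>.json`` so downstream analysis can recover the calibration.
    """
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))
    if metadata is not None:
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(metadata, indent=2))


def read_movie(path) -> tuple[np.ndarray, dict]:
    """Read a TIFF movie and its JSON sidecar (empty dict when absent)."""
    path = Path(path)
    stack = tifffile.imread(path)
    meta_path = path.with_suffix(path.suffix + ".json")
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return np.asarray(stack), metadata


def write_table(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
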