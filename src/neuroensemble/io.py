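"""CSV readers/writers and run manifests.

Matrices use the supplementary-data layout: plain comma-separated numeric
tables without header, rows = neurons, columns = time steps (connectivity
matrices have neuron labels on both axes).  Values are written with 17
significant digits so round-trips are exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ActivityMatrix

__all__ = [
    "read_matrix_csv",
    "write_matrix_csv",
    "read_activity_csv",
    "write_manifest",
    "read_manifest",
]


def read_matrix_csv(path, header: bool = False) -> np.ndarray:
    """Read a rectangular numeric CSV matrix (no header by default)."""
    try:
        df = pd.read_csv(path, header=0 if header else None, dtype=float,
                         float_precision="round_trip")
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric or ragged table ({exc})") from exc
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(f"{path}: missing or ragged value at row {r}, column {c}")
    return df.to_numpy(dtype=float)


def write_matrix_csv(path, matrix) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.atleast_2d(matrix), delimiter=",", fmt="%.17g")


def read_activity_csv(path, mode: str = "continuous",
                      header: bool = False) -> ActivityMatrix:
    """Read an activity matrix and validate it for the requested mode."""
    return ActivityMatrix(read_matrix_csv(path, header=header), mode=mode)


def write_manifest(path, manifest: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, default=_jsonify) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)!r}")
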