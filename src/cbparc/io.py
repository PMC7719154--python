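"""Readers and writers for the pipeline's on-disk formats.

Volumes (masks, label maps, probability maps) are NIfTI; connectivity
matrices are ``.npy`` arrays with a JSON sidecar recording voxel size,
samples per voxel and the coordinate convention (0-based voxel indices,
half-open down-sampling blocks); tables are CSV with schema checks; configs
round-trip through YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .connectivity import ConnectivityMatrix

COORDINATE_CONVENTION = "0-based voxel indices; half-open down-sampling blocks"


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_label_volume(
    path, values: np.ndarray, coords: np.ndarray, shape, voxel_size=(1.0, 1.0, 1.0)
) -> None:
    """Scatter per-voxel values onto a grid and save as NIfTI."""
    values = np.asarray(values)
    dtype = np.int16 if np.issubdtype(values.dtype, np.integer) else np.float32
    vol = np.zeros(shape, dtype=dtype)
    vol[tuple(np.asarray(coords).T)] = values
    nib.save(nib.Nifti1Image(vol, _affine(voxel_size)), str(path))


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine)."""
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValueError(f"cannot read NIfTI volume {path}: {exc}") from exc
    return np.asarray(img.dataobj), img.affine


def write_matrix(path_base, m: ConnectivityMatrix) -> None:
    """Save counts as .npy with a JSON sidecar of the metadata."""
    base = Path(path_base)
    np.save(base.with_suffix(".npy"), m.counts)
    side = {
        "subject_id": m.subject_id,
        "voxel_size": list(m.voxel_size),
        "samples_per_voxel": int(m.samples_per_voxel),
        "coordinate_convention": COORDINATE_CONVENTION,
        "seed_coords": np.asarray(m.seed_coords).tolist(),
        "column_coords": None
        if m.column_coords is None
        else np.asarray(m.column_coords).tolist(),
        "column_labels": None
        if m.column_labels is None
        else np.asarray(m.column_labels).tolist(),
    }
    base.with_suffix(".json").write_text(json.dumps(side))


def read_matrix(path_base) -> ConnectivityMatrix:
    base = Path(path_base)
    counts = np.load(base.with_suffix(".npy"))
    try:
        side = json.loads(base.with_suffix(".json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"malformed or missing sidecar for {base}: {exc}") from exc
    return ConnectivityMatrix(
        counts=counts,
        seed_coords=np.asarray(side["seed_coords"]),
        voxel_size=tuple(side["voxel_size"]),
        samples_per_voxel=side["samples_per_voxel"],
        column_coords=None
        if side["column_coords"] is None
        else np.asarray(side["column_coords"]),
        column_labels=None
        if side["column_labels"] is None
        else np.asarray(side["column_labels"]),
        subject_id=side["subject_id"],
    )


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_table(path, required_columns: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if required_columns:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise ValueError(f"table {path} is missing column(s) {missing}")
    return df


def write_config(path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def read_config(path) -> dict:
    try:
        out = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed config file {path}: {exc}") from exc
    if not isinstance(out, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    return out
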