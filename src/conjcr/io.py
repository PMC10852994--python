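"""Readers and writers for fields, stacks, masks, designs and boundary points.

Two interchangeable image formats are supported: NIfTI (via nibabel; a
response stack is stored as one 3-D volume per condition with observations
along the last axis) and plain delimited text grids (one file per image,
whitespace-separated rows).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .excursion_geometry import BoundaryPoint, BoundarySegmentSet, ExcursionMask
from .fields import ScalarField

__all__ = [
    "read_field",
    "write_field",
    "read_stack",
    "write_stack",
    "write_mask",
    "read_design",
    "read_contrast",
    "boundary_to_frame",
    "write_boundary_csv",
    "write_json_sidecar",
]


def _is_nifti(path: Path) -> bool:
    return path.suffix == ".nii" or path.name.endswith(".nii.gz")


def write_field(field: ScalarField | np.ndarray, path: str | Path) -> Path:
    """Write a single 2-D field as NIfTI (.nii/.nii.gz) or delimited text."""
    path = Path(path)
    values = field.values if isinstance(field, ScalarField) else np.asarray(field)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float64), np.eye(4)), path)
    else:
        np.savetxt(path, values)
    return path


def read_field(path: str | Path) -> ScalarField:
    path = Path(path)
    if _is_nifti(path):
        values = np.asarray(nib.load(path).dataobj, dtype=np.float64)
    else:
        values = np.loadtxt(path)
    return ScalarField(np.squeeze(values))


def write_stack(stack: np.ndarray, path: str | Path) -> list[Path]:
    """Write an ``(n, H, W)`` observation stack.

    NIfTI target: a single 3-D volume with observations along the last axis.
    Text target: ``path`` is used as a directory holding ``obs_0000.txt`` ...
    """
    stack = np.asarray(stack)
    path = Path(path)
    if _is_nifti(path):
        path.parent.mkdir(parents=True, exist_ok=True)
        vol = np.moveaxis(np.asarray(stack, dtype=np.float64), 0, -1)
        nib.save(nib.Nifti1Image(vol, np.eye(4)), path)
        return [path]
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for i, plane in enumerate(stack):
        p = path / f"obs_{i:04d}.txt"
        np.savetxt(p, plane)
        written.append(p)
    return written


def read_stack(path: str | Path) -> np.ndarray:
    """Read an observation stack written by :func:`write_stack`."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("obs_*.txt"))
        if not files:
            raise FileNotFoundError(f"no obs_*.txt files under {path}")
        return np.stack([np.loadtxt(f) for f in files])
    vol = np.asarray(nib.load(path).dataobj, dtype=np.float64)
    return np.moveaxis(vol, -1, 0)


def write_mask(mask: ExcursionMask, path: str | Path) -> Path:
    """Write a boolean mask as a 0/1 image."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = mask.inside.astype(np.uint8)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(values, np.eye(4)), path)
    else:
        np.savetxt(path, values, fmt="%d")
    return path


def read_design(path: str | Path) -> np.ndarray:
    """Read an ``(n, p)`` design matrix from headerless CSV."""
    return np.atleast_2d(pd.read_csv(path, header=None).to_numpy(dtype=np.float64))


def read_contrast(path: str | Path) -> np.ndarray:
    """Read a contrast vector from headerless CSV (one row or one column)."""
    return pd.read_csv(path, header=None).to_numpy(dtype=np.float64).ravel()


def boundary_to_frame(
    points: list[BoundaryPoint],
    segments: BoundarySegmentSet | None = None,
) -> pd.DataFrame:
    """Tabulate boundary points (edge endpoints, weight, location, segment label)."""
    labels = [""] * len(points)
    if segments is not None:
        for phi, idx in segments.segments.items():
            tag = "+".join(str(i) for i in sorted(phi))
            for j in idx:
                labels[j] = tag
    rows = []
    for pt, lab in zip(points, labels):
        loc = pt.location
        rows.append(
            {
                "p_row": pt.p[0],
                "p_col": pt.p[1],
                "q_row": pt.q[0],
                "q_col": pt.q[1],
                "weight": pt.w,
                "loc_row": loc[0],
                "loc_col": loc[1],
                "segment": lab,
            }
        )
    return pd.DataFrame(rows)


def write_boundary_csv(
    points: list[BoundaryPoint],
    path: str | Path,
    segments: BoundarySegmentSet | None = None,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    boundary_to_frame(points, segments).to_csv(path, index=False)
    return path


def write_json_sidecar(payload: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    path.write_text(json.dumps(payload, indent=2, default=default))
    return path
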