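"""NIfTI and cohort-table readers/writers.

Volumes are NIfTI-1 (plain or gzipped), 3D only; invalid voxels are
encoded as NaN in float outputs.  The cohort table is a CSV with one row
per subject: ``subject_id`` and ``group`` are required, covariates,
scores and TIV optional; missing scores are allowed and simply recorded
(score-based stages run on the complete rows).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .volume import Volume

__all__ = ["read_volume", "write_volume", "read_cohort"]

REQUIRED_COLUMNS = ("subject_id", "group")


def read_volume(path: str | Path) -> Volume:
    """Load a 3D NIfTI-1 volume (data as float64, NaN = invalid)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    elif data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got shape {data.shape}; "
            "split 4D files into per-volume images first"
        )
    return Volume(data.astype(np.float64), np.asarray(img.affine))


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a volume as float32 NIfTI-1 (affine preserved exactly)."""
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    nib.save(img, str(path))


def read_cohort(
    path: str | Path,
    allowed_groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Load and validate the cohort CSV.

    Raises on duplicate subject ids or (when ``allowed_groups`` is
    given) unknown group labels.
    """
    table = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"cohort table lacks required column {col!r}")
    dup = table["subject_id"][table["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id(s): {sorted(set(dup))}")
    if allowed_groups is not None:
        unknown = set(table["group"]) - set(allowed_groups)
        if unknown:
            raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    return table
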