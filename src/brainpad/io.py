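"""NIfTI and table I/O helpers used across the pipeline."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


def write_volume(path: str | Path, data: np.ndarray, spacing: float = 1.0) -> None:
    """Write a cubic volume as NIfTI-1 with an isotropic affine."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    affine = np.diag([spacing, spacing, spacing, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a NIfTI volume (plain or gzipped); returns (data, isotropic spacing)."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # malformed file or wrong format
        raise ValueError(f"could not read NIfTI volume {path}: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], atol=1e-5):
        raise ValueError(f"anisotropic voxels {zooms} in {path}; expected isotropic")
    return data, float(zooms[0])


def read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    """Read a CSV and fail with named columns if the schema is incomplete."""
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df
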