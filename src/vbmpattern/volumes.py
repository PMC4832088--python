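"""Gray-matter volume containers, NIfTI I/O, masking and matrix assembly.

The analysis operates on modulated, smoothed gray-matter partial-volume maps
that share a common voxel grid (typically a 2 mm isotropic MNI grid).  This
module turns a cohort of such maps into a ``VoxelMatrix`` — an
``n_subjects x n_voxels`` array restricted to an analysis mask, with an
invertible map from matrix column back to grid coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "GMVolume",
    "VoxelMatrix",
    "read_gm_volume",
    "write_gm_volume",
    "compute_mask",
    "assemble_matrix",
]

#: Labels recognised for the two diagnostic groups.
CASE_LABEL = "case"
CONTROL_LABEL = "control"


@dataclass
class GMVolume:
    """One subject's 3D gray-matter partial-volume map.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        GM partial-volume values, unitless and non-negative.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform in mm (MNI when the provenance says so).
    subject_id : str
        Identifier used to join with the subject table.
    """

    data: np.ndarray
    affine: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"GM volume must be 3D, got {self.data.ndim}D data"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("GM volume contains non-finite values")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass
class VoxelMatrix:
    """Cohort flattened to subjects x in-mask voxels.

    ``voxel_index`` maps column ``j`` to grid coordinate ``(i, j, k)``;
    columns follow row-major scan order over the mask (last axis fastest),
    so the ordering is stable across runs for a given mask.
    """

    values: np.ndarray
    voxel_index: np.ndarray  # (n_voxels, 3) int grid coordinates
    labels: np.ndarray  # (n_subjects,) strings "case"/"control"
    affine: np.ndarray
    grid_shape: tuple[int, int, int]
    subject_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.intp)
        self.labels = np.asarray(self.labels)
        if self.values.shape[1] != len(self.voxel_index):
            raise ValueError("column count does not match voxel index length")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("label count does not match subject row count")
        if self.subject_ids is None:
            self.subject_ids = np.array(
                [f"sub-{i:03d}" for i in range(self.values.shape[0])]
            )
        else:
            self.subject_ids = np.asarray(self.subject_ids)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    @property
    def case_rows(self) -> np.ndarray:
        return np.flatnonzero(self.labels == CASE_LABEL)

    @property
    def control_rows(self) -> np.ndarray:
        return np.flatnonzero(self.labels == CONTROL_LABEL)

    def unmask(self, row_values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-voxel vector back onto the 3D grid."""
        row_values = np.asarray(row_values, dtype=np.float64)
        if row_values.shape != (self.n_voxels,):
            raise ValueError(
                f"expected vector of length {self.n_voxels}, got {row_values.shape}"
            )
        out = np.full(self.grid_shape, fill, dtype=np.float64)
        i, j, k = self.voxel_index.T
        out[i, j, k] = row_values
        return out

    def world_coords(self, columns: np.ndarray) -> np.ndarray:
        """World (mm) coordinates of the given matrix columns."""
        vox = self.voxel_index[np.asarray(columns, dtype=np.intp)]
        homog = np.c_[vox, np.ones(len(vox))]
        return (self.affine @ homog.T).T[:, :3]


def read_gm_volume(path: str | Path, subject_id: str | None = None) -> GMVolume:
    """Read a NIfTI GM map.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the image is not 3D.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GM volume not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    elif data.ndim != 3:
        raise ValueError(
            f"expected a 3D GM image, got {data.ndim}D with shape {data.shape}"
        )
    sid = subject_id if subject_id is not None else path.name.split(".")[0]
    return GMVolume(data=data, affine=img.affine, subject_id=sid)


def write_gm_volume(volume: GMVolume, path: str | Path) -> Path:
    """Write a GM map as NIfTI-1 (.nii or .nii.gz by extension)."""
    path = Path(path)
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    nib.save(img, str(path))
    return path


def compute_mask(
    volumes: Sequence[GMVolume], min_mean: float = 0.05
) -> np.ndarray:
    """Boolean analysis mask: voxels whose cross-subject mean GM >= min_mean.

    The study's own mask is implicit (in-brain voxels); a mean-GM threshold
    is the usual VBM stand-in and excludes empty background.
    """
    if len(volumes) == 0:
        raise ValueError("need at least one volume to build a mask")
    shape = volumes[0].data.shape
    for v in volumes:
        if v.data.shape != shape:
            raise ValueError(
                f"volume shape mismatch: {v.data.shape} vs {shape}"
            )
    mean = np.mean([v.data for v in volumes], axis=0)
    return mean >= min_mean


def assemble_matrix(
    volumes: Sequence[GMVolume],
    labels: Sequence[str],
    mask: np.ndarray,
) -> VoxelMatrix:
    """Flatten a cohort into a VoxelMatrix restricted to ``mask``.

    Columns follow row-major order over the mask (last grid axis fastest);
    values are copied exactly from the source voxels.
    """
    if len(volumes) != len(labels):
        raise ValueError(
            f"{len(volumes)} volumes but {len(labels)} labels"
        )
    if len(volumes) == 0:
        raise ValueError("empty cohort")
    shape = volumes[0].data.shape
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {shape}")
    voxel_index = np.argwhere(mask)  # row-major, last axis fastest
    values = np.empty((len(volumes), len(voxel_index)), dtype=np.float64)
    for row, v in enumerate(volumes):
        if v.data.shape != shape:
            raise ValueError(
                f"volume shape mismatch: {v.data.shape} vs {shape}"
            )
        values[row] = v.data[mask]
    labels = np.asarray(labels)
    bad = set(labels) - {CASE_LABEL, CONTROL_LABEL}
    if bad:
        raise ValueError(f"unrecognised labels: {sorted(bad)}")
    return VoxelMatrix(
        values=values,
        voxel_index=voxel_index,
        labels=labels,
        affine=volumes[0].affine,
        grid_shape=tuple(shape),
        subject_ids=np.array([v.subject_id for v in volumes]),
    )


def write_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.astype(np.uint8), np.asarray(affine))
    nib.save(img, str(path))
    return path
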