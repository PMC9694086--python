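"""Core containers and rigid-body geometry shared by all pipeline stages.

A :class:`Run` is one functional acquisition: a 4-D intensity grid
(x, y, z, t) with a repetition time and voxel geometry.  Rigid-body motion
is parameterized as a 6-vector ``(rx, ry, rz, tx, ty, tz)``: rotations in
radians about the x, y, z axes (applied in that order, about the volume
center) followed by translations in mm.  This convention is fixed for the
whole package; motion-parameter text files use the FSL column order
(three rotation columns in radians, then three translation columns in mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = ["Run", "rotation_matrix", "rigid_affine", "resample_rigid"]


@dataclass
class Run:
    """One functional acquisition.

    Parameters
    ----------
    data :
        4-D array, spatial axes first, time last ``(nx, ny, nz, nt)``.
    tr :
        Repetition time in seconds.
    voxel_size :
        Edge length of a voxel along each spatial axis, in mm.
    """

    data: np.ndarray
    tr: float
    voxel_size: tuple[float, float, float] = (2.5, 2.5, 2.5)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"Run data must be 4-D (x,y,z,t); got shape {self.data.shape}")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if np.isscalar(self.voxel_size):
            self.voxel_size = (float(self.voxel_size),) * 3
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def frame(self, t: int) -> np.ndarray:
        return self.data[..., t]

    def copy(self) -> "Run":
        return Run(self.data.copy(), self.tr, self.voxel_size, dict(self.meta))

    # ---- NIfTI I/O -------------------------------------------------

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        img.header.set_zooms(tuple(self.voxel_size) + (self.tr,))
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path, tr: float | None = None) -> "Run":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        zooms = img.header.get_zooms()
        if tr is None:
            tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        return cls(data, tr, tuple(float(z) for z in zooms[:3]))


def rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation about x, then y, then z (R = Rz @ Ry @ Rx)."""
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def rigid_affine(
    params: np.ndarray,
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    invert: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-space (matrix, offset) mapping output voxels to input voxels.

    The forward motion maps a world point x (mm, origin at the volume
    center) to ``R x + t``.  Rendering a moved image samples the source at
    the inverse mapping; ``invert=True`` resamples with the forward
    mapping instead (i.e. undoes the motion).
    """
    params = np.asarray(params, dtype=float)
    R = rotation_matrix(*params[:3])
    t = params[3:6]
    S = np.diag(voxel_size)
    Sinv = np.diag([1.0 / v for v in voxel_size])
    c = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    if invert:
        A = Sinv @ R @ S
        b = c - A @ c + Sinv @ t
    else:
        A = Sinv @ R.T @ S
        b = c - A @ c - Sinv @ (R.T @ t)
    return A, b


def resample_rigid(
    vol: np.ndarray,
    params: np.ndarray,
    voxel_size: tuple[float, float, float],
    invert: bool = False,
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Trilinearly resample a 3-D volume under a rigid-body motion.

    With ``invert=False`` the returned image is the volume as it would be
    acquired after the head moved by ``params``; with ``invert=True`` the
    motion is undone (realignment).
    """
    params = np.asarray(params, dtype=float)
    if params.shape != (6,):
        raise ValueError("params must be a 6-vector")
    if not np.any(params):
        return np.asarray(vol, dtype=float).copy()
    A, b = rigid_affine(params, vol.shape, voxel_size, invert=invert)
    return ndimage.affine_transform(vol, A, offset=b, order=order, mode="constant", cval=cval)
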