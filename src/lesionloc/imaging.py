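"""Image containers, NIfTI I/O, resampling and geometric utilities.

All images are carried as numpy arrays indexed ``(i, j, k)`` together with a
4x4 voxel-to-world affine in millimetres (RAS orientation, enforced at load
time).  Two container types exist: :class:`ScalarVolume` for intensity images
(Hounsfield units, or normalised intensities after :func:`ct_preprocess`) and
:class:`LabelVolume` for integer label maps (anatomical parcellations and
lesion segmentations).

Spatial mappings follow the resampling convention used by ITK: a transform
maps points of the *target* (fixed) world frame into the *moving* image's
world frame.  :func:`resample` accepts a single transform or a sequence of
transforms applied left-to-right.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

logger = logging.getLogger(__name__)

#: Default soft-tissue CT window (HU) used for registration preprocessing.
#: [0, 100] HU emphasises brain/CSF contrast over bone.
DEFAULT_CT_WINDOW = (0.0, 100.0)


class VolumeError(ValueError):
    """Raised for malformed volumes or invalid geometric operations."""


def _check_affine(affine: np.ndarray, context: str = "") -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise VolumeError(f"affine must be 4x4{context}")
    if not np.allclose(affine[3], [0.0, 0.0, 0.0, 1.0]):
        raise VolumeError(f"affine last row must be (0,0,0,1){context}")
    if not np.all(np.isfinite(affine)):
        raise VolumeError(f"affine contains non-finite entries{context}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise VolumeError(f"affine is singular{context}")
    return affine


@dataclass
class ScalarVolume:
    """A 3D intensity grid with a voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeError(f"expected 3D data, got {self.data.ndim}D")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm (column norms of the 3x3 affine block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def grid(self) -> "Grid":
        return Grid(self.shape, self.affine)

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.data.copy(), self.affine.copy())


@dataclass
class LabelVolume:
    """A 3D integer-label grid; 0 is background and never named."""

    data: np.ndarray
    affine: np.ndarray
    label_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeError(f"expected 3D data, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise VolumeError("label data must have an integer dtype")
        if self.data.min() < 0:
            raise VolumeError("labels must be non-negative")
        self.affine = _check_affine(self.affine)
        if 0 in self.label_table:
            raise VolumeError("0 is reserved for background")
        present = set(np.unique(self.data)) - {0}
        missing = present - set(self.label_table)
        if missing:
            # auto-name unnamed labels rather than fail: loaders may not know names
            for lab in sorted(missing):
                self.label_table[int(lab)] = f"region_{int(lab):02d}"

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def grid(self) -> "Grid":
        return Grid(self.shape, self.affine)

    def labels(self) -> list[int]:
        """Sorted nonzero labels present in the data."""
        return [int(v) for v in np.unique(self.data) if v != 0]

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.data.copy(), self.affine.copy(), dict(self.label_table))


@dataclass(frozen=True)
class Grid:
    """Geometry of a reference volume: shape plus voxel-to-world affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def world_points(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (N, 3)."""
        idx = np.indices(self.shape, dtype=np.float64).reshape(3, -1).T
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class AffineTransform:
    """A 4x4 world-to-world mapping (mm); maps target-world points to
    moving-world points under the resampling convention."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = _check_affine(self.matrix)

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return points @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def invert(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    @staticmethod
    def identity() -> "AffineTransform":
        return AffineTransform(np.eye(4))


@dataclass
class DeformationField:
    """Dense displacement field d on a reference grid; maps x -> x + d(x).

    ``displacements`` has shape ``(*grid_shape, 3)`` with components in mm in
    world coordinates.
    """

    displacements: np.ndarray
    reference_affine: np.ndarray

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=np.float64)
        if self.displacements.ndim != 4 or self.displacements.shape[-1] != 3:
            raise VolumeError("displacements must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.displacements)):
            raise VolumeError("displacement field contains non-finite values")
        self.reference_affine = _check_affine(self.reference_affine)

    @property
    def grid(self) -> Grid:
        return Grid(self.displacements.shape[:3], self.reference_affine)

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinearly interpolated displacement (mm) at world points."""
        inv = np.linalg.inv(self.reference_affine)
        vox = (np.asarray(points, float) @ inv[:3, :3].T + inv[:3, 3]).T
        out = np.empty((points.shape[0], 3))
        for c in range(3):
            out[:, c] = map_coordinates(
                self.displacements[..., c], vox, order=1, mode="nearest"
            )
        return out

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) + self.sample(points)


Transform = AffineTransform | DeformationField


def invert_affine(t: AffineTransform) -> AffineTransform:
    """Exact matrix inverse of a world-to-world affine."""
    return t.invert()


def compose_affines(*transforms: AffineTransform) -> AffineTransform:
    """Compose affines applied left-to-right as point mappings."""
    m = np.eye(4)
    for t in transforms:
        m = t.matrix @ m
    return AffineTransform(m)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def load_volume(path: str | Path, as_labels: bool = False,
                label_table: Mapping[int, str] | None = None,
                window: tuple[float, float] = DEFAULT_CT_WINDOW,
                ) -> ScalarVolume | LabelVolume:
    """Load a 3D NIfTI volume, reoriented to RAS.

    Label volumes are loaded without any interpolation or rescaling.  For
    scalar volumes, non-finite voxels are replaced by the window minimum and
    counted in a logged warning.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with file name
        raise VolumeError(f"cannot read NIfTI file {path}: {exc}") from exc
    try:
        img = nib.as_closest_canonical(img)
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # noqa: BLE001
        raise VolumeError(f"corrupt image header in {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeError(f"{path}: expected 3D data, got shape {data.shape}")
    try:
        affine = _check_affine(np.asarray(img.affine), f" in {path}")
    except VolumeError as exc:
        raise VolumeError(str(exc)) from None
    if as_labels:
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.allclose(arr, rounded, atol=1e-6):
                raise VolumeError(f"{path}: non-integer values in label volume")
            arr = rounded
        return LabelVolume(arr.astype(np.int32), affine,
                           dict(label_table) if label_table else {})
    arr = np.asarray(data, dtype=np.float32)
    bad = ~np.isfinite(arr)
    if bad.any():
        logger.warning("%s: replaced %d non-finite voxels with window minimum",
                       path, int(bad.sum()))
        arr = arr.copy()
        arr[bad] = window[0]
    return ScalarVolume(arr, affine)


def save_volume(vol: ScalarVolume | LabelVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1, affine in the header."""
    data = vol.data
    if isinstance(vol, LabelVolume):
        data = data.astype(np.int32)
    else:
        data = data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


def save_deformation(fieldvol: DeformationField, path: str | Path) -> None:
    """Write a deformation field as a 4D NIfTI vector image (mm)."""
    nib.save(nib.Nifti1Image(fieldvol.displacements.astype(np.float32),
                             fieldvol.reference_affine), str(path))


def load_deformation(path: str | Path) -> DeformationField:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 5 and data.shape[3] == 1:  # NIfTI vector-intent layout
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise VolumeError(f"{path}: not a 3-vector deformation field")
    return DeformationField(np.asarray(data, float), np.asarray(img.affine))


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def voxel_volume_ml(vol: ScalarVolume | LabelVolume) -> float:
    """Volume of one voxel in mL: |det(3x3 affine block)| / 1000."""
    return float(abs(np.linalg.det(vol.affine[:3, :3])) / 1000.0)


def same_grid(a: ScalarVolume | LabelVolume | Grid,
              b: ScalarVolume | LabelVolume | Grid,
              atol: float = 1e-4) -> bool:
    return tuple(a.shape) == tuple(b.shape) and np.allclose(
        a.affine, b.affine, atol=atol)


def _as_grid(target) -> Grid:
    if isinstance(target, Grid):
        return target
    if isinstance(target, (ScalarVolume, LabelVolume)):
        return target.grid
    shape, affine = target
    return Grid(tuple(int(s) for s in shape), _check_affine(np.asarray(affine)))


def resample(moving: ScalarVolume | LabelVolume,
             transform: Transform | Sequence[Transform] | None,
             target_grid,
             mode: str | None = None,
             fill: float | None = None) -> ScalarVolume | LabelVolume:
    """Resample ``moving`` onto ``target_grid`` through ``transform``.

    ``transform`` maps target-world points into the moving image's world
    frame; a sequence is applied left-to-right; ``None`` means identity.
    Label volumes must use nearest-neighbour interpolation and are filled
    with background 0 outside the moving image; intensity volumes are
    interpolated linearly by default and filled with ``fill`` (default 0,
    the window minimum after preprocessing).
    """
    is_labels = isinstance(moving, LabelVolume)
    if mode is None:
        mode = "nearest" if is_labels else "linear"
    if is_labels and mode != "nearest":
        raise VolumeError("label volumes must be resampled with nearest mode")
    if mode not in ("nearest", "linear"):
        raise VolumeError(f"unknown interpolation mode {mode!r}")
    grid = _as_grid(target_grid)
    if transform is None:
        transforms: list[Transform] = []
    elif isinstance(transform, (AffineTransform, DeformationField)):
        transforms = [transform]
    else:
        transforms = list(transform)

    pts = grid.world_points()
    for t in transforms:
        pts = t.apply(pts)
    inv = np.linalg.inv(moving.affine)
    vox = (pts @ inv[:3, :3].T + inv[:3, 3]).T

    if is_labels:
        out = map_coordinates(moving.data, vox, order=0, mode="constant",
                              cval=0).reshape(grid.shape)
        return LabelVolume(out.astype(moving.data.dtype), grid.affine.copy(),
                           dict(moving.label_table))
    cval = 0.0 if fill is None else float(fill)
    out = map_coordinates(moving.data.astype(np.float32), vox, order=1,
                          mode="constant", cval=cval).reshape(grid.shape)
    return ScalarVolume(out.astype(np.float32), grid.affine.copy())


def ct_preprocess(vol: ScalarVolume,
                  window: tuple[float, float] = DEFAULT_CT_WINDOW) -> ScalarVolume:
    """Clip intensities to a soft-tissue HU window and rescale to [0, 1].

    Geometry is unchanged.  The default window [0, 100] HU suppresses bone
    and air so the correlation metric is driven by brain/CSF contrast.
    """
    lo, hi = window
    if not hi > lo:
        raise VolumeError("window maximum must exceed minimum")
    data = np.clip(vol.data.astype(np.float32), lo, hi)
    data = (data - lo) / (hi - lo)
    return ScalarVolume(data, vol.affine.copy())


def minmax_preprocess(vol: ScalarVolume) -> ScalarVolume:
    """Rescale intensities to [0, 1] by the image min/max (for MR targets)."""
    data = vol.data.astype(np.float32)
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        warnings.warn("constant image in minmax_preprocess; returning zeros")
        return ScalarVolume(np.zeros_like(data), vol.affine.copy())
    return ScalarVolume((data - lo) / (hi - lo), vol.affine.copy())
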