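"""Synthetic head-CT phantoms with known geometry, labels and transforms.

The phantom is a deliberately simple head model — ellipsoidal brain inside an
ellipsoidal skull shell, two ellipsoidal lateral ventricles, Gaussian noise —
whose every property is known analytically.  It serves as the test bed for the
whole pipeline: the parcellation partitions the brain into geometric sectors
(31 by default, of which two are the ventricles), lesions of the four TBI
classes are injected as spheres with exactly known volumes, and cohorts are
created by rendering the reference phantom at known random poses.

No attempt is made at radiological realism (no beam hardening, no partial
volume modelling); the lesion classes differ only by placement convention so
that the quality-control rules can be exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .imaging import (
    AffineTransform,
    LabelVolume,
    ScalarVolume,
    VolumeError,
    resample,
    voxel_volume_ml,
)

#: Lesion class encoding shared with the localiser.
LESION_CLASSES = {1: "iph", 2: "eah", 3: "oedema", 4: "ivh"}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of the synthetic head phantom.

    Distances in mm, intensities in HU.  The default 64**3 grid at 2 mm
    isotropic spacing gives a 128 mm field of view that comfortably contains
    the default brain (semi-axes 40 x 50 x 35 mm) plus skull shell.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_axes: tuple[float, float, float] = (40.0, 50.0, 35.0)
    skull_thickness: float = 6.0
    ventricle_axes: tuple[float, float, float] = (7.0, 16.0, 9.0)
    ventricle_offset: float = 13.0
    n_regions: int = 31
    hu_air: float = -1000.0
    hu_csf: float = 5.0
    hu_brain: float = 35.0
    hu_skull: float = 700.0
    texture_amp_hu: float = 15.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        extent = np.asarray(self.shape) * np.asarray(self.spacing)
        outer = np.asarray(self.brain_axes) + self.skull_thickness
        if np.any(2 * outer >= extent):
            raise VolumeError("brain plus skull does not fit inside the grid")
        if not (self.hu_air < self.hu_csf < self.hu_brain < self.hu_skull):
            raise VolumeError("tissue intensities must be ordered air<CSF<brain<skull")
        if self.n_regions < 3:
            raise VolumeError("need at least 3 regions (two are ventricles)")

    @property
    def affine(self) -> np.ndarray:
        """Voxel-to-world affine placing the world origin at the grid centre."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = -(np.asarray(self.shape) - 1) / 2.0 * np.asarray(self.spacing)
        return aff


def _world_grid(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    aff = spec.affine
    axes = [aff[d, d] * np.arange(spec.shape[d]) + aff[d, 3] for d in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def _partition_brain(spec: PhantomSpec, x, y, z, brain, ventricles):
    """Split the non-ventricular brain into n_regions - 2 geometric sectors.

    Scheme: a central core (normalised ellipsoidal radius < 0.6) plus a
    single outer ring subdivided into azimuthal wedges and, when the count
    is even, superior/inferior bands.  Every sector is contiguous and, at
    the default 31 regions, deep enough to contain a sphere of well over
    1 mL — so lesions can be placed wholly inside any chosen region.
    """
    m = spec.n_regions - 2  # non-ventricular regions
    ax = np.asarray(spec.brain_axes)
    u = np.sqrt((x / ax[0]) ** 2 + (y / ax[1]) ** 2 + (z / ax[2]) ** 2)
    azimuth = np.arctan2(y, x)  # [-pi, pi]

    rest = m - 1
    n_band = 2 if rest % 2 == 0 else 1
    n_wedge = rest // n_band

    labels = np.zeros(spec.shape, dtype=np.int32)
    core = brain & (u < 0.6)
    labels[core] = 1
    ring = brain & ~core
    band_idx = (z >= 0).astype(int) if n_band == 2 else np.zeros(spec.shape, int)
    wedge_idx = np.clip(
        np.floor((azimuth + np.pi) / (2 * np.pi) * n_wedge).astype(int), 0, n_wedge - 1
    )
    ring_label = 2 + band_idx * n_wedge + wedge_idx
    labels[ring] = ring_label[ring]
    labels[ventricles[0]] = spec.n_regions - 1
    labels[ventricles[1]] = spec.n_regions
    return labels


def _texture(spec: PhantomSpec, x, y, z) -> np.ndarray:
    """Smooth deterministic intensity texture emulating parenchymal structure.

    A fixed sum of low-frequency sinusoids of the *canonical* world
    coordinates: under an analytic pose the texture moves rigidly with the
    head, anchoring rotation and scale for intensity-based registration the
    way real anatomy does.
    """
    a = spec.texture_amp_hu
    return a * (np.sin(0.30 * x + 0.5) * np.sin(0.26 * y)
                + np.sin(0.33 * z + 1.0) * np.sin(0.21 * x + 2.0)
                + 0.6 * np.sin(0.16 * x + 0.23 * y + 0.19 * z))


def make_phantom(spec: PhantomSpec | None = None,
                 pose: AffineTransform | None = None,
                 ) -> tuple[ScalarVolume, LabelVolume, LabelVolume]:
    """Build the phantom scan, its parcellation, and the brain mask.

    Returns ``(scan, parcellation, brain_mask)``.  The parcellation labels
    are exactly ``1..n_regions``; the last two labels are the left and right
    ventricles (named ``left_ventricle`` / ``right_ventricle`` in the label
    table).  Deterministic given ``spec.seed``.

    ``pose`` renders the phantom as if the head had been moved by the
    inverse of that world-to-world affine before acquisition: the geometry
    is evaluated analytically at the pose-transformed coordinates, so edges
    stay sharp (no resampling) and registering the posed scan back onto the
    canonical scan should recover ``pose.invert()``.
    """
    spec = spec or PhantomSpec()
    x, y, z = _world_grid(spec)
    if pose is not None:
        pts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
        q = pose.apply(pts)
        x = q[:, 0].reshape(spec.shape)
        y = q[:, 1].reshape(spec.shape)
        z = q[:, 2].reshape(spec.shape)
    ax = np.asarray(spec.brain_axes)
    brain = (x / ax[0]) ** 2 + (y / ax[1]) ** 2 + (z / ax[2]) ** 2 <= 1.0
    outer = ax + spec.skull_thickness
    skull = ((x / outer[0]) ** 2 + (y / outer[1]) ** 2 + (z / outer[2]) ** 2 <= 1.0) & ~brain

    vax = np.asarray(spec.ventricle_axes)
    vents = []
    for sign in (-1.0, 1.0):
        cx = sign * spec.ventricle_offset
        vents.append(
            ((x - cx) / vax[0]) ** 2 + (y / vax[1]) ** 2 + (z / vax[2]) ** 2 <= 1.0
        )
    vents = [v & brain for v in vents]

    hu = np.full(spec.shape, spec.hu_air, dtype=np.float32)
    hu[skull] = spec.hu_skull
    parenchyma = brain & ~(vents[0] | vents[1])
    hu[parenchyma] = (spec.hu_brain + _texture(spec, x, y, z))[parenchyma]
    hu[vents[0] | vents[1]] = spec.hu_csf
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        hu = hu + rng.normal(0.0, spec.noise_sd, spec.shape).astype(np.float32)

    labels = _partition_brain(spec, x, y, z, brain, vents)
    names = {i: f"region_{i:02d}" for i in range(1, spec.n_regions - 1)}
    names[spec.n_regions - 1] = "left_ventricle"
    names[spec.n_regions] = "right_ventricle"
    parc = LabelVolume(labels, spec.affine, names)
    mask = LabelVolume(brain.astype(np.int32), spec.affine, {1: "brain"})
    return ScalarVolume(hu, spec.affine), parc, mask


def ventricle_ids(parc: LabelVolume) -> list[int]:
    """Labels whose names contain 'ventricle'."""
    return [i for i, n in parc.label_table.items() if "ventricle" in n.lower()]


def random_affine(rng: np.random.Generator,
                  max_rotation_deg: float = 15.0,
                  max_translation_mm: float = 10.0,
                  scale_range: tuple[float, float] = (0.9, 1.1)) -> AffineTransform:
    """Random world-to-world affine: rotation, isotropic-ish scale, translation.

    The rotation is about the world origin (the phantom centre).  The
    returned transform is the ground truth to be recovered by registration.
    """
    angles = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg, 3))
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    scales = rng.uniform(*scale_range, 3)
    m = np.eye(4)
    m[:3, :3] = rz @ ry @ rx @ np.diag(scales)
    m[:3, 3] = rng.uniform(-max_translation_mm, max_translation_mm, 3)
    return AffineTransform(m)


def perturb_phantom(scan: ScalarVolume, affine: AffineTransform,
                    noise_sd: float = 0.0, seed: int = 0,
                    fill: float | None = None) -> ScalarVolume:
    """Resample ``scan`` through ``affine`` (plus fresh noise) on its own grid.

    ``affine`` maps output-grid world points into the input scan's world
    frame, i.e. it is exactly the transform a registration of the output
    back to the input should recover.
    """
    if fill is None:
        fill = float(np.percentile(scan.data, 0.1))  # approximately air
    out = resample(scan, affine, scan.grid, mode="linear", fill=fill)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = ScalarVolume(
            out.data + rng.normal(0.0, noise_sd, out.shape).astype(np.float32),
            out.affine,
        )
    return out


def make_cohort(spec: PhantomSpec, n: int, seed: int = 0,
                max_rotation_deg: float = 15.0,
                max_translation_mm: float = 10.0,
                scale_range: tuple[float, float] = (0.9, 1.1),
                noise_sd: float = 5.0,
                ) -> tuple[list[ScalarVolume], list[AffineTransform]]:
    """A cohort of n scans: the reference phantom rendered at known random poses.

    Each scan is generated analytically at its pose (sharp edges, as if the
    head had been repositioned before acquisition) with an independent noise
    realisation.  Registering scan i back onto the canonical phantom should
    recover ``truths[i].invert()``.
    """
    rng = np.random.default_rng(seed)
    scans, truths = [], []
    for _ in range(n):
        t = random_affine(rng, max_rotation_deg, max_translation_mm, scale_range)
        posed_spec = replace(spec, noise_sd=noise_sd,
                             seed=int(rng.integers(2**31)))
        posed, _, _ = make_phantom(posed_spec, pose=t)
        scans.append(posed)
        truths.append(t)
    return scans, truths


def inject_lesion(scan: ScalarVolume, parcellation: LabelVolume,
                  class_id: int, center_mm: Sequence[float], radius_mm: float,
                  intensity_hu: float = 65.0,
                  seg: LabelVolume | None = None,
                  ) -> tuple[ScalarVolume, LabelVolume, pd.DataFrame]:
    """Paint a spherical lesion and return scan, segmentation, ground truth.

    The segmentation marks exactly the painted voxels with ``class_id``.  The
    ground-truth per-region table is computed by exhaustive voxel counting
    against the true parcellation (independent of the pipeline's own
    bookkeeping).  An existing ``seg`` may be passed to accumulate lesions.
    """
    if class_id not in LESION_CLASSES:
        raise VolumeError(f"lesion class must be in 1..4, got {class_id}")
    aff = scan.affine
    idx = np.indices(scan.shape).reshape(3, -1).T
    world = idx @ aff[:3, :3].T + aff[:3, 3]
    d2 = np.sum((world - np.asarray(center_mm, float)) ** 2, axis=1)
    sphere = (d2 <= radius_mm**2).reshape(scan.shape)
    if not sphere.any():
        raise VolumeError("lesion sphere does not intersect the grid")

    data = scan.data.copy()
    data[sphere] = intensity_hu
    new_scan = ScalarVolume(data, aff.copy())

    seg_data = seg.data.copy() if seg is not None else np.zeros(scan.shape, np.int32)
    seg_data[sphere] = class_id
    names = {k: v for k, v in LESION_CLASSES.items()}
    new_seg = LabelVolume(seg_data, aff.copy(), names)

    vox_ml = voxel_volume_ml(scan)
    rows = []
    for region in parcellation.labels():
        rmask = parcellation.data == region
        row = {"region_id": region,
               "region_name": parcellation.label_table[region],
               "region_volume_ml": float(rmask.sum()) * vox_ml}
        for cid, cname in LESION_CLASSES.items():
            row[f"{cname}_ml"] = float(np.sum(rmask & (seg_data == cid))) * vox_ml
        rows.append(row)
    bg = parcellation.data == 0
    row = {"region_id": 0, "region_name": "unassigned",
           "region_volume_ml": 0.0}
    for cid, cname in LESION_CLASSES.items():
        row[f"{cname}_ml"] = float(np.sum(bg & (seg_data == cid))) * vox_ml
    rows.append(row)
    total = {"region_id": -1, "region_name": "whole_brain",
             "region_volume_ml": float((parcellation.data > 0).sum()) * vox_ml}
    for cid, cname in LESION_CLASSES.items():
        total[f"{cname}_ml"] = float(np.sum(seg_data == cid)) * vox_ml
    rows.append(total)
    return new_scan, new_seg, pd.DataFrame(rows)


def deepest_point(mask: np.ndarray, affine: np.ndarray) -> tuple[np.ndarray, float]:
    """World coordinates and depth (mm) of the point deepest inside a mask.

    Useful for placing lesions guaranteed to lie wholly inside one region:
    any sphere centred there with radius below the returned depth is
    contained in the mask.
    """
    spacing = np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)
    dist = distance_transform_edt(mask, sampling=spacing)
    ijk = np.unravel_index(int(np.argmax(dist)), mask.shape)
    world = np.asarray(affine)[:3, :3] @ np.asarray(ijk, float) + np.asarray(affine)[:3, 3]
    return world, float(dist[ijk])


def mni_standin(spec: PhantomSpec | None = None,
                warp_amplitude_mm: float = 3.0,
                grid_shape: tuple[int, int, int] = (72, 72, 72),
                grid_spacing: float = 1.8,
                ) -> tuple[ScalarVolume, LabelVolume, "DeformationField"]:
    """A synthetic cross-modality target standing in for the MNI template.

    Built by warping the reference phantom through a known smooth sinusoidal
    deformation onto a different grid and remapping tissue intensities to an
    MR-like contrast (bright brain, darker CSF, dark bone).  Returns the
    stand-in image, its parcellation (the warped ground-truth parcellation),
    and the known deformation (mapping stand-in world -> phantom world).
    """
    from .imaging import DeformationField, Grid

    spec = spec or PhantomSpec()
    scan, parc, _ = make_phantom(spec)

    mni_spec = replace(spec, shape=grid_shape,
                       spacing=(grid_spacing,) * 3)
    aff = mni_spec.affine
    grid = Grid(grid_shape, aff)
    pts = grid.world_points()
    # smooth, small-amplitude periodic displacement: invertible in practice
    k = np.pi / 60.0
    disp = np.stack([
        warp_amplitude_mm * np.sin(k * pts[:, 1]),
        warp_amplitude_mm * np.sin(k * pts[:, 2]),
        warp_amplitude_mm * np.sin(k * pts[:, 0]),
    ], axis=1).reshape(*grid_shape, 3)
    field = DeformationField(disp, aff)

    warped = resample(scan, field, grid, mode="linear", fill=spec.hu_air)
    warped_parc = resample(parc, field, grid)

    hu = warped.data
    mri = np.zeros_like(hu, dtype=np.float32)
    mid_csf = (spec.hu_csf + spec.hu_brain) / 2.0
    mid_brain = (spec.hu_brain + spec.hu_skull) / 2.0
    mri[hu > -500] = 0.10          # scalp/skull region: dark in T1-like contrast
    mri[(hu > -500) & (hu < mid_csf)] = 0.25   # CSF
    brain_vox = (hu >= mid_csf) & (hu < mid_brain)
    # bright parenchyma, with the anatomical texture carried through so the
    # stand-in has internal structure the way a real T1 does
    mri[brain_vox] = np.clip(0.70 + (hu[brain_vox] - spec.hu_brain) * 0.005,
                             0.45, 0.95)
    return ScalarVolume(mri, aff), warped_parc, field
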