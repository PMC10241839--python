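"""Affine and deformable intensity-based registration.

The registration engine is SimpleITK; this module wraps it behind the
package's own containers and conventions and adds the two ingredients the
pipeline depends on: the Pearson-correlation similarity metric used both as
the optimisation objective and as the quality-control proxy (SM), and
multi-seed best-result selection, where each seed perturbs the initial
transform parameters to increase robustness of the initialisation.

All transforms map target-world (fixed) points into the moving image's world
frame, matching :func:`lesionloc.imaging.resample`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .imaging import (
    AffineTransform,
    DeformationField,
    LabelVolume,
    ScalarVolume,
    VolumeError,
    resample,
    same_grid,
)

logger = logging.getLogger(__name__)

#: Intensity above which a preprocessed voxel counts as foreground.
FOREGROUND_THRESHOLD = 0.01

#: Initial-transform perturbation ranges per seed (seed 0 is unperturbed).
SEED_MAX_ROTATION_DEG = 10.0
SEED_MAX_TRANSLATION_MM = 10.0
SEED_MAX_LOG_SCALE = 0.1


@dataclass
class RegistrationResult:
    """Outcome of one registration: transform, similarity (SM), seed."""

    transform: AffineTransform | DeformationField
    similarity: float
    seed: int = 0
    success: bool = True
    message: str = ""
    #: final optimiser objective (ITK convention: lower is better); used for
    #: best-seed selection when the objective is not the correlation itself
    objective: float = float("inf")

    def __post_init__(self) -> None:
        if not np.isfinite(self.similarity):
            raise VolumeError("similarity must be finite")
        # clamp microscopic numerical excursions outside [-1, 1]
        self.similarity = float(np.clip(self.similarity, -1.0, 1.0))


def similarity(a: ScalarVolume, b: ScalarVolume,
               mask: LabelVolume | np.ndarray | None = None) -> float:
    """Pearson correlation coefficient of intensities over mask voxels.

    With no mask, voxels where either image exceeds the foreground threshold
    are used.  Zero variance in either image yields 0 with a warning.
    """
    if not same_grid(a, b):
        raise VolumeError("similarity requires both images on the same grid")
    if mask is None:
        m = (a.data > FOREGROUND_THRESHOLD) | (b.data > FOREGROUND_THRESHOLD)
    elif isinstance(mask, LabelVolume):
        if not same_grid(mask, a):
            raise VolumeError("mask must share the image grid")
        m = mask.data > 0
    else:
        m = np.asarray(mask) > 0
    va = a.data[m].astype(np.float64)
    vb = b.data[m].astype(np.float64)
    if va.size < 2:
        warnings.warn("similarity: empty or singleton mask; returning 0")
        return 0.0
    sa, sb = va.std(), vb.std()
    if sa == 0.0 or sb == 0.0:
        warnings.warn("similarity: zero intensity variance in mask; returning 0")
        return 0.0
    r = float(np.mean((va - va.mean()) * (vb - vb.mean())) / (sa * sb))
    return float(np.clip(r, -1.0, 1.0))


def invert_affine(t: AffineTransform) -> AffineTransform:
    """Matrix inverse; compose(t, invert_affine(t)) is identity to ~1e-8."""
    return t.invert()


# ---------------------------------------------------------------------------
# SimpleITK interop
# ---------------------------------------------------------------------------


def _to_sitk(vol: ScalarVolume) -> sitk.Image:
    arr = np.ascontiguousarray(np.transpose(vol.data.astype(np.float32), (2, 1, 0)))
    img = sitk.GetImageFromArray(arr)
    A = vol.affine[:3, :3]
    spacing = np.linalg.norm(A, axis=0)
    direction = A / spacing  # columns normalised
    img.SetSpacing([float(s) for s in spacing])
    img.SetDirection([float(v) for v in direction.flatten()])
    img.SetOrigin([float(v) for v in vol.affine[:3, 3]])
    return img


def _mask_to_sitk(mask: np.ndarray, like: sitk.Image) -> sitk.Image:
    arr = np.ascontiguousarray(np.transpose(mask.astype(np.uint8), (2, 1, 0)))
    img = sitk.GetImageFromArray(arr)
    img.CopyInformation(like)
    return img


def _affine_from_sitk(tx: sitk.Transform) -> AffineTransform:
    tx = sitk.AffineTransform(tx)
    A = np.asarray(tx.GetMatrix(), float).reshape(3, 3)
    t = np.asarray(tx.GetTranslation(), float)
    c = np.asarray(tx.GetCenter(), float)
    m = np.eye(4)
    m[:3, :3] = A
    m[:3, 3] = t + c - A @ c
    return AffineTransform(m)


def _rotation(angles_rad: np.ndarray) -> np.ndarray:
    cx, cy, cz = np.cos(angles_rad)
    sx, sy, sz = np.sin(angles_rad)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _initial_affine(fixed: sitk.Image, moving: sitk.Image, seed: int,
                    initializer: str = "moments") -> sitk.AffineTransform:
    modes = {"moments": sitk.CenteredTransformInitializerFilter.MOMENTS,
             "geometry": sitk.CenteredTransformInitializerFilter.GEOMETRY}
    if initializer not in modes:
        raise VolumeError(f"unknown initializer {initializer!r}")
    tx = sitk.CenteredTransformInitializer(
        fixed, moving, sitk.AffineTransform(3), modes[initializer])
    tx = sitk.AffineTransform(tx)
    if seed != 0:
        rng = np.random.default_rng(seed)
        angles = np.deg2rad(rng.uniform(-SEED_MAX_ROTATION_DEG,
                                        SEED_MAX_ROTATION_DEG, 3))
        scales = np.exp(rng.uniform(-SEED_MAX_LOG_SCALE, SEED_MAX_LOG_SCALE, 3))
        shift = rng.uniform(-SEED_MAX_TRANSLATION_MM, SEED_MAX_TRANSLATION_MM, 3)
        A = np.asarray(tx.GetMatrix(), float).reshape(3, 3)
        P = _rotation(angles) @ np.diag(scales)
        tx.SetMatrix([float(v) for v in (P @ A).flatten()])
        tx.SetTranslation([float(v) for v in np.asarray(tx.GetTranslation()) + shift])
    return tx


def _fixed_mask(fixed: ScalarVolume) -> np.ndarray:
    return fixed.data > FOREGROUND_THRESHOLD


def register_affine(moving: ScalarVolume, fixed: ScalarVolume, seed: int = 0,
                    shrink_factors: tuple[int, ...] = (8, 4, 2, 1),
                    smoothing_sigmas: tuple[float, ...] = (3.0, 2.0, 1.0, 0.0),
                    iterations: int = 200,
                    metric: str = "correlation",
                    initializer: str = "moments",
                    ) -> RegistrationResult:
    """12-DOF affine registration of ``moving`` onto ``fixed``.

    Inputs are expected preprocessed (``ct_preprocess``) so the correlation
    metric and the foreground mask are meaningful.  Deterministic given
    (moving, fixed, seed): the optimiser is a regular-step gradient descent
    over a fixed 4-level multi-resolution schedule with single-threaded
    metric evaluation; the seed only perturbs the initial transform.  On optimiser
    failure the identity transform is returned flagged unsuccessful, with
    its (poor) similarity recorded for downstream QC.

    ``metric`` is the optimisation objective: ``correlation`` (the default;
    also the SM reported in the result) or ``mattes`` (mutual information,
    for cross-modality targets where intensities are not linearly related).
    The reported similarity is always the Pearson SM.
    """
    if metric not in ("correlation", "mattes"):
        raise VolumeError(f"unknown metric {metric!r}")
    if initializer not in ("moments", "geometry"):
        raise VolumeError(f"unknown initializer {initializer!r}")
    fimg = _to_sitk(fixed)
    mimg = _to_sitk(moving)
    mask = _fixed_mask(fixed)
    try:
        tx = _initial_affine(fimg, mimg, seed, initializer=initializer)
        reg = sitk.ImageRegistrationMethod()
        reg.SetNumberOfWorkUnits(1)
        if metric == "correlation":
            reg.SetMetricAsCorrelation()
        else:
            reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
        reg.SetMetricFixedMask(_mask_to_sitk(mask, fimg))
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=1.0, minStep=1e-4, numberOfIterations=iterations,
            relaxationFactor=0.6)
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetShrinkFactorsPerLevel(list(shrink_factors))
        reg.SetSmoothingSigmasPerLevel(list(smoothing_sigmas))
        reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
        reg.SetInitialTransform(tx, inPlace=True)
        reg.Execute(fimg, mimg)
        transform = _affine_from_sitk(tx)
        warped = resample(moving, transform, fixed.grid, mode="linear")
        sim = similarity(warped, fixed, mask=mask)
        if not np.isfinite(sim):
            raise RuntimeError("non-finite similarity")
        return RegistrationResult(transform, sim, seed=seed,
                                  objective=float(reg.GetMetricValue()))
    except Exception as exc:  # noqa: BLE001 - QC catches flagged failures
        logger.warning("affine registration failed (seed %d): %s", seed, exc)
        ident = AffineTransform.identity()
        warped = resample(moving, ident, fixed.grid, mode="linear")
        sim = similarity(warped, fixed, mask=mask)
        return RegistrationResult(ident, sim, seed=seed, success=False,
                                  message=str(exc))


def register_affine_multiseed(moving: ScalarVolume, fixed: ScalarVolume,
                              n_seeds: int = 4, **kwargs) -> RegistrationResult:
    """Run :func:`register_affine` once per seed and keep the best result.

    The result with the highest similarity wins; exact ties go to the lowest
    seed index.  If every seed fails, the best (possibly identity) result is
    returned still flagged unsuccessful.
    """
    if n_seeds < 1:
        raise VolumeError("n_seeds must be >= 1")
    by_objective = kwargs.get("metric", "correlation") != "correlation"
    best: RegistrationResult | None = None
    for seed in range(n_seeds):
        res = register_affine(moving, fixed, seed=seed, **kwargs)
        if best is None:
            best = res
        elif by_objective:
            if res.objective < best.objective:
                best = res
        elif res.similarity > best.similarity:
            best = res
    assert best is not None
    return best


def register_deformable(moving: ScalarVolume, fixed: ScalarVolume,
                        control_spacing_voxels: float = 8.0,
                        shrink_factors: tuple[int, ...] = (4, 2),
                        smoothing_sigmas: tuple[float, ...] = (2.0, 1.0),
                        iterations: int = 15,
                        metric: str = "correlation",
                        ) -> RegistrationResult:
    """Free-form deformable registration returning a dense displacement field.

    A coarse B-spline control grid (default spacing 8 voxels) is optimised
    against the chosen metric; the coarse grid itself acts as the
    smoothness constraint.  Inputs must already be approximately affinely
    aligned.  With the default correlation metric, if the optimised field
    does not improve the masked similarity the zero field is returned
    instead (similarity after warping is then never below the similarity
    before warping); with ``mattes`` (cross-modality) the Pearson gate does
    not apply.
    """
    if metric not in ("correlation", "mattes"):
        raise VolumeError(f"unknown metric {metric!r}")
    fimg = _to_sitk(fixed)
    mimg = _to_sitk(moving)
    mask = _fixed_mask(fixed)
    sim_before = similarity(moving, fixed, mask=mask) if same_grid(moving, fixed) \
        else similarity(resample(moving, None, fixed.grid, mode="linear"), fixed, mask=mask)

    zero = DeformationField(np.zeros((*fixed.shape, 3)), fixed.affine.copy())
    try:
        mesh = np.maximum(
            (np.asarray(fixed.shape) / control_spacing_voxels).astype(int) - 3, 1)
        tx = sitk.BSplineTransformInitializer(fimg, [int(v) for v in mesh])
        reg = sitk.ImageRegistrationMethod()
        reg.SetNumberOfWorkUnits(1)
        if metric == "correlation":
            reg.SetMetricAsCorrelation()
        else:
            reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
        reg.SetMetricFixedMask(_mask_to_sitk(mask, fimg))
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsLBFGSB(gradientConvergenceTolerance=1e-5,
                                 numberOfIterations=iterations)
        reg.SetShrinkFactorsPerLevel(list(shrink_factors))
        reg.SetSmoothingSigmasPerLevel(list(smoothing_sigmas))
        reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
        reg.SetInitialTransform(tx, inPlace=True)
        reg.Execute(fimg, mimg)

        to_field = sitk.TransformToDisplacementFieldFilter()
        to_field.SetReferenceImage(fimg)
        fld = to_field.Execute(tx)
        disp = sitk.GetArrayFromImage(fld)  # (z, y, x, 3), physical mm
        disp = np.ascontiguousarray(np.transpose(disp, (2, 1, 0, 3)))
        field = DeformationField(disp.astype(np.float64), fixed.affine.copy())

        warped = resample(moving, field, fixed.grid, mode="linear")
        sim_after = similarity(warped, fixed, mask=mask)
        if metric == "correlation" and (not np.isfinite(sim_after)
                                        or sim_after < sim_before):
            logger.info("deformable registration did not improve similarity "
                        "(%.4f -> %.4f); keeping zero field", sim_before, sim_after)
            return RegistrationResult(zero, sim_before, seed=0)
        return RegistrationResult(field, sim_after, seed=0,
                                  objective=float(reg.GetMetricValue()))
    except Exception as exc:  # noqa: BLE001
        logger.warning("deformable registration failed: %s", exc)
        return RegistrationResult(zero, sim_before, seed=0, success=False,
                                  message=str(exc))


# ---------------------------------------------------------------------------
# Deformation-field utilities
# ---------------------------------------------------------------------------


def jacobian_determinant(fieldvol: DeformationField) -> np.ndarray:
    """Voxelwise Jacobian determinant of x -> x + d(x); > 0 means no folding."""
    spacing = np.linalg.norm(fieldvol.reference_affine[:3, :3], axis=0)
    d = fieldvol.displacements
    J = np.zeros((*d.shape[:3], 3, 3))
    for comp in range(3):
        grads = np.gradient(d[..., comp], *spacing)
        for axis in range(3):
            J[..., comp, axis] = grads[axis]
    J += np.eye(3)
    return np.linalg.det(J)


def invert_deformation(fieldvol: DeformationField,
                       target_grid=None,
                       tol_voxel: float = 0.1,
                       max_iters: int = 50) -> DeformationField:
    """Numerical inverse of a displacement field by fixed-point iteration.

    Solves x + d(x) = y for every y of ``target_grid`` (default: the field's
    own grid); the inverse displacement is e(y) = x - y.  Converges for the
    moderate, smooth fields produced by the deformable registration.
    """
    from .imaging import _as_grid

    grid = fieldvol.grid if target_grid is None else _as_grid(target_grid)
    spacing = float(np.min(np.linalg.norm(grid.affine[:3, :3], axis=0)))
    y = grid.world_points()
    x = y.copy()
    for _ in range(max_iters):
        x_new = y - fieldvol.sample(x)
        delta = np.max(np.linalg.norm(x_new - x, axis=1))
        x = x_new
        if delta < tol_voxel * spacing:
            break
    disp = (x - y).reshape(*grid.shape, 3)
    return DeformationField(disp, np.asarray(grid.affine, float).copy())
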