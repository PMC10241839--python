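"""Propagation of an MNI-space parcellation to the CT template space.

The CT template is registered to the MNI-space template (affine followed by
deformable refinement); the composed mapping and its numerical inverse are
stored as dense displacement fields, the parcellation is pulled into
template space with nearest-neighbour interpolation, and the labels are then
dilated beyond the brain so that affine-only patient mappings of heads of
different sizes never lose lesion voxels off the edge of the atlas.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.ndimage import distance_transform_edt

from .imaging import (
    AffineTransform,
    DeformationField,
    LabelVolume,
    ScalarVolume,
    VolumeError,
    resample,
    same_grid,
)
from .registration import register_affine_multiseed, register_deformable
from .template import TemplateBundle

logger = logging.getLogger(__name__)

DEFAULT_DILATION_MM = 10.0


def map_mni_to_template(template: ScalarVolume,
                        mni_template: ScalarVolume,
                        mni_parcellation: LabelVolume,
                        n_seeds: int = 4,
                        deformable_kwargs: dict | None = None,
                        ) -> tuple[LabelVolume, DeformationField, DeformationField]:
    """Transfer an MNI-space parcellation onto the CT template grid.

    Registers the template to the MNI image (affine, then deformable
    refinement), composes both into a single dense template-to-MNI
    displacement field, computes its numerical inverse on the MNI grid, and
    pulls the parcellation into template space with nearest-neighbour
    interpolation (the label set is never extended).

    Returns ``(parcellation_in_template_space, fwd_field, inv_field)`` where
    the forward field maps template-world points to MNI-world points.
    """
    if not same_grid(mni_parcellation, mni_template):
        raise VolumeError("mni_parcellation must be on the mni_template grid")

    # affine: moving = MNI image, fixed = template, so the result maps
    # template world -> MNI world (the forward direction we want to store).
    # CT and MR intensities are not linearly related, so both stages use
    # mutual information rather than correlation.
    res_aff = register_affine_multiseed(mni_template, template, n_seeds=n_seeds,
                                        metric="mattes")
    if not res_aff.success:
        raise VolumeError("template-to-MNI affine registration failed: "
                          f"{res_aff.message}")
    t_aff = res_aff.transform

    aligned = resample(mni_template, t_aff, template.grid, mode="linear")
    res_def = register_deformable(aligned, template, metric="mattes",
                                  **(deformable_kwargs or {}))
    if not res_def.success:
        raise VolumeError("template-to-MNI deformable registration failed: "
                          f"{res_def.message}")
    d = res_def.transform  # template world -> affinely-aligned MNI frame

    # forward composite as one dense field on the template grid:
    #   x -> t_aff(x + d(x)); stored as displacement f(x) = t_aff(x+d(x)) - x
    tgrid = template.grid
    pts = tgrid.world_points()
    fwd_pts = t_aff.apply(d.apply(pts))
    fwd = DeformationField((fwd_pts - pts).reshape(*tgrid.shape, 3),
                           template.affine.copy())

    # inverse on the MNI grid: undo the affine exactly, then fixed-point
    # invert the small deformable part
    mni_grid = mni_template.grid
    y = mni_grid.world_points()
    z = t_aff.invert().apply(y)
    x = z.copy()
    for _ in range(50):
        x_new = z - d.sample(x)
        step = np.max(np.linalg.norm(x_new - x, axis=1))
        x = x_new
        if step < 0.1 * float(np.min(template.spacing)):
            break
    inv = DeformationField((x - y).reshape(*mni_grid.shape, 3),
                           np.asarray(mni_grid.affine, float).copy())

    parc_t = resample(mni_parcellation, fwd, tgrid)
    return parc_t, fwd, inv


def dilate_parcellation(parcellation: LabelVolume,
                        margin_mm: float = DEFAULT_DILATION_MM) -> LabelVolume:
    """Nearest-label dilation of the parcellation by ``margin_mm``.

    Every background voxel within ``margin_mm`` of the labelled region is
    assigned the label of its nearest labelled voxel (Euclidean distance in
    mm); originally labelled voxels are never changed.  This extends the
    atlas beyond the skull so lesions in larger heads still receive a
    region under affine-only mapping.
    """
    if margin_mm < 0:
        raise VolumeError("margin must be non-negative")
    if margin_mm == 0:
        return parcellation.copy()
    spacing = parcellation.spacing
    background = parcellation.data == 0
    dist, (ii, jj, kk) = distance_transform_edt(
        background, sampling=spacing, return_indices=True)
    out = parcellation.data.copy()
    grow = background & (dist <= margin_mm)
    out[grow] = parcellation.data[ii[grow], jj[grow], kk[grow]]
    return LabelVolume(out, parcellation.affine.copy(),
                       dict(parcellation.label_table))


def attach_atlas(bundle: TemplateBundle,
                 mni_template: ScalarVolume,
                 mni_parcellation: LabelVolume,
                 ventricle_ids: list[int] | None = None,
                 dilation_mm: float = DEFAULT_DILATION_MM,
                 n_seeds: int = 4) -> TemplateBundle:
    """Populate a template bundle with parcellation, mask and MNI transforms.

    The brain mask is the pre-dilation labelled region; the stored
    parcellation is dilated by ``dilation_mm``.  Ventricle labels default to
    those whose names contain "ventricle".
    """
    parc_t, fwd, inv = map_mni_to_template(
        bundle.template, mni_template, mni_parcellation, n_seeds=n_seeds)
    mask = LabelVolume((parc_t.data > 0).astype(np.int32),
                       parc_t.affine.copy(), {1: "brain"})
    if ventricle_ids is None:
        ventricle_ids = [i for i, n in parc_t.label_table.items()
                         if "ventricle" in n.lower()]
    bundle.parcellation = dilate_parcellation(parc_t, dilation_mm)
    bundle.brain_mask = mask
    bundle.ct_to_mni_fwd = fwd
    bundle.ct_to_mni_inv = inv
    bundle.ventricle_ids = list(ventricle_ids)
    return bundle


def map_segmentation_to_mni(seg: LabelVolume,
                            patient_affine: AffineTransform,
                            bundle: TemplateBundle) -> LabelVolume:
    """Map a native-space lesion segmentation onto the MNI grid.

    ``patient_affine`` is the template-to-native transform returned by the
    localiser's registration step.  The composition MNI -> template ->
    native is applied with nearest-neighbour resampling, so class labels are
    preserved exactly.
    """
    if bundle.ct_to_mni_inv is None:
        raise VolumeError("bundle has no ct_to_mni transform; run attach_atlas")
    mni_grid = bundle.ct_to_mni_inv.grid
    return resample(seg, [bundle.ct_to_mni_inv, patient_affine], mni_grid)
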