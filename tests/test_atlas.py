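"""Parcellation transfer, dilation, and mapping segmentations to MNI space."""

import numpy as np
import pytest

from lesionloc.atlas import (
    attach_atlas,
    dilate_parcellation,
    map_mni_to_template,
    map_segmentation_to_mni,
)
from lesionloc.imaging import (
    AffineTransform,
    DeformationField,
    LabelVolume,
    VolumeError,
    ct_preprocess,
    voxel_volume_ml,
)
from lesionloc.phantom import deepest_point, inject_lesion, make_phantom, mni_standin
from lesionloc.registration import invert_deformation
from lesionloc.template import TemplateBundle


def _labels(data, spacing=1.0, names=None):
    aff = np.eye(4)
    aff[:3, :3] *= spacing
    return LabelVolume(np.asarray(data, np.int32), aff, names or {})


class TestDilation:
    def test_margin_zero_is_identity(self, phantom):
        _, parc, _ = phantom
        out = dilate_parcellation(parc, 0.0)
        assert np.array_equal(out.data, parc.data)

    def test_single_voxel_grows_to_euclidean_ball(self):
        arr = np.zeros((15, 15, 15), np.int32)
        arr[7, 7, 7] = 3
        out = dilate_parcellation(_labels(arr, names={3: "x"}), 3.0)
        # distance-transform oracle: exactly the voxels within 3 mm
        ii, jj, kk = np.indices(arr.shape)
        d2 = (ii - 7) ** 2 + (jj - 7) ** 2 + (kk - 7) ** 2
        np.testing.assert_array_equal(out.data == 3, d2 <= 9.0)

    def test_original_labels_never_overwritten(self, phantom):
        _, parc, _ = phantom
        out = dilate_parcellation(parc, 6.0)
        orig = parc.data > 0
        assert np.array_equal(out.data[orig], parc.data[orig])

    def test_monotone_in_margin(self, phantom):
        _, parc, _ = phantom
        small = dilate_parcellation(parc, 4.0)
        large = dilate_parcellation(parc, 8.0)
        assert np.all((small.data > 0) <= (large.data > 0))

    def test_no_new_labels(self, phantom):
        _, parc, _ = phantom
        out = dilate_parcellation(parc, 10.0)
        assert set(np.unique(out.data)) <= set(np.unique(parc.data))


class TestMapMniToTemplate:
    @pytest.fixture(scope="class")
    def mapped(self, small_spec):
        """Template registered to a known-warp MNI stand-in."""
        scan, parc, mask = make_phantom(small_spec)
        mni_img, mni_parc, true_field = mni_standin(
            small_spec, grid_shape=(56, 56, 56), grid_spacing=2.2)
        template = ct_preprocess(scan)
        parc_t, fwd, inv = map_mni_to_template(template, mni_img, mni_parc,
                                               n_seeds=2)
        return scan, parc, template, mni_parc, parc_t, fwd, inv

    def test_self_mapping_preserves_parcellation(self, small_spec):
        scan, parc, _ = make_phantom(small_spec)
        template = ct_preprocess(scan)
        # "MNI" image == the template itself: labels must come back in place
        parc_t, fwd, inv = map_mni_to_template(template, template, parc,
                                               n_seeds=1)
        for r in parc.labels():
            a = parc.data == r
            b = parc_t.data == r
            dice = 2 * np.sum(a & b) / (np.sum(a) + np.sum(b))
            assert dice >= 0.95, f"region {r} dice {dice:.3f}"

    def test_no_label_invented(self, mapped):
        _, _, _, mni_parc, parc_t, _, _ = mapped
        assert set(np.unique(parc_t.data)) <= set(np.unique(mni_parc.data))
        assert len(parc_t.labels()) <= len(mni_parc.labels())

    def test_known_warp_centroid_recovery(self, mapped):
        scan, parc_true, _, _, parc_t, _, _ = mapped
        spacing = float(np.min(np.asarray(scan.spacing)))
        worst = 0.0
        for r in parc_true.labels():
            if not np.any(parc_t.data == r):
                continue
            aff = parc_true.affine
            c_true = np.mean(np.argwhere(parc_true.data == r), axis=0)
            c_got = np.mean(np.argwhere(parc_t.data == r), axis=0)
            err_mm = np.linalg.norm((c_true - c_got) * np.asarray(scan.spacing))
            worst = max(worst, err_mm)
        assert worst < 2 * spacing  # centroids within 2 voxels

    def test_forward_inverse_composition_residual(self, mapped):
        scan, _, _, _, _, fwd, inv = mapped
        grid = scan.grid
        pts = grid.world_points()[::53]
        back = inv.apply(fwd.apply(pts))
        resid = np.linalg.norm(back - pts, axis=1)
        assert resid.mean() < 0.5 * float(np.min(scan.spacing))

    def test_grid_mismatch_rejected(self, small_spec):
        scan, parc, _ = make_phantom(small_spec)
        template = ct_preprocess(scan)
        wrong = _labels(np.zeros((8, 8, 8)))
        with pytest.raises(VolumeError, match="grid"):
            map_mni_to_template(template, template, wrong)

    def test_native_and_mni_route_volumes_agree(self, mapped):
        # the two routes of the pipeline's optional step: per-region volume
        # measured natively vs after mapping the segmentation to MNI space
        from lesionloc.localise import compute_region_volumes
        scan, parc_true, template, mni_parc, _, fwd, inv = mapped
        bundle = TemplateBundle(template=template, ct_to_mni_fwd=fwd,
                                ct_to_mni_inv=inv)
        region = 9
        center, depth = deepest_point(parc_true.data == region, parc_true.affine)
        _, seg, _ = inject_lesion(scan, parc_true, class_id=1, center_mm=center,
                                  radius_mm=depth - 0.5)
        native = compute_region_volumes(seg, parc_true, voxel_volume_ml(seg))
        mni_seg = map_segmentation_to_mni(seg, AffineTransform.identity(), bundle)
        via_mni = compute_region_volumes(mni_seg, mni_parc,
                                         voxel_volume_ml(mni_seg))
        v_native = float(native.row(region).iph_ml)
        v_mni = float(via_mni.row(region).iph_ml)
        # tolerance covers the known warp's volume change plus interpolation
        assert v_mni == pytest.approx(v_native, rel=0.25)
        assert v_mni / float(via_mni.row(-1).iph_ml) >= 0.8


class TestInvertDeformation:
    def test_sinusoidal_field_inverts(self, small_spec):
        _, _, field = mni_standin(small_spec, grid_shape=(40, 40, 40),
                                  grid_spacing=3.0)
        inv = invert_deformation(field)
        pts = field.grid.world_points()[::29]
        resid = np.linalg.norm(inv.apply(field.apply(pts)) - pts, axis=1)
        assert resid.mean() < 1.5  # mm, half a voxel at 3 mm


class TestMapSegmentationToMni:
    @pytest.fixture(scope="class")
    def identity_bundle(self, spec, phantom):
        """Bundle whose MNI space is the template space itself."""
        scan, parc, mask = phantom
        zero = DeformationField(np.zeros((*scan.shape, 3)), scan.affine.copy())
        return TemplateBundle(template=ct_preprocess(scan), parcellation=parc,
                              brain_mask=mask, ct_to_mni_fwd=zero,
                              ct_to_mni_inv=zero,
                              ventricle_ids=[spec.n_regions - 1, spec.n_regions])

    def test_empty_segmentation_stays_empty(self, phantom, identity_bundle):
        scan, _, _ = phantom
        seg = LabelVolume(np.zeros(scan.shape, np.int32), scan.affine,
                          {1: "iph", 2: "eah", 3: "oedema", 4: "ivh"})
        out = map_segmentation_to_mni(seg, AffineTransform.identity(),
                                      identity_bundle)
        assert out.data.sum() == 0

    def test_identity_transforms_conserve_volume(self, phantom, identity_bundle):
        scan, parc, _ = phantom
        _, seg, _ = inject_lesion(scan, parc, class_id=3,
                                  center_mm=(0.0, 0.0, 0.0), radius_mm=8.0)
        out = map_segmentation_to_mni(seg, AffineTransform.identity(),
                                      identity_bundle)
        v_in = (seg.data == 3).sum() * voxel_volume_ml(seg)
        v_out = (out.data == 3).sum() * voxel_volume_ml(out)
        assert v_out == pytest.approx(v_in, rel=0.05)

    def test_lesion_lands_in_its_mni_region(self, phantom, identity_bundle):
        scan, parc, _ = phantom
        center, depth = deepest_point(parc.data == 9, parc.affine)
        _, seg, _ = inject_lesion(scan, parc, class_id=1, center_mm=center,
                                  radius_mm=depth - 0.5)
        out = map_segmentation_to_mni(seg, AffineTransform.identity(),
                                      identity_bundle)
        lesion = out.data == 1
        in_region = lesion & (parc.data == 9)
        assert in_region.sum() / lesion.sum() >= 0.8

    def test_missing_transform_rejected(self, phantom, ideal_bundle):
        scan, parc, _ = phantom
        seg = LabelVolume(np.zeros(scan.shape, np.int32), scan.affine,
                          {1: "iph", 2: "eah", 3: "oedema", 4: "ivh"})
        with pytest.raises(VolumeError, match="ct_to_mni"):
            map_segmentation_to_mni(seg, AffineTransform.identity(), ideal_bundle)


class TestAttachAtlas:
    def test_bundle_populated_and_ventricles_found(self, small_spec):
        scan, parc, _ = make_phantom(small_spec)
        mni_img, mni_parc, _ = mni_standin(small_spec, grid_shape=(56, 56, 56),
                                           grid_spacing=2.2)
        bundle = TemplateBundle(template=ct_preprocess(scan))
        attach_atlas(bundle, mni_img, mni_parc, n_seeds=1, dilation_mm=8.0)
        assert bundle.parcellation is not None
        assert bundle.brain_mask is not None
        assert bundle.ct_to_mni_fwd is not None and bundle.ct_to_mni_inv is not None
        assert bundle.ventricle_ids == [small_spec.n_regions - 1,
                                        small_spec.n_regions]
        # dilation: labelled region strictly contains the brain mask
        assert np.all((bundle.brain_mask.data > 0) <= (bundle.parcellation.data > 0))
        assert (bundle.parcellation.data > 0).sum() > (bundle.brain_mask.data > 0).sum()
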