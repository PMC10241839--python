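"""Iterative construction of a population CT template.

The template is built from non-lesioned scans by alternating registration to
the current target and voxelwise averaging: in each iteration every scan is
registered (affinely in early iterations, deformably in late ones) to the
target produced by the previous iteration, and the mean of the registered
scans becomes the next target.  The default schedule is four affine followed
by three deformable iterations; the very first target is a cross-modality
MR template (or any supplied reference), which the first affine iteration
replaces with a CT average.

Scans are intensity-preprocessed before registration and averaging so that
the first, cross-modality iteration optimises a meaningful correlation; the
template is therefore stored on the normalised [0, 1] intensity scale (it is
only ever used as a registration target and label carrier).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Sequence

import numpy as np

from .imaging import (
    AffineTransform,
    DeformationField,
    LabelVolume,
    ScalarVolume,
    VolumeError,
    load_deformation,
    load_volume,
    resample,
    save_deformation,
    save_volume,
)
from .registration import register_affine_multiseed, register_deformable

logger = logging.getLogger(__name__)

DEFAULT_SCHEDULE: tuple[str, ...] = ("affine",) * 4 + ("deformable",) * 3


@dataclass
class TemplateBundle:
    """The CT template with its parcellation, mask and MNI mapping.

    ``ct_to_mni_fwd`` maps template-world points to MNI-world points as a
    dense displacement field on the template grid; ``ct_to_mni_inv`` is its
    numerical inverse on the MNI grid.  ``provenance`` records the build
    schedule and the per-iteration mean similarity.
    """

    template: ScalarVolume
    parcellation: LabelVolume | None = None
    brain_mask: LabelVolume | None = None
    ct_to_mni_fwd: DeformationField | None = None
    ct_to_mni_inv: DeformationField | None = None
    ventricle_ids: list[int] = dataclass_field(default_factory=list)
    provenance: dict = dataclass_field(default_factory=dict)

    def __post_init__(self) -> None:
        for vol in (self.parcellation, self.brain_mask):
            if vol is not None and (
                tuple(vol.shape) != tuple(self.template.shape)
                or not np.allclose(vol.affine, self.template.affine, atol=1e-4)
            ):
                raise VolumeError("parcellation/brain_mask must share the template grid")

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_volume(self.template, directory / "template.nii.gz")
        if self.parcellation is not None:
            save_volume(self.parcellation, directory / "parcellation.nii.gz")
            (directory / "labels.json").write_text(json.dumps({
                "labels": {str(k): v for k, v in self.parcellation.label_table.items()},
                "ventricle_ids": self.ventricle_ids,
            }, indent=2))
        if self.brain_mask is not None:
            save_volume(self.brain_mask, directory / "brain_mask.nii.gz")
        if self.ct_to_mni_fwd is not None:
            save_deformation(self.ct_to_mni_fwd, directory / "ct_to_mni_fwd.nii.gz")
        if self.ct_to_mni_inv is not None:
            save_deformation(self.ct_to_mni_inv, directory / "ct_to_mni_inv.nii.gz")
        (directory / "provenance.json").write_text(json.dumps(self.provenance, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "TemplateBundle":
        directory = Path(directory)
        template = load_volume(directory / "template.nii.gz")
        parcellation = brain_mask = fwd = inv = None
        ventricle_ids: list[int] = []
        if (directory / "parcellation.nii.gz").exists():
            table = {}
            if (directory / "labels.json").exists():
                meta = json.loads((directory / "labels.json").read_text())
                table = {int(k): v for k, v in meta.get("labels", {}).items()}
                ventricle_ids = [int(v) for v in meta.get("ventricle_ids", [])]
            parcellation = load_volume(directory / "parcellation.nii.gz",
                                       as_labels=True, label_table=table)
        if (directory / "brain_mask.nii.gz").exists():
            brain_mask = load_volume(directory / "brain_mask.nii.gz", as_labels=True)
        if (directory / "ct_to_mni_fwd.nii.gz").exists():
            fwd = load_deformation(directory / "ct_to_mni_fwd.nii.gz")
        if (directory / "ct_to_mni_inv.nii.gz").exists():
            inv = load_deformation(directory / "ct_to_mni_inv.nii.gz")
        provenance = {}
        if (directory / "provenance.json").exists():
            provenance = json.loads((directory / "provenance.json").read_text())
        return cls(template, parcellation, brain_mask, fwd, inv,
                   ventricle_ids, provenance)


def average_images(vols: Sequence[ScalarVolume]) -> ScalarVolume:
    """Voxelwise arithmetic mean of images sharing one grid."""
    if not vols:
        raise VolumeError("cannot average an empty list of images")
    ref = vols[0]
    for v in vols[1:]:
        if tuple(v.shape) != tuple(ref.shape) or not np.allclose(
                v.affine, ref.affine, atol=1e-4):
            raise VolumeError("average_images requires a common grid")
    stack = np.stack([v.data.astype(np.float64) for v in vols])
    return ScalarVolume(stack.mean(axis=0).astype(np.float32), ref.affine.copy())


def template_sharpness(template: ScalarVolume,
                       mask: np.ndarray | None = None) -> float:
    """Mean gradient magnitude (per mm) within a mask — a sharpness index."""
    spacing = template.spacing
    grads = np.gradient(template.data.astype(np.float64), *spacing)
    mag = np.sqrt(sum(g**2 for g in grads))
    if mask is None:
        mask = template.data > 0.01
    return float(mag[mask].mean())


def build_template(scans: Sequence[ScalarVolume],
                   initial_target: ScalarVolume,
                   schedule: Sequence[str] = DEFAULT_SCHEDULE,
                   n_seeds: int = 1,
                   preprocessed: bool = True) -> TemplateBundle:
    """Iterative template construction from a cohort of scans.

    In each iteration every scan is registered to the current target (per
    the stage kind in ``schedule``), resampled onto the target grid, and the
    voxelwise mean of the registered scans becomes the next target.  Affine
    stages re-register from scratch with ``n_seeds`` initialisation seeds;
    deformable stages compose a deformable refinement with the scan's last
    affine.  Scans whose registration fails in an iteration are excluded
    from that iteration's average and logged.

    ``scans`` and ``initial_target`` must already be on the normalised
    intensity scale (``ct_preprocess`` / ``minmax_preprocess``) unless
    ``preprocessed`` is False, in which case a CT soft-tissue window is
    applied here.

    Returns a :class:`TemplateBundle` holding the final template and a
    provenance dict with per-iteration mean similarity.
    """
    from .imaging import ct_preprocess

    if len(scans) < 2:
        raise VolumeError("template construction needs at least 2 scans")
    if not schedule:
        raise VolumeError("schedule must be nonempty")
    for kind in schedule:
        if kind not in ("affine", "deformable"):
            raise VolumeError(f"unknown stage kind {kind!r}")

    if not preprocessed:
        scans = [ct_preprocess(s) for s in scans]
        initial_target = ct_preprocess(initial_target)

    target = initial_target
    grid = initial_target.grid
    affines: list[AffineTransform] = [AffineTransform.identity() for _ in scans]
    mean_similarity: list[float] = []
    sharpness: list[float] = []

    for it, kind in enumerate(schedule):
        warped_all: list[ScalarVolume] = []
        sims: list[float] = []
        # the very first target is typically a cross-modality (MR) template,
        # where intensities are not linearly related to CT: optimise mutual
        # information there; all CT-to-CT iterations use correlation
        metric = "mattes" if it == 0 else "correlation"
        for i, scan in enumerate(scans):
            if kind == "affine":
                res = register_affine_multiseed(scan, target, n_seeds=n_seeds,
                                                metric=metric)
                if not res.success:
                    logger.warning("iteration %d: scan %d failed affine "
                                   "registration; excluded from average", it, i)
                    continue
                affines[i] = res.transform
                warped = resample(scan, res.transform, grid, mode="linear")
            else:
                pre = resample(scan, affines[i], grid, mode="linear")
                res = register_deformable(pre, target)
                if not res.success:
                    logger.warning("iteration %d: scan %d failed deformable "
                                   "registration; excluded from average", it, i)
                    continue
                # one interpolation: target point -> +d -> affine -> scan world
                warped = resample(scan, [res.transform, affines[i]], grid,
                                  mode="linear")
            warped_all.append(warped)
            sims.append(res.similarity)
        if not warped_all:
            raise VolumeError(f"iteration {it}: every scan failed registration")
        target = average_images(warped_all)
        mean_similarity.append(float(np.mean(sims)))
        sharpness.append(template_sharpness(target))
        logger.info("iteration %d (%s): mean similarity %.4f over %d scans",
                    it, kind, mean_similarity[-1], len(warped_all))

    provenance = {
        "schedule": list(schedule),
        "n_iterations": len(schedule),
        "n_scans": len(scans),
        "n_seeds": n_seeds,
        "mean_similarity": mean_similarity,
        "sharpness": sharpness,
    }
    return TemplateBundle(template=target, provenance=provenance)
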