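"""Per-patient lesion localisation: register, invert, project, quantify.

The three-step pipeline for one scan: (1) the preprocessed native CT is
affinely registered to the CT template with multi-seed initialisation; (2)
the inverse of the winning transform projects the (dilated) template
parcellation into native patient space with nearest-neighbour
interpolation; (3) the overlap between the projected regions and the lesion
segmentation map yields per-region lesion volumes in mL, together with
region volumes and whole-brain totals.

Lesion voxels that fall on atlas background even after dilation are
reported under an explicit ``unassigned`` row, never dropped, so that for
every lesion class the region rows plus ``unassigned`` sum exactly to the
whole-brain total (the table's conservation law).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import (
    LabelVolume,
    ScalarVolume,
    VolumeError,
    ct_preprocess,
    resample,
    same_grid,
    voxel_volume_ml,
)
from .registration import RegistrationResult, invert_affine, register_affine_multiseed
from .template import TemplateBundle

logger = logging.getLogger(__name__)

#: Lesion class encoding of the segmentation maps (configurable via
#: ``class_map``): intraparenchymal haemorrhage, extra-axial haemorrhage,
#: perilesional oedema, intraventricular haemorrhage.
LESION_CLASSES: dict[int, str] = {1: "iph", 2: "eah", 3: "oedema", 4: "ivh"}

UNASSIGNED_ID = 0
WHOLE_BRAIN_ID = -1

TABLE_COLUMNS = ["scan_id", "region_id", "region_name", "region_volume_ml",
                 "iph_ml", "eah_ml", "oedema_ml", "ivh_ml"]


def check_segmentation(seg: LabelVolume,
                       class_map: dict[int, str] | None = None) -> dict[int, str]:
    """Validate that a segmentation uses only the known class labels."""
    class_map = dict(class_map or LESION_CLASSES)
    extra = set(seg.labels()) - set(class_map)
    if extra:
        raise VolumeError(f"segmentation contains unknown class labels {sorted(extra)}")
    return class_map


@dataclass
class RegionVolumeTable:
    """Per-region x per-class lesion volumes (mL) for one scan.

    ``df`` has one row per atlas region plus an ``unassigned`` row
    (region_id 0: lesion voxels outside every region) and a ``whole_brain``
    row (region_id -1) carrying the totals.
    """

    scan_id: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(TABLE_COLUMNS) - set(self.df.columns)
        if missing:
            raise VolumeError(f"RegionVolumeTable missing columns {sorted(missing)}")

    @property
    def class_columns(self) -> list[int]:
        return [c for c in self.df.columns if c.endswith("_ml")
                and c != "region_volume_ml"]

    def region_rows(self) -> pd.DataFrame:
        """Rows for actual atlas regions (no unassigned / whole-brain)."""
        return self.df[self.df.region_id > 0]

    def row(self, region_id: int) -> pd.Series:
        sel = self.df[self.df.region_id == region_id]
        if sel.empty:
            raise KeyError(f"region {region_id} not in table")
        return sel.iloc[0]

    def total(self, class_name: str) -> float:
        return float(self.row(WHOLE_BRAIN_ID)[f"{class_name}_ml"])

    def conservation_residual(self) -> float:
        """Max abs difference between region+unassigned sums and totals."""
        parts = self.df[self.df.region_id >= 0]
        worst = 0.0
        for col in self.class_columns:
            worst = max(worst, abs(float(parts[col].sum()) - float(
                self.row(WHOLE_BRAIN_ID)[col])))
        return worst

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RegionVolumeTable":
        df = pd.read_csv(path)
        scan_id = str(df["scan_id"].iloc[0]) if len(df) else ""
        return cls(scan_id, df)


def compute_region_volumes(seg: LabelVolume, parc_native: LabelVolume,
                           vox_ml: float, scan_id: str = "scan",
                           brain_mask: LabelVolume | None = None,
                           class_map: dict[int, str] | None = None,
                           ) -> RegionVolumeTable:
    """Overlap bookkeeping between a segmentation and a projected parcellation.

    Cell (region r, class c) is ``vox_ml`` times the count of voxels with
    parcellation label r and segmentation label c.  Lesion voxels on
    parcellation background go to the ``unassigned`` row; the
    ``whole_brain`` row holds per-class totals and the brain volume
    (non-background parcellation voxels, restricted to ``brain_mask`` when
    given so that dilated atlas labels outside the head do not inflate it).
    """
    if not same_grid(seg, parc_native):
        raise VolumeError("segmentation and parcellation must share one grid")
    if brain_mask is not None and not same_grid(brain_mask, parc_native):
        raise VolumeError("brain mask must share the parcellation grid")
    class_map = check_segmentation(seg, class_map)
    class_ids = sorted(class_map)
    n_classes = len(class_ids)
    remap = np.zeros(max(class_ids) + 1, dtype=np.int64)
    for slot, cid in enumerate(class_ids, start=1):
        remap[cid] = slot

    parc = parc_native.data.astype(np.int64).ravel()
    segr = remap[seg.data.astype(np.int64).ravel()]
    joint = np.bincount(parc * (n_classes + 1) + segr,
                        minlength=(parc.max() + 1) * (n_classes + 1))
    joint = joint.reshape(-1, n_classes + 1)  # rows: parc label, cols: 0 + classes

    rows = []
    region_ids = sorted(parc_native.label_table)
    for r in region_ids:
        counts = joint[r] if r < joint.shape[0] else np.zeros(n_classes + 1, int)
        row = {"scan_id": scan_id, "region_id": int(r),
               "region_name": parc_native.label_table[r],
               "region_volume_ml": float(counts.sum()) * vox_ml}
        for slot, cid in enumerate(class_ids, start=1):
            row[f"{class_map[cid]}_ml"] = float(counts[slot]) * vox_ml
        rows.append(row)

    bg = joint[0]
    row = {"scan_id": scan_id, "region_id": UNASSIGNED_ID,
           "region_name": "unassigned", "region_volume_ml": 0.0}
    for slot, cid in enumerate(class_ids, start=1):
        row[f"{class_map[cid]}_ml"] = float(bg[slot]) * vox_ml
    rows.append(row)

    brain_ml = brain_volume(parc_native, vox_ml, brain_mask=brain_mask)
    total = {"scan_id": scan_id, "region_id": WHOLE_BRAIN_ID,
             "region_name": "whole_brain", "region_volume_ml": brain_ml}
    # totals as the float sum of the cells above: conservation is bit-exact
    for cid in class_ids:
        col = f"{class_map[cid]}_ml"
        total[col] = float(np.sum(np.array([r[col] for r in rows])))
    rows.append(total)

    return RegionVolumeTable(scan_id, pd.DataFrame(rows, columns=TABLE_COLUMNS))


def brain_volume(parc_native: LabelVolume, vox_ml: float,
                 brain_mask: LabelVolume | None = None) -> float:
    """Whole-brain volume in mL from the projected parcellation.

    Counts non-background parcellation voxels; when a projected brain mask
    is given, dilated labels outside the mask are excluded so the figure
    stays anatomically meaningful.
    """
    nz = parc_native.data > 0
    if brain_mask is not None:
        nz = nz & (brain_mask.data > 0)
    return float(nz.sum()) * vox_ml


def localise(scan: ScalarVolume, seg: LabelVolume, bundle: TemplateBundle,
             n_seeds: int = 4, scan_id: str = "scan",
             class_map: dict[int, str] | None = None,
             ) -> tuple[RegionVolumeTable, RegistrationResult]:
    """Full per-scan pipeline: register, invert, project, quantify.

    Returns the per-region volume table and the winning registration result
    (whose similarity is the scan's SM for quality control).  A failed
    registration still produces a table — computed through the identity
    mapping — with the failure flagged on the result, so QC can catch it.
    """
    if not same_grid(scan, seg):
        raise VolumeError("scan and segmentation must be on the same native grid")
    if bundle.parcellation is None:
        raise VolumeError("bundle has no parcellation; run attach_atlas first")
    check_segmentation(seg, class_map)

    pre = ct_preprocess(scan)
    res = register_affine_multiseed(pre, bundle.template, n_seeds=n_seeds)
    if not res.success:
        logger.warning("%s: registration failed (%s); table computed through "
                       "identity transform", scan_id, res.message)

    # res.transform maps template world -> native world; its inverse maps the
    # native grid into template space, pulling the parcellation to the patient
    to_template = invert_affine(res.transform)
    parc_native = resample(bundle.parcellation, to_template, scan.grid)
    mask_native = None
    if bundle.brain_mask is not None:
        mask_native = resample(bundle.brain_mask, to_template, scan.grid)

    table = compute_region_volumes(seg, parc_native, voxel_volume_ml(scan),
                                   scan_id=scan_id, brain_mask=mask_native,
                                   class_map=class_map)
    return table, res
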