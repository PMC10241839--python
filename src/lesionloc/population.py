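"""Cohort-level lesion prevalence maps and outcome-stratified distributions.

Two prevalence views: per-region subject counts above a lesion-volume
threshold (minimum 0.1 mL, to exclude counts produced by minor
misalignments), and voxelwise per-class count maps over segmentations
mapped to a common atlas space.  Volume distributions can additionally be
stratified by functional outcome on the Extended Glasgow Outcome Scale
(GOSE, 1-8), with QC-flagged scans excluded.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import LabelVolume, VolumeError, same_grid
from .localise import RegionVolumeTable
from .qc import QCRecord

#: Minimum defensible prevalence threshold (mL); affine-only mapping does not
#: support voxel-level localisation, so smaller volumes are likely noise.
MIN_PREVALENCE_THRESHOLD_ML = 0.1


def region_prevalence(tables: Sequence[RegionVolumeTable],
                      threshold_ml: float = MIN_PREVALENCE_THRESHOLD_ML,
                      allow_below_minimum: bool = False) -> pd.DataFrame:
    """Subjects per region and class with lesion volume above threshold.

    Returns a DataFrame indexed by (region_id, region_name) with one count
    column per lesion class: the number of subjects whose volume of that
    class in that region strictly exceeds ``threshold_ml``.
    """
    if threshold_ml < MIN_PREVALENCE_THRESHOLD_ML and not allow_below_minimum:
        raise VolumeError(
            f"threshold below the {MIN_PREVALENCE_THRESHOLD_ML} mL minimum; "
            "pass allow_below_minimum=True to override")
    if not tables:
        return pd.DataFrame(columns=["region_id", "region_name"])
    class_cols = tables[0].class_columns
    long = pd.concat([t.region_rows() for t in tables], ignore_index=True)
    counts = (long[class_cols].gt(threshold_ml)
              .groupby([long.region_id, long.region_name]).sum().astype(int))
    counts.columns = [c.replace("_ml", "_n") for c in class_cols]
    return counts.reset_index()


def voxelwise_prevalence(mni_segs: Sequence[LabelVolume],
                         class_ids: Sequence[int] | None = None,
                         ) -> dict[int, np.ndarray]:
    """Per-class voxelwise subject counts over atlas-space segmentations.

    All segmentations must share the (MNI) grid; the value of the count map
    at a voxel is the number of subjects with that class at that voxel.
    """
    if not mni_segs:
        return {}
    ref = mni_segs[0]
    for s in mni_segs[1:]:
        if not same_grid(s, ref):
            raise VolumeError("all segmentations must share the MNI grid")
    if class_ids is None:
        class_ids = sorted({lab for s in mni_segs for lab in s.labels()})
    return {int(c): np.sum([s.data == c for s in mni_segs], axis=0).astype(np.int32)
            for c in class_ids}


def stratified_distributions(tables: Sequence[RegionVolumeTable],
                             outcomes: Mapping[str, int],
                             qc: Sequence[QCRecord] | None = None,
                             good_threshold: int = 7,
                             strict: bool = True,
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-region, per-class volume samples grouped by functional outcome.

    Subjects with GOSE > ``good_threshold`` form the "good" group and GOSE
    < ``good_threshold`` the "poor" group; under the default strict reading
    subjects exactly at the threshold are excluded (set ``strict=False``
    for the conventional >= / < dichotomy).  Scans flagged by QC are
    excluded, as are subjects without an outcome (with a warning).

    Returns ``(samples, summary)``: a long DataFrame of per-scan volumes
    with their group, and five-number summaries per (region, class, group).
    """
    flagged = {r.scan_id for r in qc or [] if r.overall == "flagged"}
    frames = []
    for t in tables:
        if t.scan_id in flagged:
            continue
        if t.scan_id not in outcomes:
            warnings.warn(f"no outcome for subject {t.scan_id}; excluded")
            continue
        gose = int(outcomes[t.scan_id])
        if not 1 <= gose <= 8:
            raise VolumeError(f"GOSE must be in 1..8, got {gose}")
        if gose > good_threshold or (not strict and gose == good_threshold):
            group = "good"
        elif gose < good_threshold:
            group = "poor"
        else:
            continue  # strict reading: GOSE == threshold excluded
        sub = t.df[t.df.region_id != 0].copy()  # regions + whole_brain row
        sub["group"] = group
        frames.append(sub)
    if not frames:
        return (pd.DataFrame(columns=["scan_id", "region_id", "group"]),
                pd.DataFrame())
    samples = pd.concat(frames, ignore_index=True)
    class_cols = [c for c in samples.columns
                  if c.endswith("_ml") and c != "region_volume_ml"]
    melted = samples.melt(
        id_vars=["scan_id", "region_id", "region_name", "group"],
        value_vars=class_cols, var_name="lesion_class", value_name="volume_ml")
    melted["lesion_class"] = melted["lesion_class"].str.replace("_ml", "")
    summary = (melted.groupby(["region_id", "region_name", "lesion_class", "group"])
               ["volume_ml"]
               .describe(percentiles=[0.25, 0.5, 0.75])
               [["count", "min", "25%", "50%", "75%", "max"]]
               .reset_index())
    return melted, summary
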