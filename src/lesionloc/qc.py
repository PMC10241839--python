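"""Automatic quality control of atlas mappings.

Three per-scan flags are derived: (1) a similarity-metric flag, raised when
the registration SM (Pearson correlation) falls below a threshold (default
0.65); (2) a region-outlier flag, raised when more than five of a scan's
projected region volumes are outliers of the cohort distribution for that
region (Tukey fences at 1.5 x IQR); and (3) an IVH flag, raised when more
than 1 mL of intraventricular haemorrhage is localised outside the
ventricle labels — an anatomically implausible result.  A scan is flagged
overall iff any individual flag is raised.

The SM's ability to discriminate acceptable from unacceptable mappings can
be evaluated against expert visual scores (1-5 scale) as the area under the
ROC curve, i.e. the Mann-Whitney probability that an acceptable scan's SM
exceeds an unacceptable one's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .imaging import VolumeError
from .localise import RegionVolumeTable

#: Default SM threshold below which a mapping is considered sub-optimal.
SM_THRESHOLD = 0.65

#: A scan is flagged when it has strictly more than this many outlier regions.
MAX_OUTLIER_REGIONS = 5

#: IVH volume outside the ventricles (mL) above which a scan is flagged.
IVH_OUTSIDE_THRESHOLD_ML = 1.0

#: Visual scores >= this value count as acceptable when binarising (the
#: stricter alternative for ventricle-sensitive studies is 4).
ACCEPTABLE_SCORE_CUTOFF = 3


@dataclass
class QCRecord:
    """Per-scan QC summary; ``overall`` is 'flagged' iff any flag is set."""

    scan_id: str
    sm: float
    sm_flag: bool
    n_outlier_regions: int
    outlier_flag: bool
    ivh_outside_ml: float
    ivh_flag: bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.sm):
            raise VolumeError("SM must be finite")
        if self.ivh_outside_ml < 0:
            raise VolumeError("extraventricular IVH volume must be >= 0")

    @property
    def overall(self) -> str:
        return "flagged" if (self.sm_flag or self.outlier_flag
                             or self.ivh_flag) else "pass"

    def to_dict(self) -> dict:
        return {"scan_id": self.scan_id, "sm": self.sm,
                "sm_flag": self.sm_flag,
                "n_outlier_regions": self.n_outlier_regions,
                "outlier_flag": self.outlier_flag,
                "ivh_outside_ml": self.ivh_outside_ml,
                "ivh_flag": self.ivh_flag, "overall": self.overall}


def sm_flag(sm: float, threshold: float = SM_THRESHOLD) -> bool:
    """True iff the similarity metric is strictly below the threshold."""
    if not np.isfinite(sm):
        raise VolumeError("SM must be finite")
    return bool(sm < threshold)


def region_outlier_flags(cohort_tables: Sequence[RegionVolumeTable],
                         max_outliers: int = MAX_OUTLIER_REGIONS,
                         iqr_factor: float = 1.5) -> pd.DataFrame:
    """Count per-scan outlier regions against the cohort distribution.

    For each region, the cohort distribution of projected region volume is
    summarised by Tukey fences (quartiles +/- ``iqr_factor`` x IQR); values
    strictly outside the fences are outliers.  A scan is flagged iff its
    outlier-region count exceeds ``max_outliers``.  Returns a DataFrame with
    columns scan_id, n_outlier_regions, outlier_flag.
    """
    if len(cohort_tables) < 5:
        warnings.warn("cohort too small to estimate region-volume "
                      "distributions; outlier flags set to False")
        return pd.DataFrame({
            "scan_id": [t.scan_id for t in cohort_tables],
            "n_outlier_regions": 0,
            "outlier_flag": False,
        })
    long = pd.concat([t.region_rows().assign(scan_id=t.scan_id)
                      for t in cohort_tables], ignore_index=True)
    q1 = long.groupby("region_id")["region_volume_ml"].quantile(0.25)
    q3 = long.groupby("region_id")["region_volume_ml"].quantile(0.75)
    iqr = q3 - q1
    lo = long.region_id.map(q1 - iqr_factor * iqr)
    hi = long.region_id.map(q3 + iqr_factor * iqr)
    long["is_outlier"] = (long.region_volume_ml < lo) | (long.region_volume_ml > hi)
    counts = long.groupby("scan_id", sort=False)["is_outlier"].sum().astype(int)
    out = counts.reindex([t.scan_id for t in cohort_tables], fill_value=0)
    return pd.DataFrame({
        "scan_id": out.index,
        "n_outlier_regions": out.to_numpy(),
        "outlier_flag": out.to_numpy() > max_outliers,
    }).reset_index(drop=True)


def ivh_outside_ventricles(table: RegionVolumeTable,
                           ventricle_ids: Iterable[int],
                           threshold_ml: float = IVH_OUTSIDE_THRESHOLD_ML,
                           ) -> tuple[float, bool]:
    """IVH volume localised outside the ventricle labels, and its flag.

    Sums the IVH column over all region rows not in ``ventricle_ids`` plus
    the unassigned row; the flag is raised iff the volume strictly exceeds
    ``threshold_ml``.
    """
    ventricle_ids = set(int(v) for v in ventricle_ids)
    if not ventricle_ids:
        raise VolumeError("ventricle_ids must be nonempty")
    known = set(table.df.region_id[table.df.region_id > 0].astype(int))
    unknown = ventricle_ids - known
    if unknown:
        raise VolumeError(f"ventricle ids {sorted(unknown)} not in parcellation")
    rows = table.df[(table.df.region_id >= 0)
                    & ~table.df.region_id.isin(ventricle_ids)]
    volume = float(rows["ivh_ml"].sum())
    return volume, bool(volume > threshold_ml)


def make_qc_record(table: RegionVolumeTable, sm: float,
                   ventricle_ids: Iterable[int],
                   n_outlier_regions: int = 0,
                   sm_threshold: float = SM_THRESHOLD,
                   max_outliers: int = MAX_OUTLIER_REGIONS,
                   ivh_threshold_ml: float = IVH_OUTSIDE_THRESHOLD_ML,
                   ) -> QCRecord:
    """Assemble the per-scan QC record from its components."""
    ivh_ml, ivh_fl = ivh_outside_ventricles(table, ventricle_ids,
                                            threshold_ml=ivh_threshold_ml)
    return QCRecord(
        scan_id=table.scan_id,
        sm=float(sm),
        sm_flag=sm_flag(sm, threshold=sm_threshold),
        n_outlier_regions=int(n_outlier_regions),
        outlier_flag=bool(n_outlier_regions > max_outliers),
        ivh_outside_ml=ivh_ml,
        ivh_flag=ivh_fl,
    )


def qc_records_for_cohort(tables: Sequence[RegionVolumeTable],
                          sms: Sequence[float],
                          ventricle_ids: Iterable[int],
                          **kwargs) -> list[QCRecord]:
    """QC records for a cohort, with outlier counts from the cohort itself."""
    if len(tables) != len(sms):
        raise VolumeError("tables and sms must have equal length")
    outliers = region_outlier_flags(tables)
    counts = dict(zip(outliers.scan_id, outliers.n_outlier_regions))
    return [make_qc_record(t, sm, ventricle_ids,
                           n_outlier_regions=counts.get(t.scan_id, 0), **kwargs)
            for t, sm in zip(tables, sms)]


def qc_auc(sm_values: Sequence[float], visual_scores: Sequence[int],
           acceptable_cutoff: int = ACCEPTABLE_SCORE_CUTOFF) -> float | None:
    """AUC of the SM against binarised visual quality scores.

    Scores >= ``acceptable_cutoff`` are the positive (acceptable) class.
    The AUC is the Mann-Whitney probability that a positive's SM exceeds a
    negative's, ties counting one half.  Returns None when only one class is
    present (the AUC is undefined).
    """
    sm_values = np.asarray(sm_values, dtype=float)
    scores = np.asarray(visual_scores)
    if sm_values.shape != scores.shape:
        raise VolumeError("sm_values and visual_scores must have equal length")
    if scores.size == 0 or scores.min() < 1 or scores.max() > 5:
        raise VolumeError("visual scores must be in 1..5")
    pos = sm_values[scores >= acceptable_cutoff]
    neg = sm_values[scores < acceptable_cutoff]
    if len(pos) == 0 or len(neg) == 0:
        warnings.warn("qc_auc undefined: only one class present")
        return None
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (len(pos) * len(neg)))
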