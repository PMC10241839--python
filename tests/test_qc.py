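"""Quality-control flags and the SM-versus-visual-score AUC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lesionloc.imaging import VolumeError
from lesionloc.localise import LESION_CLASSES, RegionVolumeTable, TABLE_COLUMNS
from lesionloc.qc import (
    QCRecord,
    ivh_outside_ventricles,
    make_qc_record,
    qc_auc,
    region_outlier_flags,
    sm_flag,
)


def make_table(scan_id, region_volumes, ivh=None, n_regions=31):
    """Synthetic RegionVolumeTable from a dict of region volumes."""
    ivh = ivh or {}
    rows = []
    for r in range(1, n_regions + 1):
        rows.append({"scan_id": scan_id, "region_id": r,
                     "region_name": f"region_{r:02d}",
                     "region_volume_ml": region_volumes.get(r, 10.0),
                     "iph_ml": 0.0, "eah_ml": 0.0, "oedema_ml": 0.0,
                     "ivh_ml": ivh.get(r, 0.0)})
    rows.append({"scan_id": scan_id, "region_id": 0,
                 "region_name": "unassigned", "region_volume_ml": 0.0,
                 "iph_ml": 0.0, "eah_ml": 0.0, "oedema_ml": 0.0,
                 "ivh_ml": ivh.get(0, 0.0)})
    total_ivh = sum(ivh.values())
    rows.append({"scan_id": scan_id, "region_id": -1,
                 "region_name": "whole_brain",
                 "region_volume_ml": sum(region_volumes.values()) or 300.0,
                 "iph_ml": 0.0, "eah_ml": 0.0, "oedema_ml": 0.0,
                 "ivh_ml": total_ivh})
    return RegionVolumeTable(scan_id, pd.DataFrame(rows, columns=TABLE_COLUMNS))


class TestSmFlag:
    @pytest.mark.parametrize("sm,expected", [
        (0.64, True),    # just below the default threshold
        (0.65, False),   # boundary: strict inequality
        (1.0, False),
        (-0.2, True),
    ])
    def test_default_threshold_boundary(self, sm, expected):
        assert sm_flag(sm) is expected

    def test_custom_threshold(self):
        assert sm_flag(0.7, threshold=0.75)
        assert not sm_flag(0.75, threshold=0.75)


class TestRegionOutliers:
    def test_identical_scans_have_no_outliers(self):
        tables = [make_table(f"s{i}", {}) for i in range(10)]
        out = region_outlier_flags(tables)
        assert (out.n_outlier_regions == 0).all()
        assert not out.outlier_flag.any()

    def test_scaled_scan_flagged(self, rng):
        tables = [make_table(f"s{i}", {r: 10.0 + rng.normal(0, 0.5)
                                       for r in range(1, 32)})
                  for i in range(20)]
        scaled = make_table("bad", {r: 30.0 + rng.normal(0, 0.5)
                                    for r in range(1, 32)})
        out = region_outlier_flags(tables + [scaled])
        bad = out[out.scan_id == "bad"].iloc[0]
        assert bad.n_outlier_regions > 5
        assert bad.outlier_flag
        assert not out[out.scan_id != "bad"].outlier_flag.any()

    def test_exactly_five_outlier_regions_not_flagged(self, rng):
        # "more than five": a scan with exactly 5 outlier regions passes
        tables = [make_table(f"s{i}", {r: 10.0 + rng.normal(0, 0.5)
                                       for r in range(1, 32)})
                  for i in range(20)]
        edge_vols = {r: 10.0 for r in range(1, 32)}
        for r in range(1, 6):
            edge_vols[r] = 40.0  # 5 extreme regions only
        edge = make_table("edge", edge_vols)
        out = region_outlier_flags(tables + [edge])
        row = out[out.scan_id == "edge"].iloc[0]
        assert row.n_outlier_regions == 5
        assert not row.outlier_flag

    def test_matches_direct_quantile_computation(self, rng):
        tables = [make_table(f"s{i}", {r: float(rng.gamma(2, 5))
                                       for r in range(1, 32)})
                  for i in range(12)]
        out = region_outlier_flags(tables)
        # oracle: direct per-region quantiles
        vols = np.array([[t.row(r).region_volume_ml for r in range(1, 32)]
                         for t in tables])
        q1, q3 = np.quantile(vols, [0.25, 0.75], axis=0)
        iqr = q3 - q1
        is_out = (vols < q1 - 1.5 * iqr) | (vols > q3 + 1.5 * iqr)
        np.testing.assert_array_equal(out.n_outlier_regions.to_numpy(),
                                      is_out.sum(axis=1))

    def test_small_cohort_warns_and_passes_all(self):
        tables = [make_table(f"s{i}", {}) for i in range(3)]
        with pytest.warns(UserWarning, match="cohort"):
            out = region_outlier_flags(tables)
        assert not out.outlier_flag.any()

    def test_permutation_invariant(self, rng):
        tables = [make_table(f"s{i}", {r: float(rng.gamma(2, 5))
                                       for r in range(1, 32)})
                  for i in range(8)]
        a = region_outlier_flags(tables).sort_values("scan_id").reset_index(drop=True)
        b = region_outlier_flags(tables[::-1]).sort_values("scan_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestIvhOutside:
    def test_all_ivh_inside_ventricles(self):
        t = make_table("s", {}, ivh={30: 3.0, 31: 2.0})
        vol, flag = ivh_outside_ventricles(t, [30, 31])
        assert vol == 0.0 and not flag

    @pytest.mark.parametrize("outside,expected_flag", [(0.5, False), (1.5, True),
                                                       (1.0, False)])
    def test_threshold_boundary(self, outside, expected_flag):
        t = make_table("s", {}, ivh={5: outside})
        vol, flag = ivh_outside_ventricles(t, [30, 31])
        assert vol == pytest.approx(outside)
        assert flag is expected_flag

    def test_unassigned_ivh_counts_as_outside(self):
        t = make_table("s", {}, ivh={0: 2.0})
        vol, flag = ivh_outside_ventricles(t, [30, 31])
        assert vol == pytest.approx(2.0) and flag

    def test_unknown_ventricle_ids_rejected(self):
        t = make_table("s", {})
        with pytest.raises(VolumeError, match="not in parcellation"):
            ivh_outside_ventricles(t, [99])

    def test_empty_ventricle_ids_rejected(self):
        t = make_table("s", {})
        with pytest.raises(VolumeError, match="nonempty"):
            ivh_outside_ventricles(t, [])

    def test_straddling_sphere_matches_voxel_count(self, spec, phantom):
        # IVH sphere straddling the ventricle boundary: reported volume equals
        # the brute-force count of IVH voxels outside ventricle labels
        from lesionloc.imaging import voxel_volume_ml
        from lesionloc.localise import compute_region_volumes
        from lesionloc.phantom import inject_lesion, ventricle_ids
        scan, parc, _ = phantom
        # centred at a ventricle tip so that part of the sphere sticks out
        center = (spec.ventricle_offset + spec.ventricle_axes[0], 0.0, 0.0)
        _, seg, _ = inject_lesion(scan, parc, class_id=4, center_mm=center,
                                  radius_mm=6.0)
        vox = voxel_volume_ml(seg)
        table = compute_region_volumes(seg, parc, vox)
        vids = ventricle_ids(parc)
        vol, _ = ivh_outside_ventricles(table, vids)
        outside = (seg.data == 4) & ~np.isin(parc.data, vids)
        assert vol == pytest.approx(outside.sum() * vox)


class TestQCRecord:
    def test_overall_is_disjunction(self, rng):
        for _ in range(50):
            flags = rng.random(3) < 0.5
            rec = QCRecord("s", sm=0.8, sm_flag=bool(flags[0]),
                           n_outlier_regions=7 if flags[1] else 0,
                           outlier_flag=bool(flags[1]),
                           ivh_outside_ml=2.0 if flags[2] else 0.0,
                           ivh_flag=bool(flags[2]))
            assert (rec.overall == "flagged") == bool(flags.any())

    def test_make_record_wires_components(self):
        t = make_table("s", {}, ivh={5: 2.0})
        rec = make_qc_record(t, sm=0.5, ventricle_ids=[30, 31],
                             n_outlier_regions=6)
        assert rec.sm_flag and rec.outlier_flag and rec.ivh_flag
        assert rec.overall == "flagged"


class TestQcAuc:
    def test_perfect_separation(self):
        sms = [0.9, 0.8, 0.85, 0.3, 0.2]
        scores = [4, 5, 3, 2, 1]
        assert qc_auc(sms, scores) == 1.0

    def test_all_ties_give_half(self):
        assert qc_auc([0.7] * 6, [1, 2, 3, 4, 5, 3]) == 0.5

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 30))
            sms = np.round(rng.uniform(0, 1, n), 2)  # rounding forces ties
            scores = rng.integers(1, 6, n)
            auc = qc_auc(sms, scores)
            pos = sms[scores >= 3]
            neg = sms[scores < 3]
            if len(pos) == 0 or len(neg) == 0:
                assert auc is None
                continue
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc == pytest.approx(wins / (len(pos) * len(neg)))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 1, allow_nan=False),
                              st.integers(1, 5)), min_size=4, max_size=40))
    def test_invariant_under_monotone_transform(self, pairs):
        sms = np.array([p[0] for p in pairs])
        scores = [p[1] for p in pairs]
        base = qc_auc(sms, scores)
        transformed = qc_auc(np.exp(3 * sms), scores)
        if base is None:
            assert transformed is None
        else:
            assert transformed == pytest.approx(base)

    def test_single_class_undefined(self):
        with pytest.warns(UserWarning, match="one class"):
            assert qc_auc([0.5, 0.6], [4, 5]) is None

    def test_stricter_cutoff_option(self):
        sms = [0.9, 0.4, 0.8, 0.3]
        scores = [4, 3, 5, 2]
        # cutoff 4: scores {4,5} positive, {3,2} negative -> perfect
        assert qc_auc(sms, scores, acceptable_cutoff=4) == 1.0
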