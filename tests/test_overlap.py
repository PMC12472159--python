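"""Hit decisions, IoU, and stratified overlap count tables."""

import numpy as np
import pandas as pd
import pytest

from fundusxai.heatmap_ops import (
    BinaryActivationMap,
    Heatmap,
    ThresholdSpec,
    normalize_heatmap,
    percentile_threshold,
)
from fundusxai.mask_ops import LesionMask
from fundusxai.overlap_analysis import (
    OverlapRecord,
    build_overlap_table,
    evaluate_image,
    intersect,
    records_to_frame,
)


def _amap(values):
    return BinaryActivationMap(np.asarray(values, dtype=np.uint8), threshold_used=0.5)


def _mask(values, lesion="EX"):
    return LesionMask(np.asarray(values, dtype=np.uint8), lesion)


class TestIntersect:
    def test_identical_sets_full_overlap(self):
        v = np.zeros((10, 10), np.uint8)
        v[:2, :10] = 1  # 20 pixels
        rec = intersect(_amap(v), _mask(v))
        assert rec.hit and rec.intersection_pixels == 20 and rec.iou == 1.0

    def test_disjoint_sets_no_hit(self):
        a = np.zeros((10, 10), np.uint8)
        m = np.zeros((10, 10), np.uint8)
        a[0, :10] = 1
        m[5:7, :10] = 1
        rec = intersect(_amap(a), _mask(m))
        assert not rec.hit and rec.iou == 0.0 and rec.intersection_pixels == 0

    def test_partial_overlap_jaccard(self):
        a = np.zeros((10, 10), np.uint8)
        m = np.zeros((10, 10), np.uint8)
        a[0, :10] = 1  # 10 px
        m[0, 5:10] = 1  # overlap 5
        m[1, :10] = 1
        m[2, :5] = 1  # total 20 px
        rec = intersect(_amap(a), _mask(m))
        assert rec.intersection_pixels == 5
        assert rec.iou == pytest.approx(5 / 25)

    def test_both_empty_flagged(self):
        rec = intersect(_amap(np.zeros((4, 4))), _mask(np.zeros((4, 4))))
        assert rec.iou == 0.0 and rec.both_empty and not rec.hit

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            intersect(_amap(np.zeros((4, 4))), _mask(np.zeros((5, 5))))

    def test_bounds_invariants_random(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = (rng.uniform(size=(8, 8)) > 0.6).astype(np.uint8)
            m = (rng.uniform(size=(8, 8)) > 0.6).astype(np.uint8)
            rec = intersect(_amap(a), _mask(m))
            assert rec.intersection_pixels <= min(a.sum(), m.sum())
            if max(a.sum(), m.sum()) > 0:
                assert rec.iou <= rec.intersection_pixels / max(a.sum(), m.sum()) + 1e-12
            assert rec.hit == (rec.intersection_pixels > 0)


class TestEvaluateImage:
    def _heatmaps(self, rng, shape=(20, 20)):
        return {
            "gradcam": normalize_heatmap(rng.uniform(size=shape), "gradcam"),
            "ig": normalize_heatmap(rng.uniform(size=shape), "ig"),
        }

    def test_blob_inside_top_decile_is_hit(self):
        field = np.zeros((20, 20))
        field[5:8, 5:8] = 1.0  # the only activation
        h = normalize_heatmap(field, "gradcam")
        m = np.zeros((20, 20), np.uint8)
        m[6, 6] = 1
        recs = evaluate_image(
            "img0", [LesionMask(m, "EX")], {"gradcam": h, "ig": h}, 2, 2
        )
        assert all(r.hit for r in recs)

    def test_no_masks_warns_and_returns_empty(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="no masks"):
            assert evaluate_image("x", [], self._heatmaps(rng), 0, 0) == []

    def test_missing_heatmap_rejected(self):
        rng = np.random.default_rng(0)
        h = self._heatmaps(rng)
        del h["ig"]
        with pytest.raises(KeyError):
            evaluate_image("x", [_mask(np.zeros((20, 20)))], h, 0, 0)

    def test_matches_brute_force_recount(self):
        """Records must agree with an independent nested-loop recount."""
        rng = np.random.default_rng(12)
        shape = (20, 20)
        heatmaps = self._heatmaps(rng, shape)
        masks = [
            LesionMask((rng.uniform(size=shape) > 0.8).astype(np.uint8), t)
            for t in ("MA", "EX", "HE")
        ]
        recs = evaluate_image("img", masks, heatmaps, 3, 2)
        assert len(recs) == 6  # 2 methods x 3 lesions
        pcts = {"gradcam": 90.0, "ig": 97.0}
        for rec in recs:
            h = heatmaps[rec.method].values
            t = np.percentile(h, pcts[rec.method])
            mask = next(m for m in masks if m.lesion_type == rec.lesion_type)
            count = 0
            for i in range(shape[0]):
                for j in range(shape[1]):
                    if h[i, j] >= t and mask.values[i, j]:
                        count += 1
            assert rec.intersection_pixels == count
            assert rec.hit == (count > 0)
            assert rec.correct is False and rec.grade == 3

    def test_lowering_percentile_never_unhits(self):
        rng = np.random.default_rng(4)
        shape = (16, 16)
        heatmaps = self._heatmaps(rng, shape)
        masks = [LesionMask((rng.uniform(size=shape) > 0.9).astype(np.uint8), "EX")]
        hits = []
        for p in (99.0, 95.0, 80.0, 50.0):
            recs = evaluate_image(
                "x", masks, heatmaps, 1, 1, percentiles={"gradcam": p, "ig": p}
            )
            hits.append({(r.method): r.hit for r in recs})
        for later, earlier in zip(hits[1:], hits[:-1]):
            for method in later:
                assert later[method] >= earlier[method]


class TestBuildOverlapTable:
    def _rec(self, image_id, lesion="EX", hit=True, grade=2, correct=True, method="gradcam"):
        return OverlapRecord(image_id, method, lesion, hit, int(hit), float(hit), grade, correct)

    def test_counts_single_stratum(self):
        recs = [self._rec(f"i{k}") for k in range(3)]
        table = build_overlap_table(recs)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["n_images"] == 3 and row["n_hit"] == 3

    def test_empty_records(self):
        assert build_overlap_table([]).empty

    def test_inconsistent_duplicates_rejected(self):
        recs = [self._rec("a", hit=True), self._rec("a", hit=False)]
        with pytest.raises(ValueError, match="duplicate"):
            build_overlap_table(recs)

    def test_matches_groupby_oracle_random(self):
        rng = np.random.default_rng(99)
        recs = []
        for i in range(50):
            grade = int(rng.integers(0, 5))
            correct = bool(rng.integers(0, 2))
            for lesion in ("MA", "EX"):
                recs.append(
                    self._rec(
                        f"img{i}",
                        lesion=lesion,
                        hit=bool(rng.integers(0, 2)),
                        grade=grade,
                        correct=correct,
                    )
                )
        table = build_overlap_table(recs)
        # brute-force oracle over raw python dicts
        oracle: dict = {}
        totals: dict = {}
        for r in recs:
            key = (r.method, r.grade, r.correct, r.lesion_type)
            oracle[key] = oracle.get(key, 0) + int(r.hit)
            totals.setdefault(key, set()).add(r.image_id)
        for _, row in table.iterrows():
            key = (row["method"], row["grade"], row["correct"], row["lesion"])
            assert row["n_hit"] == oracle[key]
            assert row["n_images"] == len(totals[key])
            assert row["n_hit"] <= row["n_images"]
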