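"""Overlap metrics, 95% Hausdorff distance and paired comparison."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import t as t_dist

from vertebox.errors import DegenerateInputError, EmptyMaskError, InvalidInputError
from vertebox.metrics import (
    boundary_points, dsc, evaluate_cases, hausdorff, hd95, iou, paired_compare,
)

RNG = np.random.default_rng(41)


def random_mask(shape=(24, 24), p=0.3, rng=RNG):
    return (rng.random(shape) < p).astype(np.uint8)


def brute_force_hd(a, b, percentile):
    """All-pairs O(n^2) oracle over the same boundary point sets."""
    pa, pb = boundary_points(a).astype(float), boundary_points(b).astype(float)
    d = cdist(pa, pb)
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return np.percentile(pooled, percentile)


class TestOverlap:
    def test_identity_masks(self):
        m = random_mask()
        assert dsc(m, m) == 1.0
        assert iou(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((6, 6), dtype=np.uint8)
        b = np.zeros((6, 6), dtype=np.uint8)
        a[0, 0] = 1
        b[5, 5] = 1
        assert dsc(a, b) == 0.0
        assert iou(a, b) == 0.0

    def test_counted_example(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 4), dtype=np.uint8)
        a[0, :4] = 1          # |A| = 4
        b[0, 2:], b[1, :2] = 1, 1  # |B| = 4, overlap = 2
        assert dsc(a, b) == pytest.approx(0.5)
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_both_empty_defined_as_one(self):
        z = np.zeros((5, 5), dtype=np.uint8)
        assert dsc(z, z) == 1.0 and iou(z, z) == 1.0

    def test_dice_iou_link_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b = random_mask(rng=rng), random_mask(rng=rng)
            i = iou(a, b)
            assert dsc(a, b) == pytest.approx(2 * i / (1 + i), abs=1e-12)

    def test_symmetry(self):
        a, b = random_mask(), random_mask()
        assert dsc(a, b) == dsc(b, a)
        assert iou(a, b) == iou(b, a)

    def test_input_validation(self):
        with pytest.raises(InvalidInputError):
            dsc(np.zeros((3, 3)), np.zeros((4, 4)))
        with pytest.raises(InvalidInputError):
            iou(np.full((3, 3), 2), np.zeros((3, 3)))


class TestHausdorff:
    def test_identical_masks_zero(self):
        m = random_mask()
        m[10:14, 10:14] = 1
        assert hd95(m, m) == 0.0

    def test_single_pixel_pair_is_euclidean_distance(self):
        a = np.zeros((8, 8), dtype=np.uint8)
        b = np.zeros((8, 8), dtype=np.uint8)
        a[0, 0] = 1
        b[3, 4] = 1
        assert hd95(a, b) == pytest.approx(5.0)
        assert hausdorff(a, b) == pytest.approx(5.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        checked = 0
        while checked < 60:
            a, b = random_mask(rng=rng, p=0.2), random_mask(rng=rng, p=0.2)
            if not a.any() or not b.any():
                continue
            assert hd95(a, b) == pytest.approx(brute_force_hd(a, b, 95), abs=1e-10)
            checked += 1

    def test_hd95_bounded_by_max_hausdorff(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            a, b = random_mask(rng=rng), random_mask(rng=rng)
            if a.any() and b.any():
                assert hd95(a, b) <= hausdorff(a, b) + 1e-12

    def test_spacing_scales_distances_linearly(self):
        a = np.zeros((10, 10), dtype=np.uint8)
        b = np.zeros((10, 10), dtype=np.uint8)
        a[2:4, 2:4] = 1
        b[6:8, 6:8] = 1
        assert hd95(a, b, spacing=(2.0, 2.0)) == pytest.approx(2 * hd95(a, b))

    def test_symmetry(self):
        a, b = random_mask(p=0.2), random_mask(p=0.2)
        assert hd95(a, b) == hd95(b, a)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            hd95(np.zeros((5, 5), dtype=np.uint8), np.ones((5, 5), dtype=np.uint8))

    def test_3d_boundary_uses_six_connectivity(self):
        m = np.zeros((5, 5, 5), dtype=np.uint8)
        m[1:4, 1:4, 1:4] = 1
        pts = boundary_points(m)
        assert len(pts) == 27 - 1  # all cube voxels except the centre


class TestPairedCompare:
    def test_matches_textbook_computation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a + np.array([0.1, -0.1, 0.1, -0.1])
        d = a - b
        tstat = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        expected = 2 * t_dist.sf(abs(tstat), df=len(d) - 1)
        assert paired_compare(a, b) == pytest.approx(expected, rel=1e-12)

    def test_symmetric_in_arguments(self):
        a = RNG.standard_normal(8)
        b = a + RNG.standard_normal(8)
        assert paired_compare(a, b) == pytest.approx(paired_compare(b, a), rel=1e-12)

    def test_constant_shift_rejected_as_degenerate(self):
        a = np.array([0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
        with pytest.raises(DegenerateInputError):
            paired_compare(a, a + 0.1)

    def test_length_validation(self):
        with pytest.raises(InvalidInputError):
            paired_compare([1.0], [2.0])


class TestEvaluateCases:
    def test_per_case_link_and_summary(self):
        rng = np.random.default_rng(3)
        preds = [random_mask(rng=rng) for _ in range(5)]
        truths = [random_mask(rng=rng) for _ in range(5)]
        report = evaluate_cases(preds, truths)
        for _, row in report.per_case.iterrows():
            assert row.dsc == pytest.approx(2 * row.iou / (1 + row.iou), abs=1e-9)
        assert report.summary.loc["mean", "dsc"] == pytest.approx(
            report.per_case.dsc.mean())

    def test_empty_mask_case_reported_missing_not_zero(self):
        z = np.zeros((6, 6), dtype=np.uint8)
        o = np.zeros((6, 6), dtype=np.uint8)
        o[2:4, 2:4] = 1
        report = evaluate_cases([z], [o])
        assert np.isnan(report.per_case.hd95.iloc[0])
        assert report.per_case.dsc.iloc[0] == 0.0

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd
        m = random_mask()
        report = evaluate_cases([m], [m], case_ids=["case0"])
        out = tmp_path / "report.csv"
        report.to_csv(out)
        table = pd.read_csv(out)
        assert list(table.case) == ["case0", "mean", "std"]
        assert table.dsc.iloc[0] == 1.0

    def test_per_slice_mode_expands_3d_cases(self):
        vol = np.zeros((4, 8, 8), dtype=np.uint8)
        vol[:, 2:5, 2:5] = 1
        report = evaluate_cases([vol], [vol], case_ids=["v"], per_slice=True,
                                spacing=(1.0, 1.0, 1.0))
        assert len(report.per_case) == 4
        assert (report.per_case.dsc == 1.0).all()
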