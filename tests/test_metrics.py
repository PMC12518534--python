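"""Evaluation indicators: Dice, Hausdorff distances, confusion metrics."""

import numpy as np
import pytest

from dcfnet.metrics import (MetricReport, confusion_metrics, dsc_metric,
                            evaluate_case, evaluate_dataset, hausdorff,
                            write_report)


def random_blob_mask(rng, size=24):
    m = np.zeros((size, size), dtype=bool)
    for _ in range(rng.integers(1, 4)):
        cy, cx = rng.integers(4, size - 4, size=2)
        r = rng.integers(2, 6)
        yy, xx = np.mgrid[:size, :size]
        m |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
    return m


class TestDsc:
    def test_identical_nonempty_masks_score_one(self, rng):
        m = random_blob_mask(rng)
        assert dsc_metric(m, m) == 1.0

    def test_pixel_count_oracle(self):
        # |P| = 8, |L| = 10, |P∩L| = 6 -> 12/18
        P = np.zeros((5, 5), dtype=bool)
        L = np.zeros((5, 5), dtype=bool)
        P.flat[:8] = True
        L.flat[2:12] = True
        assert dsc_metric(P, L) == pytest.approx(12 / 18)

    def test_disjoint_masks_score_zero(self):
        P = np.eye(4, dtype=bool)
        assert dsc_metric(P, ~P) == 0.0

    def test_empty_mask_conventions(self):
        z = np.zeros((3, 3), dtype=bool)
        o = np.ones((3, 3), dtype=bool)
        assert dsc_metric(z, z) == 1.0
        assert dsc_metric(z, o) == 0.0

    def test_equals_two_iou_over_one_plus_iou(self, rng):
        for _ in range(20):
            P, L = random_blob_mask(rng), random_blob_mask(rng)
            iou = confusion_metrics(P, L).iou
            assert dsc_metric(P, L) == pytest.approx(2 * iou / (1 + iou), abs=1e-12)


class TestHausdorff:
    def test_identical_masks_give_zero(self, rng):
        m = random_blob_mask(rng)
        assert hausdorff(m, m) == 0.0

    def test_three_four_five_geometry(self):
        P = np.zeros((6, 6), dtype=bool)
        L = np.zeros((6, 6), dtype=bool)
        P[0, 0] = True
        L[3, 4] = True
        assert hausdorff(P, L) == pytest.approx(5.0)

    def test_symmetry_and_percentile_ordering_on_500_random_pairs(self, rng):
        for _ in range(500):
            P, L = random_blob_mask(rng), random_blob_mask(rng)
            hd = hausdorff(P, L)
            assert hd == pytest.approx(hausdorff(L, P))
            assert hausdorff(P, L, percentile=95) <= hd + 1e-12

    def test_percentile_against_brute_force_all_pairs(self, rng):
        from dcfnet.metrics import boundary_points
        P, L = random_blob_mask(rng), random_blob_mask(rng)
        bp, bl = boundary_points(P), boundary_points(L)
        d = np.linalg.norm(bp[:, None, :] - bl[None, :, :], axis=-1)
        d_pl, d_lp = d.min(axis=1), d.min(axis=0)
        assert hausdorff(P, L) == pytest.approx(max(d_pl.max(), d_lp.max()))
        assert hausdorff(P, L, 95) == pytest.approx(
            max(np.percentile(d_pl, 95), np.percentile(d_lp, 95)))

    def test_empty_boundary_reports_nan_with_warning(self):
        z = np.zeros((4, 4), dtype=bool)
        with pytest.warns(UserWarning):
            assert np.isnan(hausdorff(z, np.ones((4, 4), dtype=bool)))

    def test_spacing_scales_distances(self):
        P = np.zeros((6, 6), dtype=bool)
        L = np.zeros((6, 6), dtype=bool)
        P[0, 0] = True
        L[0, 3] = True
        assert hausdorff(P, L, spacing=(1.0, 2.0)) == pytest.approx(6.0)


class TestConfusion:
    def test_counting_oracle(self):
        # TP=8, FP=2, FN=1, TN=89 on a 10x10 grid
        P = np.zeros((10, 10), dtype=bool)
        L = np.zeros((10, 10), dtype=bool)
        L.flat[:9] = True          # 9 positives
        P.flat[:8] = True          # 8 true positives
        P.flat[9:11] = True        # 2 false positives (index 9 is FN)
        rep = confusion_metrics(P, L)
        assert rep.ac == pytest.approx(0.97)
        assert rep.pr == pytest.approx(0.8)
        assert rep.se == pytest.approx(8 / 9)
        assert rep.sp == pytest.approx(89 / 91)
        assert rep.iou == pytest.approx(8 / 11)

    def test_perfect_prediction_scores_one_everywhere(self, rng):
        m = random_blob_mask(rng)
        rep = confusion_metrics(m, m)
        for v in (rep.ac, rep.pr, rep.se, rep.sp, rep.iou):
            assert v == pytest.approx(1.0)

    def test_all_background_prediction_has_zero_sensitivity(self, rng):
        L = random_blob_mask(rng)
        rep = confusion_metrics(np.zeros_like(L), L)
        assert rep.se == 0.0
        assert np.isnan(rep.pr)  # no predicted positives: precision undefined


class TestInvariances:
    def test_metrics_invariant_under_joint_horizontal_flip(self, rng):
        P, L = random_blob_mask(rng), random_blob_mask(rng)
        Pf, Lf = P[:, ::-1], L[:, ::-1]
        assert dsc_metric(P, L) == dsc_metric(Pf, Lf)
        assert hausdorff(P, L) == pytest.approx(hausdorff(Pf, Lf))
        a, b = confusion_metrics(P, L), confusion_metrics(Pf, Lf)
        assert (a.ac, a.pr, a.se, a.sp, a.iou) == (b.ac, b.pr, b.se, b.sp, b.iou)

    def test_hd95_never_exceeds_hd_in_case_report(self, rng):
        pred = (random_blob_mask(rng)).astype(int)
        lab = (random_blob_mask(rng)).astype(int)
        rep = evaluate_case(pred, lab, num_classes=2)
        if not np.isnan(rep.hd):
            assert rep.hd95 <= rep.hd + 1e-12


class TestReports:
    def test_ground_truth_against_itself(self, rng):
        masks = [(random_blob_mask(rng)).astype(int) for _ in range(3)]
        cases, agg = evaluate_dataset(masks, masks, num_classes=2)
        assert agg.mean_dsc == pytest.approx(1.0)
        assert agg.hd == pytest.approx(0.0)
        assert len(cases) == 3

    def test_per_class_table_has_foreground_rows_only(self, rng):
        pred = np.zeros((8, 8), dtype=int)
        pred[2:5, 2:5] = 3
        rep = evaluate_case(pred, pred, num_classes=9)
        assert len(rep.per_class_dsc) == 8

    def test_report_files_written(self, tmp_path, rng):
        m = (random_blob_mask(rng)).astype(int)
        cases, agg = evaluate_dataset([m], [m], num_classes=2)
        write_report(tmp_path / "report", cases, agg)
        assert (tmp_path / "report.json").exists()
        assert (tmp_path / "report.csv").exists()
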