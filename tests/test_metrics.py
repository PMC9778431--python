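"""Metric oracles: hand counts, algebraic identities, brute-force HD95 and
independently coded S-/E-measure references."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nodulecomp.metrics import (
    confusion_counts, e_measure, evaluate_dataset, evaluate_pairs, hd95,
    image_metrics, mae, region_metrics, s_measure,
)


# ---------------------------------------------------------------------------
# independent reference implementations (loop-based, kept deliberately naive)


def brute_force_hd95(s, gt):
    ps = np.argwhere(s)
    ts = np.argwhere(gt)
    d = np.sqrt(((ps[:, None, :] - ts[None, :, :]) ** 2).sum(-1))
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return np.percentile(pooled, 95)


def ref_s_object_part(vals):
    x = vals.mean()
    sigma = vals.std(ddof=1) if vals.size > 1 else 0.0
    return 2 * x / (x ** 2 + 1 + sigma + 1e-12)


def ref_s_measure(p, gt):
    gt = gt.astype(bool)
    mu = gt.mean()
    so = mu * ref_s_object_part(p[gt]) + (1 - mu) * ref_s_object_part((1 - p)[~gt])
    ys, xs = np.nonzero(gt)
    cy, cx = int(round(ys.mean())) + 1, int(round(xs.mean())) + 1
    h, w = gt.shape
    sr = 0.0
    for rs, cs in [((0, cy), (0, cx)), ((0, cy), (cx, w)),
                   ((cy, h), (0, cx)), ((cy, h), (cx, w))]:
        pb = p[rs[0]:rs[1], cs[0]:cs[1]]
        gb = gt[rs[0]:rs[1], cs[0]:cs[1]].astype(float)
        n = pb.size
        x, y = pb.mean(), gb.mean()
        sx = ((pb - x) ** 2).sum() / (n - 1)
        sy = ((gb - y) ** 2).sum() / (n - 1)
        sxy = ((pb - x) * (gb - y)).sum() / (n - 1)
        a, b = 4 * x * y * sxy, (x * x + y * y) * (sx + sy)
        if a != 0:
            q = a / (b + 1e-12)
        else:
            q = 1.0 if b == 0 else 0.0
        sr += (n / gt.size) * q
    return max(0.5 * so + 0.5 * sr, 0.0)


def ref_e_measure(s, gt):
    s = s.astype(float)
    g = gt.astype(float)
    h, w = g.shape
    sc = s - s.mean()
    gc = g - g.mean()
    total = 0.0
    for i in range(h):
        for j in range(w):
            xi = 2 * gc[i, j] * sc[i, j] / (gc[i, j] ** 2 + sc[i, j] ** 2 + 1e-12)
            total += (xi + 1) ** 2 / 4
    return total / (h * w - 1 + 1e-12)


# ---------------------------------------------------------------------------


class TestRegionMetrics:
    def test_perfect_overlap(self):
        gt = np.zeros((5, 5), np.uint8)
        gt[1:4, 1:4] = 1
        m = region_metrics(gt, gt)
        assert m["DSC"] == m["JA"] == m["SE"] == 1.0

    def test_hand_counted_toy_masks(self):
        """|S|=6, |GT|=4, |S∩GT|=3 on a 4x4 field."""
        s = np.zeros((4, 4), np.uint8)
        gt = np.zeros((4, 4), np.uint8)
        s[0, :3] = 1
        s[1, :3] = 1                    # S: rows 0-1, cols 0-2 (6 px)
        gt[0, 0] = gt[0, 1] = gt[1, 0] = 1  # 3 px inside S
        gt[3, 3] = 1                    # 1 px outside S
        c = confusion_counts(s, gt)
        assert (c.TP, c.FP, c.FN, c.TN) == (3, 3, 1, 9)
        m = region_metrics(s, gt)
        assert m["DSC"] == pytest.approx(2 * 3 / (6 + 4))
        assert m["JA"] == pytest.approx(3 / 7)
        assert m["SE"] == pytest.approx(3 / 4)
        assert m["SP"] == pytest.approx(9 / 12)

    def test_empty_vs_empty_conventions(self):
        z = np.zeros((4, 4), np.uint8)
        m = region_metrics(z, z)
        assert m["DSC"] == m["JA"] == 1.0
        assert np.isnan(m["SE"])
        assert m["SP"] == 1.0

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_ja_dsc_identity(self, seed):
        rng = np.random.default_rng(seed)
        s = (rng.random((10, 10)) > 0.5).astype(np.uint8)
        gt = (rng.random((10, 10)) > 0.5).astype(np.uint8)
        m = region_metrics(s, gt)
        assert m["JA"] == pytest.approx(m["DSC"] / (2 - m["DSC"]), abs=1e-12)


class TestHD95:
    def test_identical_masks_zero(self):
        m = np.zeros((8, 8), np.uint8)
        m[2:5, 3:6] = 1
        assert hd95(m, m) == 0.0

    def test_singleton_pixels_euclidean(self):
        a = np.zeros((8, 8), np.uint8)
        b = np.zeros((8, 8), np.uint8)
        a[0, 0] = 1
        b[3, 4] = 1
        assert hd95(a, b) == pytest.approx(5.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            h, w = rng.integers(3, 13, 2)
            s = (rng.random((h, w)) > 0.6).astype(np.uint8)
            gt = (rng.random((h, w)) > 0.6).astype(np.uint8)
            if not s.any() or not gt.any():
                continue
            assert hd95(s, gt) == pytest.approx(brute_force_hd95(s, gt), abs=1e-9)

    def test_symmetry_and_bounded_by_full_hausdorff(self, rng):
        s = (rng.random((12, 12)) > 0.6).astype(np.uint8)
        gt = (rng.random((12, 12)) > 0.6).astype(np.uint8)
        assert hd95(s, gt) == pytest.approx(hd95(gt, s))
        ps, ts = np.argwhere(s), np.argwhere(gt)
        d = np.sqrt(((ps[:, None] - ts[None]) ** 2).sum(-1))
        full_hd = max(d.min(1).max(), d.min(0).max())
        assert hd95(s, gt) <= full_hd + 1e-12

    def test_empty_mask_is_nan_with_warning(self):
        m = np.zeros((4, 4), np.uint8)
        n = m.copy()
        n[1, 1] = 1
        with pytest.warns(UserWarning, match="empty"):
            assert np.isnan(hd95(m, n))

    def test_spacing_scales_distances(self):
        a = np.zeros((4, 4), np.uint8)
        b = np.zeros((4, 4), np.uint8)
        a[0, 0] = 1
        b[0, 2] = 1
        assert hd95(a, b, spacing=2.0) == pytest.approx(4.0)


class TestStructureMeasures:
    def _toy(self, rng):
        gt = np.zeros((16, 16), np.uint8)
        gt[4:11, 5:13] = 1
        p = np.clip(gt + rng.normal(0, 0.2, gt.shape), 0, 1)
        return p, gt

    def test_perfect_binary_prediction(self):
        gt = np.zeros((16, 16), np.uint8)
        gt[4:11, 5:13] = 1
        assert s_measure(gt.astype(float), gt) >= 0.99
        assert e_measure(gt, gt) == pytest.approx(1.0, abs=1e-6)

    def test_s_measure_matches_reference(self, rng):
        for _ in range(10):
            p, gt = self._toy(rng)
            assert s_measure(p, gt) == pytest.approx(ref_s_measure(p, gt),
                                                     abs=1e-6)

    def test_e_measure_matches_reference(self, rng):
        for _ in range(10):
            _, gt = self._toy(rng)
            s = (rng.random(gt.shape) > 0.5).astype(np.uint8)
            assert e_measure(s, gt) == pytest.approx(ref_e_measure(s, gt),
                                                     abs=1e-6)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_bounded_metrics_stay_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random((8, 8))
        gt = (rng.random((8, 8)) > rng.random()).astype(np.uint8)
        s = (p > 0.5).astype(np.uint8)
        assert 0 <= s_measure(p, gt) <= 1
        assert 0 <= e_measure(s, gt) <= 1
        assert 0 <= mae(p, gt) <= 1
        m = region_metrics(s, gt)
        for k in ("DSC", "JA", "SP"):
            # undefined values (e.g. SP when GT fills the field) are NaN
            assert np.isnan(m[k]) or 0 <= m[k] <= 1

    def test_mae_closed_forms(self):
        gt = np.zeros((4, 4))
        assert mae(gt, gt) == 0.0
        assert mae(1 - gt, gt) == 1.0
        assert mae(np.full((4, 4), 0.25), gt) == pytest.approx(0.25)


class TestDatasetEvaluation:
    def _write_pairs(self, tmp_path, identical=True):
        import imageio.v3 as iio
        pred = tmp_path / "pred"
        gt = tmp_path / "gt"
        pred.mkdir()
        gt.mkdir()
        rng = np.random.default_rng(0)
        for i in range(10):
            m = np.zeros((32, 32), np.uint8)
            r, c = rng.integers(4, 20, 2)
            m[r:r + 8, c:c + 8] = 255
            iio.imwrite(gt / f"img{i:02d}.png", m)
            iio.imwrite(pred / f"img{i:02d}.png", m if identical else 255 - m)
        return pred, gt

    def test_identical_predictions_give_perfect_report(self, tmp_path):
        pred, gt = self._write_pairs(tmp_path)
        report = evaluate_dataset(pred, gt)
        means = report.aggregate.loc["mean"]
        sds = report.aggregate.loc["sd"]
        for k in ("DSC", "JA", "Sm", "Em"):
            assert means[k] == pytest.approx(1.0, abs=1e-6)
            assert sds[k] == pytest.approx(0.0, abs=1e-6)
        assert means["HD95"] == 0.0
        assert means["MAE"] == 0.0

    def test_missing_pair_is_hard_error(self, tmp_path):
        pred, gt = self._write_pairs(tmp_path)
        (gt / "img03.png").unlink()
        with pytest.raises(FileNotFoundError, match="img03"):
            evaluate_dataset(pred, gt)

    def test_aggregate_mean_equals_hand_average(self, tmp_path):
        pred, gt = self._write_pairs(tmp_path, identical=False)
        report = evaluate_dataset(pred, gt)
        for k in ("DSC", "MAE", "Em"):
            vals = report.per_image[k].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            assert report.aggregate.loc["mean", k] == pytest.approx(vals.mean())

    def test_csv_roundtrip_has_aggregate_rows(self, tmp_path):
        import pandas as pd
        pred, gt = self._write_pairs(tmp_path)
        out = tmp_path / "report.csv"
        evaluate_dataset(pred, gt, out_csv=out)
        df = pd.read_csv(out)
        assert list(df.columns)[:3] == ["image_id", "DSC", "JA"]
        assert {"mean", "sd", "ci95_lower", "ci95_upper"} <= set(df["image_id"])


def test_image_metrics_reports_all_eight(rng):
    gt = np.zeros((24, 24), np.uint8)
    gt[6:16, 8:20] = 1
    prob = np.clip(gt + rng.normal(0, 0.1, gt.shape), 0, 1)
    m = image_metrics(prob, gt)
    assert set(m) == {"DSC", "JA", "HD95", "SE", "SP", "Sm", "Em", "MAE"}
    assert all(np.isfinite(v) for v in m.values())
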