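"""Edge ground truth, edge weights and the hybrid loss: closed-form cases,
reduction identities and gradient sanity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nodulecomp.losses import (
    EdgeWeightMap, LossConfig, edge_gt, edge_loss, edge_weights, seg_loss,
    total_loss, weighted_bce, weighted_iou,
)
from nodulecomp.cm import PredictionSet
from nodulecomp.nn import Tensor


class TestEdgeGT:
    def test_constant_masks_have_no_edge(self):
        assert edge_gt(np.zeros((6, 6), np.uint8)).sum() == 0
        inner = edge_gt(np.ones((6, 6), np.uint8))[1:-1, 1:-1]
        assert inner.sum() == 0

    def test_single_pixel_gives_3x3_block(self):
        gs = np.zeros((7, 7), np.uint8)
        gs[3, 3] = 1
        ge = edge_gt(gs)
        assert ge.sum() == 9
        assert ge[2:5, 2:5].all()

    def test_edge_between_dilation_and_erosion(self, rng):
        from scipy.ndimage import binary_dilation, binary_erosion
        gs = (rng.random((16, 16)) > 0.6).astype(np.uint8)
        ge = edge_gt(gs).astype(bool)
        dil = binary_dilation(gs.astype(bool), np.ones((3, 3), bool))
        ero = binary_erosion(gs.astype(bool), np.ones((3, 3), bool))
        assert (ge <= dil).all() and not (ge & ero).any()

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            edge_gt(np.full((4, 4), 0.5))


class TestEdgeWeights:
    def test_constant_mask_gives_alpha(self):
        for gs in (np.zeros((9, 9)), np.ones((9, 9))):
            w = edge_weights(gs.astype(np.uint8))
            np.testing.assert_allclose(w.W, 1.0)

    def test_pool_size_one_degenerates_to_alpha(self, rng):
        gs = (rng.random((9, 9)) > 0.5).astype(np.uint8)
        w = edge_weights(gs, LossConfig(pool_size=1))
        np.testing.assert_allclose(w.W, 1.0)

    def test_half_plane_boundary_value(self):
        """5x5 mask, left two columns 1, 3x3 pool: boundary-column weight
        is 1 + 5*|1 - 2/3| = 8/3."""
        gs = np.zeros((5, 5), np.uint8)
        gs[:, :2] = 1
        w = edge_weights(gs, LossConfig(pool_size=3)).W
        np.testing.assert_allclose(w[:, 1], 8.0 / 3.0, atol=1e-12)

    def test_even_pool_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            LossConfig(pool_size=4)

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_bounds_alpha_to_alpha_plus_beta(self, seed):
        rng = np.random.default_rng(seed)
        gs = (rng.random((24, 24)) > rng.random()).astype(np.uint8)
        w = edge_weights(gs)
        assert (w.W >= 1.0 - 1e-12).all() and (w.W <= 6.0 + 1e-12).all()


class TestWeightedBCE:
    def test_unit_weights_equal_unweighted_mean_bce(self, rng):
        ps = rng.uniform(0.05, 0.95, (8, 8))
        gs = (rng.random((8, 8)) > 0.5).astype(float)
        w = np.ones_like(ps)
        ours = weighted_bce(ps, gs, w).item()
        ref = -np.mean(gs * np.log(ps) + (1 - gs) * np.log(1 - ps))
        assert math.isclose(ours, ref, rel_tol=1e-9)

    def test_single_pixel_closed_form(self):
        loss = weighted_bce(np.array([[0.5]]), np.array([[1.0]]),
                            np.array([[2.0]]))
        assert math.isclose(loss.item(), math.log(2), rel_tol=1e-9)

    def test_perfect_prediction_is_tiny(self):
        gs = np.array([[1.0, 0.0], [0.0, 1.0]])
        loss = weighted_bce(gs.copy(), gs, np.ones_like(gs), epsilon=1e-7)
        assert loss.item() <= 2e-7

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_bce(np.zeros((2, 3)), np.zeros((3, 2)), np.zeros((2, 3)))


class TestWeightedIoU:
    def test_perfect_and_inverted_predictions(self):
        gs = np.array([[1.0, 0.0], [1.0, 0.0]])
        w = np.ones_like(gs)
        assert weighted_iou(gs.copy(), gs, w).item() == pytest.approx(0.0)
        assert weighted_iou(1 - gs, gs, w).item() == pytest.approx(1.0)

    def test_four_pixel_hand_case(self):
        """Gs=(1,1,0,0), Ps=0.5: inter=1.0, union=3.0, loss=2/3."""
        gs = np.array([1.0, 1.0, 0.0, 0.0]).reshape(1, 4)
        ps = np.full((1, 4), 0.5)
        loss = weighted_iou(ps, gs, np.ones_like(gs))
        assert loss.item() == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_empty_vs_empty_warns_and_returns_zero(self):
        z = np.zeros((3, 3))
        with pytest.warns(UserWarning, match="empty"):
            assert weighted_iou(z, z, np.ones_like(z)).item() == 0.0


def test_seg_loss_is_mean_of_components(rng):
    ps = rng.uniform(0.05, 0.95, (6, 6))
    gs = (rng.random((6, 6)) > 0.5).astype(float)
    w = edge_weights(gs.astype(np.uint8)).W
    combined = seg_loss(ps, gs, w).item()
    parts = (weighted_bce(ps, gs, w).item() + weighted_iou(ps, gs, w).item()) / 2
    assert math.isclose(combined, parts, rel_tol=1e-9)


def test_seg_loss_four_pixel_composition():
    gs = np.array([1.0, 1.0, 0.0, 0.0]).reshape(1, 4)
    ps = np.full((1, 4), 0.5)
    expected = (math.log(2) + 2.0 / 3.0) / 2
    assert seg_loss(ps, gs, np.ones_like(gs)).item() == pytest.approx(expected,
                                                                      abs=1e-9)


class TestEdgeLoss:
    def test_half_probability_gives_ln2(self, rng):
        ge = (rng.random((5, 5)) > 0.5).astype(np.uint8)
        loss = edge_loss(np.full((5, 5), 0.5), ge)
        assert loss.item() == pytest.approx(math.log(2), rel=1e-9)

    def test_matches_unit_weighted_bce(self, rng):
        prob = rng.uniform(0.1, 0.9, (5, 5))
        ge = (rng.random((5, 5)) > 0.5).astype(np.uint8)
        assert edge_loss(prob, ge).item() == pytest.approx(
            weighted_bce(prob, ge.astype(float), np.ones((5, 5))).item())


def _fake_pred(ps, edge, fg):
    return PredictionSet(Tensor(ps), Tensor(edge), Tensor(fg), Tensor(edge))


def test_total_loss_composition_and_nonnegativity(rng):
    gs = np.zeros((32, 32), np.uint8)
    gs[8:20, 10:24] = 1
    ps = rng.uniform(0.05, 0.95, (1, 1, 32, 32))
    edge = rng.uniform(0.05, 0.95, (1, 1, 16, 16))
    fg = rng.normal(size=(1, 1, 8, 8))
    cfg = LossConfig(deep_supervision=False)
    total, bd = total_loss(_fake_pred(ps, edge, fg), gs, cfg)
    assert total.item() == pytest.approx(bd["edge"] + bd["seg"], rel=1e-6)
    assert all(v >= 0 for v in bd.values())
    total_ds, bd_ds = total_loss(_fake_pred(ps, edge, fg), gs, LossConfig())
    assert "deep" in bd_ds
    assert total_ds.item() >= total.item()
    assert total_ds.item() >= max(bd_ds["edge"], bd_ds["seg"], bd_ds["deep"])


def test_perfect_predictions_give_near_zero_total():
    gs = np.zeros((32, 32), np.uint8)
    gs[10:22, 10:22] = 1
    from nodulecomp.losses import _downsample_mask
    ge16 = edge_gt(_downsample_mask(gs, (16, 16)))
    ps = gs[None, None].astype(np.float64)
    fg_logits = np.where(_downsample_mask(gs, (8, 8)) > 0, 50.0, -50.0)[None, None]
    total, _ = total_loss(_fake_pred(ps, ge16[None, None].astype(float),
                                     fg_logits), gs,
                          LossConfig(deep_supervision=False))
    assert total.item() < 1e-5


def test_gradient_step_decreases_loss(rng):
    """One Adam step on a free logit map lowers the hybrid seg loss."""
    from nodulecomp.nn import Adam
    gs = (rng.random((12, 12)) > 0.7).astype(np.uint8)
    w = edge_weights(gs).W
    logits = Tensor(rng.normal(size=(12, 12)), requires_grad=True)
    opt = Adam([logits], lr=0.05)
    before = seg_loss(logits.sigmoid(), gs.astype(float), w)
    opt.zero_grad()
    before.backward()
    opt.step()
    after = seg_loss(logits.sigmoid(), gs.astype(float), w)
    assert after.item() < before.item()
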