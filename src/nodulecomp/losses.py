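"""Edge ground truth, edge-pixel weight map and the hybrid training loss.

Pixels at the nodule boundary carry the diagnostically hardest decisions,
so every pixel i receives an importance weight

    W_i = α + β · |Gs − mean_{A_n}(Gs)|

where the local mean is a same-size average pooling of the ground-truth
mask Gs over a pool_size×pool_size neighbourhood A_n (reflective padding).
Far from the boundary the local mean equals Gs and W = α; at the boundary
the deviation pushes W toward α+β.  Defaults α=1, β=5, pool_size=31.

The segmentation loss is the mean of a weighted binary cross entropy
(local, pixel-wise) and a weighted IoU loss (global, structure-aware);
the total hybrid loss adds an unweighted BCE edge supervision between the
predicted edge map and the morphological-gradient edge ground truth, plus
(optionally) deep supervision on the upsampled coarse map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion, uniform_filter
from skimage.transform import resize as sk_resize

from .cm import PredictionSet
from .nn import Tensor, as_tensor
from .nn import functional as F

_STRUCT3 = np.ones((3, 3), dtype=bool)


@dataclass
class LossConfig:
    alpha: float = 1.0
    beta: float = 5.0
    pool_size: int = 31
    epsilon: float = 1e-7
    deep_supervision: bool = True

    def __post_init__(self):
        if self.pool_size < 1 or self.pool_size % 2 == 0:
            raise ValueError("pool_size must be odd and >= 1")


@dataclass
class EdgeWeightMap:
    W: np.ndarray
    alpha: float = 1.0
    beta: float = 5.0
    pool_size: int = 31


def _check_binary(gs: np.ndarray, name: str = "mask") -> np.ndarray:
    gs = np.asarray(gs)
    if not np.all(np.isin(np.unique(gs), (0, 1))):
        raise ValueError(f"{name} must be binary (0/1)")
    return gs.astype(np.float64)


def edge_gt(gs: np.ndarray) -> np.ndarray:
    """Edge map Ge: 3×3 morphological gradient (dilation − erosion) of Gs."""
    gsb = _check_binary(gs, "Gs").astype(bool)
    dil = binary_dilation(gsb, structure=_STRUCT3)
    ero = binary_erosion(gsb, structure=_STRUCT3)
    return (dil & ~ero).astype(np.uint8)


def edge_weights(gs: np.ndarray, cfg: LossConfig | None = None) -> EdgeWeightMap:
    """Per-pixel importance W = α + β·|Gs − local mean(Gs)| (bounded [α, α+β])."""
    cfg = cfg or LossConfig()
    gsf = _check_binary(gs, "Gs")
    if gsf.ndim == 2:
        size = cfg.pool_size
    else:  # batched (N,H,W) or (N,1,H,W): pool only the spatial axes
        size = (1,) * (gsf.ndim - 2) + (cfg.pool_size, cfg.pool_size)
    local_mean = uniform_filter(gsf, size=size, mode="reflect")
    w = cfg.alpha + cfg.beta * np.abs(gsf - local_mean)
    return EdgeWeightMap(w, cfg.alpha, cfg.beta, cfg.pool_size)


def _as_pred(ps) -> Tensor:
    t = as_tensor(ps)
    return t


def _weights_array(w) -> np.ndarray:
    if isinstance(w, EdgeWeightMap):
        return w.W
    return np.asarray(w, dtype=np.float64)


def weighted_bce(ps, gs, w, epsilon: float = 1e-7) -> Tensor:
    """−Σ W·[Gs·log Ps + (1−Gs)·log(1−Ps)] / Σ W."""
    ps = _as_pred(ps)
    gs = np.asarray(gs, dtype=np.float64)
    w = _weights_array(w)
    w = np.broadcast_to(w, ps.shape) if w.shape != ps.shape else w
    gs = np.broadcast_to(gs, ps.shape) if gs.shape != ps.shape else gs
    if ps.shape != gs.shape:
        raise ValueError(f"shape mismatch: Ps {ps.shape} vs Gs {gs.shape}")
    p = ps.clip(epsilon, 1.0 - epsilon)
    ll = Tensor(w * gs) * p.log() + Tensor(w * (1.0 - gs)) * (1.0 - p).log()
    return -(ll.sum()) / float(w.sum())


def weighted_iou(ps, gs, w) -> Tensor:
    """1 − Σ(W·Ps·Gs) / Σ(W·(Ps + Gs − Ps·Gs))."""
    ps = _as_pred(ps)
    gs = np.asarray(gs, dtype=np.float64)
    w = _weights_array(w)
    w = np.broadcast_to(w, ps.shape) if w.shape != ps.shape else w
    gs = np.broadcast_to(gs, ps.shape) if gs.shape != ps.shape else gs
    if ps.shape != gs.shape:
        raise ValueError(f"shape mismatch: Ps {ps.shape} vs Gs {gs.shape}")
    wt = Tensor(w)
    inter = (wt * ps * Tensor(gs)).sum()
    union = (wt * (ps + Tensor(gs) - ps * Tensor(gs))).sum()
    if abs(union.item()) < 1e-12:
        warnings.warn("weighted IoU: empty ground truth and prediction; "
                      "loss defined as 0")
        return Tensor(0.0)
    return 1.0 - inter / union


def seg_loss(ps, gs, w, epsilon: float = 1e-7) -> Tensor:
    """Joint segmentation loss: (weighted BCE + weighted IoU) / 2."""
    return (weighted_bce(ps, gs, w, epsilon) + weighted_iou(ps, gs, w)) * 0.5


def edge_loss(edge_prob, ge, epsilon: float = 1e-7) -> Tensor:
    """Mean BCE between the predicted edge map and the edge ground truth."""
    ge = np.asarray(ge, dtype=np.float64)
    return weighted_bce(edge_prob, ge, np.ones_like(ge), epsilon)


def _downsample_mask(gs: np.ndarray, hw: tuple[int, int]) -> np.ndarray:
    if gs.shape[-2:] == tuple(hw):
        return gs
    out = sk_resize(gs.astype(np.float64), gs.shape[:-2] + tuple(hw), order=0,
                    anti_aliasing=False)
    return (out > 0.5).astype(np.uint8)


def total_loss(pred: PredictionSet, gs: np.ndarray,
               cfg: LossConfig | None = None) -> tuple[Tensor, dict[str, float]]:
    """Hybrid loss L_total = L_edge + L_segω (+ deep supervision on fg).

    `gs` is the binary ground-truth mask at input resolution, shaped (H,W)
    or (N,H,W).  Returns the scalar loss tensor and a per-term breakdown.
    """
    cfg = cfg or LossConfig()
    gs = np.asarray(gs)
    if gs.ndim == 2:
        gs = gs[None]
    gs4 = gs[:, None].astype(np.float64)  # (N,1,H,W)

    w = edge_weights(gs4, cfg).W
    l_seg = seg_loss(pred.seg_prob, gs4, w, cfg.epsilon)

    he, we = pred.edge_prob.shape[-2:]
    gs_small = np.stack([_downsample_mask(g, (he, we)) for g in gs])
    ge = np.stack([edge_gt(g) for g in gs_small])[:, None]
    l_edge = edge_loss(pred.edge_prob, ge, cfg.epsilon)

    total = l_edge + l_seg
    breakdown = {"edge": l_edge.item(), "seg": l_seg.item()}
    if cfg.deep_supervision:
        h, w_in = gs.shape[-2:]
        ps_coarse = F.bilinear_resize(pred.coarse_logits, (h, w_in)).sigmoid()
        l_deep = seg_loss(ps_coarse, gs4, w, cfg.epsilon)
        total = total + l_deep
        breakdown["deep"] = l_deep.item()
    breakdown["total"] = total.item()
    return total, breakdown
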