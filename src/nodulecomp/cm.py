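"""Complementary module: location fusion (LF), edge fusion (EF) and the
1-channel edge prediction head.

LF injects high-level location information into the edge feature:

    fE^ = Conv( fE ⊕ Up( f4′ ⊗ σ(Up(Conv(Convs(f5′)) → f4′)) → fE ) )

i.e. the deepest refined feature f5′ is resized and passed through a small
convolution stack, squashed by a sigmoid and used as a multiplicative gate
on f4′; the gated location map is upsampled to fE's resolution and added
point-by-point to the edge feature, then mixed by a final convolution.

EF refines the coarse nodule map with the final edge guidance:

    Ps_raw = fE^ ⊕ Up(Conv(Convs(fg)) → fE^)

and Ps_raw is projected to one channel, bilinearly upsampled to the network
input resolution and passed through a sigmoid, giving the segmentation
probability map Ps in [0,1].  The addition happens in logit space
(pre-sigmoid).

"Convs" is two 3×3 conv+ReLU stages and "Conv" one 3×3 conv+ReLU; every
convolution is an injectable operator slot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import nn
from .nn import Tensor, as_tensor
from .nn import functional as F

SlotFactory = Callable[..., nn.Module]


@dataclass
class PredictionSet:
    """All network outputs for one forward pass."""

    seg_prob: Tensor        # Ps, 1×H×W in [0,1] at input resolution
    edge_prob: Tensor       # 1-channel edge probability at fE^'s resolution
    coarse_logits: Tensor   # fg, 1-channel logits at f3's resolution
    edge_guidance: Tensor   # fE^, C-channel edge guidance at stride 4


def _convs(name, cin, cout, rng) -> nn.Module:
    """'Convs': two 3×3 conv+ReLU stages."""
    return nn.Sequential(nn.ConvReLU(cin, cout, 3, rng=rng),
                         nn.ConvReLU(cout, cout, 3, rng=rng))


def _default_slot(name: str, cin: int, cout: int, rng) -> nn.Module:
    if name.startswith("convs"):
        return _convs(name, cin, cout, rng)
    if name == "proj":
        return nn.Conv2d(cin, cout, 1, rng=rng)
    return nn.ConvReLU(cin, cout, 3, rng=rng)


class LocationFusion(nn.Module):
    """LF block: gate f4′ by processed f5′, add the edge feature fE."""

    def __init__(self, channels: int = 32,
                 slot_factory: SlotFactory | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        make = slot_factory or _default_slot
        rng = rng if rng is not None else np.random.default_rng(0)
        self.convs5 = make("convs5", channels, channels, rng)
        self.conv5 = make("conv5", channels, channels, rng)
        self.out = make("out", channels, channels, rng)

    def forward(self, f4p, f5p, fE) -> Tensor:
        f4p, f5p, fE = as_tensor(f4p), as_tensor(f5p), as_tensor(fE)
        g = self.conv5(self.convs5(f5p))
        gate = F.bilinear_resize(g, f4p.shape[-2:]).sigmoid()
        if gate.shape[1] not in (1, f4p.shape[1]):
            raise ValueError("location gate channels incompatible with f4'")
        loc = f4p * gate
        fused = fE + F.bilinear_resize(loc, fE.shape[-2:])
        return self.out(fused)


class EdgeFusion(nn.Module):
    """EF block: refine coarse logits with the edge guidance, emit Ps."""

    def __init__(self, channels: int = 32,
                 slot_factory: SlotFactory | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        make = slot_factory or _default_slot
        rng = rng if rng is not None else np.random.default_rng(0)
        self.convs_g = make("convs_g", 1, channels, rng)
        self.conv_g = make("conv_g", channels, channels, rng)
        self.proj = make("proj", channels, 1, rng)

    def fuse(self, fg, fE_hat) -> Tensor:
        """Pre-sigmoid fusion: fE^ ⊕ Up(Conv(Convs(fg)) → fE^'s size)."""
        fg, fE_hat = as_tensor(fg), as_tensor(fE_hat)
        g = self.conv_g(self.convs_g(fg))
        up = F.bilinear_resize(g, fE_hat.shape[-2:])
        if up.shape[1] not in (1, fE_hat.shape[1]):
            raise ValueError("coarse-map channels incompatible with fE^")
        return fE_hat + up

    def forward(self, fg, fE_hat, out_hw: tuple[int, int]) -> Tensor:
        raw = self.fuse(fg, fE_hat)
        logits = F.bilinear_resize(self.proj(raw), out_hw)
        return logits.sigmoid()


class EdgeHead(nn.Module):
    """1×1 projection + sigmoid: edge probability at fE^'s resolution."""

    def __init__(self, channels: int = 32,
                 slot_factory: SlotFactory | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        make = slot_factory or _default_slot
        rng = rng if rng is not None else np.random.default_rng(0)
        self.proj = make("proj", channels, 1, rng)

    def forward(self, fE_hat) -> Tensor:
        return self.proj(as_tensor(fE_hat)).sigmoid()


def location_fusion(f4p, f5p, fE, block: LocationFusion | None = None) -> Tensor:
    block = block or LocationFusion(as_tensor(f4p).shape[1])
    return block(f4p, f5p, fE)


def edge_fusion(fg, fE_hat, out_hw: tuple[int, int] | None = None,
                block: EdgeFusion | None = None) -> Tensor:
    fE_hat = as_tensor(fE_hat)
    block = block or EdgeFusion(fE_hat.shape[1])
    return block(fg, fE_hat, out_hw or fE_hat.shape[-2:])


def edge_probability(fE_hat, head: EdgeHead | None = None) -> Tensor:
    fE_hat = as_tensor(fE_hat)
    head = head or EdgeHead(fE_hat.shape[1])
    return head(fE_hat)
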