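"""High-level feature decoder: MF (multi-receptive-field) refinement blocks
and the cross-scale weighted MD (multi-scale decoder) block.

The MF block refines one backbone level through four cascade branches
b0..b3.  Branch m applies a 1×1 channel-reduction, then (for m ≥ 1) a
factorized 1×(2m+1) / (2m+1)×1 pair followed by a 3×3 convolution with
dilation rate 2m+1, so the branch receptive fields are 1, 9, 15 and 21
input pixels.  The four branch outputs are concatenated (4×32 → 32 via a
3×3 convolution) and a 1×1-projected shortcut is added element-wise.

The MD block aggregates the three refined high-level features f3′, f4′, f5′
top-down: each shallower feature is multiplied element-wise with every
deeper feature (bilinearly upsampled and passed through a 3×3 conv + BN),
and the concatenation of the updated maps is reduced by two 3×3 and one 1×1
convolution into the coarse nodule logit map fg at f3's resolution.

Every convolution is an injectable "operator slot" so the block algebra can
be unit-tested with identity or averaging stubs independent of learned
weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import nn
from .nn import Tensor, as_tensor
from .nn import functional as F

N_BRANCHES = 4
MF_CHANNELS = 32

SlotFactory = Callable[..., nn.Module]


@dataclass
class RefinedFeature:
    """32-channel multi-receptive-field feature at one pyramid level."""

    values: Tensor
    level: int

    def __post_init__(self):
        if self.level not in (3, 4, 5):
            raise ValueError("level must be 3, 4 or 5")


@dataclass
class CoarseMap:
    """Single-channel coarse nodule logits at f3's resolution."""

    logits: Tensor


# ---------------------------------------------------------------------------
# receptive-field arithmetic


def branch_operator_chain(m: int) -> list[tuple[int, int, int, int]]:
    """Operator chain of cascade branch b_m as (kh, kw, dh, dw) tuples."""
    if not 0 <= m <= 3:
        raise ValueError(f"branch index m must be in 0..3, got {m}")
    if m == 0:
        return [(1, 1, 1, 1)]
    k = 2 * m + 1
    return [(1, 1, 1, 1), (1, k, 1, 1), (k, 1, 1, 1), (3, 3, k, k)]


def receptive_field_2d(chain: list[tuple[int, int, int, int]]) -> tuple[int, int]:
    """Effective receptive field of a stride-1 convolution chain.

    Each layer of kernel extent k and dilation d grows the field by (k−1)·d
    along its axis.
    """
    rf_h = rf_w = 1
    for kh, kw, dh, dw in chain:
        rf_h += (kh - 1) * dh
        rf_w += (kw - 1) * dw
    return rf_h, rf_w


def branch_receptive_field(m: int) -> int:
    """Receptive field (pixels) of MF branch b_m: 1, 9, 15, 21 for m=0..3."""
    rf_h, rf_w = receptive_field_2d(branch_operator_chain(m))
    assert rf_h == rf_w
    return rf_h


# ---------------------------------------------------------------------------
# blocks


def _default_mf_slot(name: str, cin: int, cout: int, kernel, dilation: int,
                     rng: np.random.Generator) -> nn.Module:
    if name == "shortcut":
        return nn.Sequential(
            nn.Conv2d(cin, cout, kernel, bias=False, rng=rng),
            nn.BatchNorm2d(cout),
        )
    return nn.ConvBNReLU(cin, cout, kernel, dilation=dilation, rng=rng)


class MFBlock(nn.Module):
    """Multi-receptive-field refinement of one high-level feature map."""

    def __init__(self, cin: int, cout: int = MF_CHANNELS,
                 slot_factory: SlotFactory | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        make = slot_factory or _default_mf_slot
        rng = rng if rng is not None else np.random.default_rng(0)
        for m in range(N_BRANCHES):
            setattr(self, f"b{m}_reduce", make(f"b{m}_reduce", cin, cout, 1, 1, rng))
            if m >= 1:
                k = 2 * m + 1
                setattr(self, f"b{m}_h", make(f"b{m}_h", cout, cout, (1, k), 1, rng))
                setattr(self, f"b{m}_v", make(f"b{m}_v", cout, cout, (k, 1), 1, rng))
                setattr(self, f"b{m}_dil", make(f"b{m}_dil", cout, cout, 3, k, rng))
        self.reduce = make("reduce", N_BRANCHES * cout, cout, 3, 1, rng)
        self.shortcut = make("shortcut", cin, cout, 1, 1, rng)

    def forward(self, f) -> Tensor:
        f = as_tensor(f)
        branches = []
        for m in range(N_BRANCHES):
            y = getattr(self, f"b{m}_reduce")(f)
            if m >= 1:
                y = getattr(self, f"b{m}_h")(y)
                y = getattr(self, f"b{m}_v")(y)
                y = getattr(self, f"b{m}_dil")(y)
            branches.append(y)
        out = self.reduce(nn.concat(branches, axis=1))
        return (out + self.shortcut(f)).relu()


def _default_md_slot(name: str, cin: int, cout: int, kernel, dilation: int,
                     rng: np.random.Generator) -> nn.Module:
    if name.startswith("conv_"):
        # cross-scale weighting conv: 3x3 with BN, no activation, to keep
        # the multiplicative gating signed
        return nn.Sequential(
            nn.Conv2d(cin, cout, kernel, padding=1, bias=False, rng=rng),
            nn.BatchNorm2d(cout),
        )
    if name == "head_out":
        return nn.Conv2d(cin, cout, 1, rng=rng)
    return nn.ConvBNReLU(cin, cout, kernel, rng=rng)


class MDBlock(nn.Module):
    """Cross-scale weighted aggregation of f3′, f4′, f5′ into coarse logits."""

    def __init__(self, channels: int = MF_CHANNELS,
                 slot_factory: SlotFactory | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        make = slot_factory or _default_md_slot
        rng = rng if rng is not None else np.random.default_rng(0)
        c = channels
        self.conv_45 = make("conv_45", c, c, 3, 1, rng)  # Up(f5'->f4') weighting
        self.conv_34 = make("conv_34", c, c, 3, 1, rng)  # Up(f4'->f3') weighting
        self.conv_35 = make("conv_35", c, c, 3, 1, rng)  # Up(f5'->f3') weighting
        self.head1 = make("head1", 3 * c, c, 3, 1, rng)
        self.head2 = make("head2", c, c, 3, 1, rng)
        self.head_out = make("head_out", c, 1, 1, 1, rng)

    def forward(self, f3p, f4p, f5p) -> Tensor:
        f3p, f4p, f5p = as_tensor(f3p), as_tensor(f4p), as_tensor(f5p)
        if not (f3p.shape[1] == f4p.shape[1] == f5p.shape[1]):
            raise ValueError("refined features must share one channel count")
        hw3, hw4 = f3p.shape[-2:], f4p.shape[-2:]
        # deepest level is the fixpoint: f5'' = f5'
        f4pp = f4p * self.conv_45(F.bilinear_resize(f5p, hw4))
        f3pp = (f3p * self.conv_34(F.bilinear_resize(f4p, hw3))
                * self.conv_35(F.bilinear_resize(f5p, hw3)))
        cat = nn.concat([f3pp,
                         F.bilinear_resize(f4pp, hw3),
                         F.bilinear_resize(f5p, hw3)], axis=1)
        return self.head_out(self.head2(self.head1(cat)))


def mf_block(f, cin: int | None = None, **kwargs) -> Tensor:
    """Functional form of :class:`MFBlock` (builds a block, runs it once)."""
    f = as_tensor(f)
    return MFBlock(cin if cin is not None else f.shape[1], **kwargs)(f)


def md_block(f3p: RefinedFeature, f4p: RefinedFeature, f5p: RefinedFeature,
             block: MDBlock | None = None) -> CoarseMap:
    """Aggregate refined levels {3,4,5}; returns the coarse map at f3's size."""
    levels = (f3p.level, f4p.level, f5p.level)
    if levels != (3, 4, 5):
        raise ValueError(f"md_block expects levels (3,4,5), got {levels}")
    block = block or MDBlock(channels=f3p.values.shape[1])
    return CoarseMap(block(f3p.values, f4p.values, f5p.values))
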