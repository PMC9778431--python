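"""Low-level feature decoder: the LE (low-level edge) block.

Fuses the two edge-rich shallow backbone features f1 (stride 2) and f2
(stride 4) into an initial edge feature map

    fE = f2 ⊕ (f1 ⊗ f2)

where ⊕ (element-wise sum) emphasizes complementary features and ⊗
(element-wise product) enhances features the two levels share.  fE lives at
f2's resolution (stride 4): f1 is average-pooled down rather than f2
upsampled, keeping the map at a moderate, memory-friendly resolution.  Each
input passes through a 1×1 projection and a 3×3 filter slot before fusion;
all convolutions are injectable operator slots for stub-based testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import nn
from .nn import Tensor, as_tensor
from .nn import functional as F

EDGE_CHANNELS = 32  # matches the refined high-level features, so the
                    # complementary module needs no extra projections


@dataclass
class EdgeFeature:
    """Initial edge feature map at f2's resolution (stride 4)."""

    values: Tensor
    stride: int = 4


def _default_slot(name: str, cin: int, cout: int, kernel, rng) -> nn.Module:
    return nn.ConvReLU(cin, cout, kernel, rng=rng)


class LEBlock(nn.Module):
    def __init__(self, c1: int, c2: int, cout: int = EDGE_CHANNELS,
                 slot_factory: Callable[..., nn.Module] | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        make = slot_factory or _default_slot
        rng = rng if rng is not None else np.random.default_rng(0)
        self.proj1 = make("proj1", c1, cout, 1, rng)
        self.filt1 = make("filt1", cout, cout, 3, rng)
        self.proj2 = make("proj2", c2, cout, 1, rng)
        self.filt2 = make("filt2", cout, cout, 3, rng)
        self.out = make("out", cout, cout, 3, rng)

    def forward(self, f1, f2) -> Tensor:
        f1, f2 = as_tensor(f1), as_tensor(f2)
        h1, w1 = f1.shape[-2:]
        h2, w2 = f2.shape[-2:]
        if (h1, w1) != (h2, w2):
            if h1 % h2 or w1 % w2:
                raise ValueError(f"f1 size {h1}x{w1} not an integer multiple "
                                 f"of f2 size {h2}x{w2}")
            f1 = F.avg_pool2d(f1, (h1 // h2, w1 // w2))
        a = self.filt1(self.proj1(f1))
        b = self.filt2(self.proj2(f2))
        if a.shape != b.shape:
            raise ValueError(f"shape mismatch after alignment: {a.shape} vs {b.shape}")
        return self.out(b + a * b)


def le_block(f1, f2, block: LEBlock | None = None) -> EdgeFeature:
    """Functional wrapper returning an :class:`EdgeFeature`."""
    f1, f2 = as_tensor(f1), as_tensor(f2)
    block = block or LEBlock(f1.shape[1], f2.shape[1])
    return EdgeFeature(block(f1, f2))
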