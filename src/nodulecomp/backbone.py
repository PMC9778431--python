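"""Modified Res2Net50-style five-level feature extractor.

Compared with a stock classification Res2Net50, the stem's 7×7 convolution
is replaced by three consecutive 3×3 convolution(+BN)+ReLU stages (the first
with stride 2), and the global pooling / fully connected head is removed —
the network is a pure feature pyramid with five taps:

==== ======================== ======
tap  source                   stride
==== ======================== ======
f1   stem output                 2
f2   stage 1 (3 bottlenecks)     4
f3   stage 2 (4 bottlenecks)     8
f4   stage 3 (6 bottlenecks)    16
f5   stage 4 (3 bottlenecks)    32
==== ======================== ======

f1/f2 are the low-level (edge-rich) features; f3–f5 the high-level semantic
ones.  A width multiplier scales every channel count so unit tests can run a
tiny backbone; externally supplied pretrained weights can be loaded through
an optional hook (random He initialization is the default).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .nn import functional as F

STRIDES = (2, 4, 8, 16, 32)
_SCALE = 4  # Res2Net split width


@dataclass
class PyramidFeatures:
    """Backbone feature maps f1..f5 with their strides w.r.t. the input."""

    f1: Tensor
    f2: Tensor
    f3: Tensor
    f4: Tensor
    f5: Tensor
    strides: tuple[int, ...] = STRIDES

    def __iter__(self):
        return iter((self.f1, self.f2, self.f3, self.f4, self.f5))


class Bottle2neck(nn.Module):
    """Res2Net bottleneck: 1×1 reduce, hierarchical 3×3 group convs, 1×1 expand."""

    def __init__(self, cin: int, planes: int, cout: int, stride: int = 1,
                 *, rng: np.random.Generator):
        super().__init__()
        assert planes % _SCALE == 0
        gw = planes // _SCALE
        self.gw = gw
        self.stride = stride
        self.reduce = nn.ConvBNReLU(cin, planes, 1, rng=rng)
        self.branches = nn.Sequential(*[
            nn.ConvBNReLU(gw, gw, 3, stride=stride, rng=rng)
            for _ in range(_SCALE - 1)
        ])
        self.expand = nn.Sequential(
            nn.Conv2d(planes, cout, 1, bias=False, rng=rng),
            nn.BatchNorm2d(cout),
        )
        if stride != 1 or cin != cout:
            self.shortcut = nn.Sequential(
                nn.Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng),
                nn.BatchNorm2d(cout),
            )
        else:
            self.shortcut = nn.Identity()

    def forward(self, x: Tensor) -> Tensor:
        y = self.reduce(x)
        n, c, h, w = y.shape
        groups = [Tensor._make(
            np.ascontiguousarray(y.data[:, i * self.gw:(i + 1) * self.gw]),
            (y,), _slice_bwd(y, i * self.gw, (i + 1) * self.gw))
            for i in range(_SCALE)]
        outs = []
        prev = None
        for i in range(1, _SCALE):
            conv = self.branches[i - 1]
            xi = groups[i]
            if self.stride == 1 and prev is not None:
                xi = xi + prev
            prev = conv(xi)
            outs.append(prev)
        g0 = groups[0]
        if self.stride != 1:
            # 3x3/stride/pad-1 pooling keeps this branch aligned with the
            # padded 3x3 stride convs on odd input sizes
            g0 = F.avg_pool2d(g0, 3, self.stride, 1)
        outs.insert(0, g0)
        out = self.expand(nn.concat(outs, axis=1))
        return (out + self.shortcut(x)).relu()


def _slice_bwd(parent: Tensor, a: int, b: int):
    def bwd(out: Tensor) -> None:
        g = np.zeros_like(parent.data)
        g[:, a:b] = out.grad
        parent._accumulate(g)
    return bwd


class Res2NetBackbone(nn.Module):
    def __init__(self, width: float = 1.0, blocks: tuple[int, ...] = (3, 4, 6, 3),
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.width = width
        self.blocks = tuple(blocks)

        def c(base: int) -> int:
            return max(_SCALE, int(round(base * width / _SCALE)) * _SCALE)

        # stem: three consecutive 3x3 conv(+BN)+ReLU, first with stride 2
        self.stem = nn.Sequential(
            nn.ConvBNReLU(1, c(32), 3, stride=2, rng=rng),
            nn.ConvBNReLU(c(32), c(32), 3, rng=rng),
            nn.ConvBNReLU(c(32), c(64), 3, rng=rng),
        )
        self.pool = nn.MaxPool2d(3, 2, 1)

        def stage(cin, planes, cout, n, stride):
            layers = [Bottle2neck(cin, planes, cout, stride, rng=rng)]
            layers += [Bottle2neck(cout, planes, cout, 1, rng=rng)
                       for _ in range(n - 1)]
            return nn.Sequential(*layers)

        self.stage1 = stage(c(64), c(64), c(256), blocks[0], 1)
        self.stage2 = stage(c(256), c(128), c(512), blocks[1], 2)
        self.stage3 = stage(c(512), c(256), c(1024), blocks[2], 2)
        self.stage4 = stage(c(1024), c(512), c(2048), blocks[3], 2)
        #: per-tap channel counts, low to high level
        self.channels = (c(64), c(256), c(512), c(1024), c(2048))

    def forward(self, x: Tensor) -> PyramidFeatures:
        f1 = self.stem(x)
        f2 = self.stage1(self.pool(f1))
        f3 = self.stage2(f2)
        f4 = self.stage3(f3)
        f5 = self.stage4(f4)
        return PyramidFeatures(f1, f2, f3, f4, f5)

    @property
    def feature_taps(self) -> int:
        return 5


def build_backbone(config: dict | None = None) -> Res2NetBackbone:
    """Build the feature extractor from a config dict.

    Keys (all optional): ``width`` (channel multiplier, default 1.0),
    ``blocks`` (bottlenecks per stage), ``seed`` (init seed),
    ``pretrained_path`` (npz state dict; an absent file is a hard error,
    never a silent fallback to random weights).
    """
    cfg = config or {}
    net = Res2NetBackbone(width=float(cfg.get("width", 1.0)),
                          blocks=tuple(cfg.get("blocks", (3, 4, 6, 3))),
                          seed=int(cfg.get("seed", 0)))
    path = cfg.get("pretrained_path")
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"pretrained weights requested but absent: {p}")
        with np.load(p) as z:
            net.load_state_dict({k: z[k] for k in z.files})
    return net


def extract_features(backbone: Res2NetBackbone, image) -> PyramidFeatures:
    """Run the backbone on a 1×H×W (or N×1×H×W) image in [0,1].

    H and W must be divisible by the deepest stride (32) so every level's
    spatial size is exactly H/stride.
    """
    arr = image.data if isinstance(image, Tensor) else np.asarray(image)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[None]
    h, w = arr.shape[-2:]
    if h % STRIDES[-1] or w % STRIDES[-1]:
        raise ValueError(f"input size {h}x{w} must be divisible by {STRIDES[-1]}")
    return backbone(image if isinstance(image, Tensor) else Tensor(arr))
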