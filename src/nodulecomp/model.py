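"""The assembled features-complementary segmentation network.

Backbone taps f1..f5; MF blocks refine f3..f5 to 32 channels; the MD block
aggregates them into the coarse map fg; the LE block fuses f1/f2 into the
initial edge feature fE; location fusion injects f4′/f5′ into fE giving the
edge guidance fE^; edge fusion refines fg with fE^ into the segmentation
probability map Ps at input resolution; a 1×1 head on fE^ yields the edge
probability used for edge supervision.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .backbone import Res2NetBackbone
from .cm import EdgeFusion, EdgeHead, LocationFusion, PredictionSet
from .hdm import MDBlock, MFBlock, MF_CHANNELS, _default_md_slot, _default_mf_slot
from .ldm import LEBlock
from .nn import Tensor, as_tensor

CHECKPOINT_FORMAT = 1


class NoduleCompNet(nn.Module):
    """End-to-end network: image (N,1,H,W) in [0,1] → PredictionSet."""

    def __init__(self, width: float = 1.0, blocks: tuple[int, ...] = (3, 4, 6, 3),
                 seed: int = 0):
        super().__init__()
        self.width, self.block_config, self.seed = width, tuple(blocks), seed
        rng = np.random.default_rng(seed + 1)
        self.backbone = Res2NetBackbone(width=width, blocks=blocks, seed=seed)
        c1, c2, c3, c4, c5 = self.backbone.channels
        mf = lambda cin: MFBlock(cin, MF_CHANNELS, _default_mf_slot, rng=rng)
        self.mf3, self.mf4, self.mf5 = mf(c3), mf(c4), mf(c5)
        self.md = MDBlock(MF_CHANNELS, _default_md_slot, rng=rng)
        self.le = LEBlock(c1, c2, MF_CHANNELS, rng=rng)
        self.lf = LocationFusion(MF_CHANNELS, rng=rng)
        self.ef = EdgeFusion(MF_CHANNELS, rng=rng)
        self.edge_head = EdgeHead(MF_CHANNELS, rng=rng)

    def forward(self, x) -> PredictionSet:
        x = as_tensor(x)
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        h, w = x.shape[-2:]
        feats = self.backbone(x)
        f3p = self.mf3(feats.f3)
        f4p = self.mf4(feats.f4)
        f5p = self.mf5(feats.f5)
        fg = self.md(f3p, f4p, f5p)
        fE = self.le(feats.f1, feats.f2)
        fE_hat = self.lf(f4p, f5p, fE)
        ps = self.ef(fg, fE_hat, (h, w))
        edge_prob = self.edge_head(fE_hat)
        return PredictionSet(ps, edge_prob, fg, fE_hat)

    # -- checkpointing --------------------------------------------------------

    def save_checkpoint(self, path) -> None:
        import json
        meta = json.dumps({"format": CHECKPOINT_FORMAT, "width": self.width,
                           "blocks": list(self.block_config), "seed": self.seed})
        np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.state_dict())

    @classmethod
    def load_checkpoint(cls, path) -> "NoduleCompNet":
        import json
        with np.load(path) as z:
            if "_meta" not in z.files:
                raise ValueError(f"not a model checkpoint: {path}")
            meta = json.loads(bytes(z["_meta"]).decode())
            if meta.get("format") != CHECKPOINT_FORMAT:
                raise ValueError(
                    f"incompatible checkpoint format {meta.get('format')} "
                    f"(expected {CHECKPOINT_FORMAT})")
            net = cls(width=meta["width"], blocks=tuple(meta["blocks"]),
                      seed=meta["seed"])
            net.load_state_dict({k: z[k] for k in z.files if k != "_meta"})
        return net
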