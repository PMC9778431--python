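import numpy as np
import pytest

from nodulecomp import nn


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def identity_slots(*args, **kwargs) -> nn.Identity:
    """Slot factory stubbing every convolution to the identity operator."""
    return nn.Identity()


class ChannelSum(nn.Module):
    """Stub head: sums across channels (no gradient support needed)."""

    def forward(self, x):
        return nn.Tensor(x.data.sum(axis=1, keepdims=True))


class MeanKernel(nn.Module):
    """Stub conv: channel mean + 3x3 reflective spatial average, zero bias.

    Mean-preserving: a constant input c maps to a constant output c.
    """

    def forward(self, x):
        from scipy.ndimage import uniform_filter
        a = x.data.mean(axis=1, keepdims=True)
        out = uniform_filter(a, size=(1, 1, 3, 3), mode="reflect")
        return nn.Tensor(out)


def mean_kernel_slots(*args, **kwargs) -> MeanKernel:
    return MeanKernel()


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small synthetic dataset shared by engine/pipeline tests."""
    from nodulecomp.synthdata import build_dataset

    out = tmp_path_factory.mktemp("dataset")
    manifest = build_dataset({"n_patients": 10, "nodules_per_patient": 1,
                              "crops_per_nodule": 5, "seed": 7}, out)
    return out, manifest
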