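"""Multidimensional collaborative attention (MCA).

The block models attention independently along the channel, width and height
axes of a feature map.  Each branch:

1. *squeeze* — pools the map along the two complementary axes with average
   and standard-deviation pooling, fused by a learnable convex weight pair
   (a softmax over two logits, so the convex-combination property is
   structural).  Max pooling is computed as well and can join the fusion
   behind a config flag, in which case the softmax runs over three logits.
2. *excitation* — a shared 1-D convolution of odd width ``k`` slides over
   the pooled descriptor (replacing an MLP bottleneck), followed by a
   sigmoid, yielding per-position weights strictly inside (0, 1).

The three sigmoid-normalised branch maps are broadcast to the input shape,
averaged (suppressing single-branch noise), and multiplied elementwise with
the input.  Output shape always equals input shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import (Module, Parameter, Tensor, concat, exp, sigmoid,
                        tensor)

__all__ = ["MCAConfig", "MCA", "squeeze_stats", "excitation",
           "adaptive_kernel_size", "mca_forward"]

_BRANCH_AXES = {"channel": (2, 3), "height": (1, 3), "width": (1, 2)}


def adaptive_kernel_size(channels: int) -> int:
    """Odd excitation width from the descriptor length: nearest odd integer
    to log2(C)/2 + 1/2, floored at 3."""
    t = abs(np.log2(max(channels, 1))) / 2.0 + 0.5
    k = int(2 * round((t - 1) / 2) + 1)
    return max(k, 3)


@dataclass(frozen=True)
class MCAConfig:
    """kernel_size: odd int or "adaptive"; use_max_pool adds the max-pool
    statistic as a third fusion term."""

    kernel_size: int | str = "adaptive"
    use_max_pool: bool = False

    def __post_init__(self):
        if isinstance(self.kernel_size, int):
            if self.kernel_size < 1 or self.kernel_size % 2 == 0:
                raise ValueError("kernel_size must be odd and >= 1")
        elif self.kernel_size != "adaptive":
            raise ValueError("kernel_size must be an odd int or 'adaptive'")


def _pool_stats(x: Tensor, axes: tuple[int, int]):
    avg = x.mean(axis=axes)
    std = x.std(axis=axes)
    mx = Tensor(x.data.max(axis=axes))  # max joins fusion without gradient
    return avg, std, mx


def squeeze_stats(x, branch: str, fusion) -> Tensor:
    """Fused pooled descriptor along one branch axis.

    x : (N, C, H, W) array or tensor.  branch in {channel, height, width}.
    fusion : sequence of 2 (or 3, with max pooling) convex weights.
    Returns a (N, L) tensor, L = C, H or W respectively.
    """
    if branch not in _BRANCH_AXES:
        raise ValueError(f"unknown branch {branch!r}")
    x = tensor(x)
    if x.ndim != 4:
        raise ValueError("expected a (N, C, H, W) feature map")
    w = np.asarray([float(f) for f in fusion])
    avg, std, mx = _pool_stats(x, _BRANCH_AXES[branch])
    out = avg * w[0] + std * w[1]
    if len(w) > 2:
        out = out + mx * w[2]
    return out


def excitation(descriptor, kernel) -> Tensor:
    """1-D local convolution over the descriptor, then sigmoid.

    descriptor : (N, L) or (L,) array/tensor; kernel : odd-width 1-D weights.
    Output has the same length as the input, values strictly in (0, 1).
    """
    kernel = tensor(kernel)
    k = kernel.shape[0]
    if k % 2 == 0:
        raise ValueError("excitation kernel width must be odd")
    d = tensor(descriptor)
    squeeze_back = d.ndim == 1
    if squeeze_back:
        d = d.reshape(1, d.shape[0])
    n, length = d.shape
    pad = k // 2
    if pad:
        z = Tensor(np.zeros((n, pad)))
        d = concat([z, d, z], axis=1)
    x4 = d.reshape(n, 1, 1, length + 2 * pad)
    w4 = kernel.reshape(1, 1, 1, k)
    from ._autograd import conv2d
    out = conv2d(x4, w4).reshape(n, length)
    out = sigmoid(out)
    return out.reshape(length) if squeeze_back else out


class MCA(Module):
    """The attention block; ``channels`` fixes the channel-branch length."""

    def __init__(self, channels: int, cfg: MCAConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg = cfg or MCAConfig()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        k = (adaptive_kernel_size(channels) if cfg.kernel_size == "adaptive"
             else cfg.kernel_size)
        self.k = k
        n_fuse = 3 if cfg.use_max_pool else 2
        # per-branch, unshared: fusion logits (softmaxed to convex weights)
        # and excitation kernels
        self.branches = list(_BRANCH_AXES)
        base = rng.normal(0.0, 1.0 / np.sqrt(k), k)
        for b in self.branches:
            setattr(self, f"fuse_{b}", Parameter(np.zeros(n_fuse)))
            kern = (rng.normal(0.0, 1.0 / np.sqrt(k), k)
                    if b == "channel" else base.copy())
            # height/width kernels start identical (branches are mirror
            # images of each other); they decouple during training
            setattr(self, f"kernel_{b}", Parameter(kern))

    def fusion_weights(self, branch: str) -> np.ndarray:
        logits = getattr(self, f"fuse_{branch}")
        e = np.exp(logits.data - logits.data.max())
        return e / e.sum()

    def _fusion_tensor(self, branch: str) -> Tensor:
        logits = getattr(self, f"fuse_{branch}")
        shift = logits - float(logits.data.max())
        e = exp(shift)
        return e / e.sum()

    def forward(self, x) -> Tensor:
        x = tensor(x)
        squeeze_back = x.ndim == 3
        if squeeze_back:
            x = x.reshape(1, *x.shape)
        n, c, h, w = x.shape
        maps = []
        for branch in self.branches:
            fw = self._fusion_tensor(branch)
            avg, std, mx = _pool_stats(x, _BRANCH_AXES[branch])
            desc = avg * fw[0] + std * fw[1]
            if self.cfg.use_max_pool:
                desc = desc + mx * fw[2]
            att = excitation(desc, getattr(self, f"kernel_{branch}"))
            if branch == "channel":
                att = att.reshape(n, c, 1, 1)
            elif branch == "height":
                att = att.reshape(n, 1, h, 1)
            else:
                att = att.reshape(n, 1, 1, w)
            maps.append(att)
        att = (maps[0] + maps[1] + maps[2]) * (1.0 / 3.0)
        out = x * att
        return out.reshape(c, h, w) if squeeze_back else out


def mca_forward(x, mca: MCA) -> np.ndarray:
    """Functional wrapper: run the block and return a plain array."""
    out = mca(x)
    return out.data if isinstance(out, Tensor) else np.asarray(out)
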