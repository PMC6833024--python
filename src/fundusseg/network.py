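"""The multi-scale multi-kernel U-shaped segmentation network (MSMKU).

The contracting path consumes a four-level image pyramid.  Each pyramid
level gets a small convolutional stem; stem outputs are fused additively
in a hierarchical chain of multi-kernel residual modules, each followed
by a strided convolution that halves the spatial size (no pooling layers
anywhere).  With input side W the fused chain is

    F3(F2(F1(f1(X1) + f2(X2)) + f3(X3)) + f4(X4))

whose output — the bottleneck — has side W/16.  The expanding path
mirrors the four halvings with (linear up-sampling, convolution) stages
and additive skip connections from the pre-strided module outputs, and a
final 1x1 convolution + sigmoid yields a full-resolution probability map.

Channel width doubles at every halving, starting from ``base_width`` at
full resolution.  The stem of the full-resolution level ends in a strided
convolution so that its output matches the second pyramid level, which is
what makes the printed fusion sizes work out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn

__all__ = ["NetworkConfig", "build_image_pyramid", "MultiKernelModule", "MSMKU", "build_msmku"]

PYRAMID_LEVELS = 4


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters.

    input_side
        Square input resolution; must be divisible by 16 so the
        bottleneck side input_side/16 is integral.  384 is the working
        resolution for optic-disc segmentation and 256 for optic-cup
        segmentation; tests use much smaller sides.
    base_width
        Channel count at full resolution; doubled at every halving.
    """

    input_side: int
    base_width: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.input_side % 16 != 0 or self.input_side < 16:
            raise ValueError("input_side must be a positive multiple of 16")
        if self.base_width < 2:
            raise ValueError("base_width must be >= 2")


def _halve(x: np.ndarray) -> np.ndarray:
    """Area (2x2 block mean) downsampling of an (N, H, W, C) batch."""
    n, h, w, c = x.shape
    return x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))


def build_image_pyramid(image: np.ndarray):
    """Four-level pyramid of an RGB image: sides (W, W/2, W/4, W/8).

    Accepts an (H, W, 3) image; H and W must be divisible by 8.  Level 1
    is the input unchanged; deeper levels are area-resized copies.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    h, w = img.shape[:2]
    if h % 8 != 0 or w % 8 != 0:
        raise ValueError("image sides must be divisible by 8")
    x = img.astype(np.float64)[None]
    levels = [x]
    for _ in range(PYRAMID_LEVELS - 1):
        levels.append(_halve(levels[-1]))
    return [lev[0] for lev in levels]


class MultiKernelModule:
    """Residual multi-kernel block.

    Four parallel branches — three 3x3 convolutions and one branch of two
    successive 4x4 convolutions — are concatenated along channels, mixed
    by a 1x1 convolution (ReLU, batch norm), and corrected by an additive
    short connection from the module input (1x1-projected when the widths
    differ).  Spatial size is preserved; even 4x4 kernels pad
    asymmetrically (1 left/top, 2 right/bottom).
    """

    def __init__(self, name, in_ch, out_ch, rng, dtype=np.float32):
        # branch width: the architecture fixes kernel sizes, not channel
        # counts; half the module width keeps the stacked features at
        # twice the module width before the 1x1 mix
        bc = max(out_ch // 2, 2)
        self.b3 = [nn.Conv2d(f"{name}.b3_{i}", in_ch, bc, 3, rng, dtype=dtype) for i in range(3)]
        self.b3_relu = [nn.ReLU() for _ in range(3)]
        self.b4a = nn.Conv2d(f"{name}.b4a", in_ch, bc, 4, rng, dtype=dtype)
        self.b4a_relu = nn.ReLU()
        self.b4b = nn.Conv2d(f"{name}.b4b", bc, bc, 4, rng, dtype=dtype)
        self.b4b_relu = nn.ReLU()
        self.mix = nn.Conv2d(f"{name}.mix", 4 * bc, out_ch, 1, rng, dtype=dtype)
        self.mix_relu = nn.ReLU()
        self.bn = nn.BatchNorm2d(f"{name}.bn", out_ch, dtype=dtype)
        self.proj = None if in_ch == out_ch else nn.Conv2d(f"{name}.proj", in_ch, out_ch, 1, rng, dtype=dtype)
        self.in_ch = in_ch
        self.branch_ch = bc

    def params(self):
        ps = []
        for c in self.b3:
            ps += c.params()
        ps += self.b4a.params() + self.b4b.params() + self.mix.params() + self.bn.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x, train):
        branches = [r.forward(c.forward(x)) for c, r in zip(self.b3, self.b3_relu)]
        b4 = self.b4b_relu.forward(self.b4b.forward(self.b4a_relu.forward(self.b4a.forward(x))))
        branches.append(b4)
        cat = np.concatenate(branches, axis=3)
        z = self.bn.forward(self.mix_relu.forward(self.mix.forward(cat)), train)
        shortcut = x if self.proj is None else self.proj.forward(x)
        return z + shortcut

    def backward(self, dy):
        dx = dy if self.proj is None else self.proj.backward(dy)
        dcat = self.mix.backward(self.mix_relu.backward(self.bn.backward(dy)))
        c = self.branch_ch
        dx = dx.copy()
        for i, (conv, relu) in enumerate(zip(self.b3, self.b3_relu)):
            dx += conv.backward(relu.backward(dcat[..., i * c : (i + 1) * c]))
        d4 = self.b4a.backward(self.b4a_relu.backward(self.b4b.backward(self.b4b_relu.backward(dcat[..., 3 * c :]))))
        dx += d4
        return dx


class MSMKU:
    """U-shaped segmentation network: image batch in, probability map out.

    ``forward_batch``/``backward_batch`` operate on (N, side, side, 3)
    float arrays scaled to [0, 1]; ``predict`` wraps a single (H, W, 3)
    image in evaluation mode (batch-norm running statistics, so inference
    is deterministic).
    """

    def __init__(self, config: NetworkConfig, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        self.skips_enabled = True  # diagnostic switch; skips are part of the architecture
        bw = config.base_width
        rng = np.random.default_rng(config.seed)
        mk = lambda *a, **k: MultiKernelModule(*a, rng=rng, dtype=dtype, **k)
        cb = lambda name, i, o, k=3, s=1: nn.ConvBlock(name, i, o, k, rng, stride=s, dtype=dtype)
        # contracting stems (one per pyramid level)
        self.f1 = cb("f1", 3, bw)
        self.f1_stride = cb("f1s", bw, 2 * bw, 3, 2)
        self.f2 = cb("f2", 3, 2 * bw)
        self.f3 = cb("f3", 3, 4 * bw)
        self.f4 = cb("f4", 3, 8 * bw)
        # multi-kernel modules + strided halvings
        self.mk1 = mk("mk1", 2 * bw, 2 * bw)
        self.mk1_stride = cb("mk1s", 2 * bw, 4 * bw, 3, 2)
        self.mk2 = mk("mk2", 4 * bw, 4 * bw)
        self.mk2_stride = cb("mk2s", 4 * bw, 8 * bw, 3, 2)
        self.mk3 = mk("mk3", 8 * bw, 8 * bw)
        self.mk3_stride = cb("mk3s", 8 * bw, 16 * bw, 3, 2)
        # expanding path: upsample -> conv, with additive skips
        self.up = [nn.BilinearUp2(dtype=dtype) for _ in range(4)]
        self.dec3 = cb("dec3", 16 * bw, 8 * bw)
        self.dec2 = cb("dec2", 8 * bw, 4 * bw)
        self.dec1 = cb("dec1", 4 * bw, 2 * bw)
        self.dec0 = cb("dec0", 2 * bw, bw)
        self.head = nn.Conv2d("head", bw, 1, 1, rng, dtype=dtype)
        self._blocks = [
            self.f1, self.f1_stride, self.f2, self.f3, self.f4,
            self.mk1, self.mk1_stride, self.mk2, self.mk2_stride,
            self.mk3, self.mk3_stride,
            self.dec3, self.dec2, self.dec1, self.dec0, self.head,
        ]

    # -- parameters -------------------------------------------------------
    def params(self):
        ps = []
        for b in self._blocks:
            ps += b.params()
        return ps

    def zero_grad(self):
        for p in self.params():
            p.zero_grad()

    # -- forward / backward ----------------------------------------------
    def _pyramid(self, x):
        levels = [x]
        for _ in range(PYRAMID_LEVELS - 1):
            levels.append(_halve(levels[-1]))
        return levels

    def forward_batch(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[3] != 3:
            raise ValueError("expected an (N, H, W, 3) batch")
        if x.shape[1] != self.config.input_side or x.shape[2] != self.config.input_side:
            raise ValueError(
                f"input side {x.shape[1:3]} does not match configured {self.config.input_side}"
            )
        x = x.astype(self.dtype, copy=False)
        x1, x2, x3, x4 = self._pyramid(x)
        sk = 1.0 if self.skips_enabled else 0.0
        a0 = self.f1.forward(x1, train)
        s1 = self.f1_stride.forward(a0, train) + self.f2.forward(x2, train)
        m1 = self.mk1.forward(s1, train)
        s2 = self.mk1_stride.forward(m1, train) + self.f3.forward(x3, train)
        m2 = self.mk2.forward(s2, train)
        s3 = self.mk2_stride.forward(m2, train) + self.f4.forward(x4, train)
        m3 = self.mk3.forward(s3, train)
        bott = self.mk3_stride.forward(m3, train)
        self.last_bottleneck_shape = bott.shape[1:3]
        e3 = self.dec3.forward(self.up[3].forward(bott), train) + sk * m3
        e2 = self.dec2.forward(self.up[2].forward(e3), train) + sk * m2
        e1 = self.dec1.forward(self.up[1].forward(e2), train) + sk * m1
        e0 = self.dec0.forward(self.up[0].forward(e1), train) + sk * a0
        logits = self.head.forward(e0)
        p = nn.sigmoid(logits)
        self._p = p
        self._sk = sk
        return p

    def backward_batch(self, dp: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the probability map."""
        p = self._p
        self._p = None
        dlogits = (dp * p * (1.0 - p)).astype(self.dtype, copy=False)
        sk = self._sk
        de0 = self.head.backward(dlogits)
        da0 = sk * de0
        de1 = self.up[0].backward(self.dec0.backward(de0))
        dm1 = sk * de1
        de2 = self.up[1].backward(self.dec1.backward(de1))
        dm2 = sk * de2
        de3 = self.up[2].backward(self.dec2.backward(de2))
        dm3 = sk * de3
        dbott = self.up[3].backward(self.dec3.backward(de3))
        dm3 = dm3 + self.mk3_stride.backward(dbott)
        ds3 = self.mk3.backward(dm3)
        self.f4.backward(ds3)
        dm2 = dm2 + self.mk2_stride.backward(ds3)
        ds2 = self.mk2.backward(dm2)
        self.f3.backward(ds2)
        dm1 = dm1 + self.mk1_stride.backward(ds2)
        ds1 = self.mk1.backward(dm1)
        self.f2.backward(ds1)
        da0 = da0 + self.f1_stride.backward(ds1)
        self.f1.backward(da0)

    # -- inference --------------------------------------------------------
    def predict(self, image: np.ndarray) -> np.ndarray:
        """Probability map for one (H, W, 3) image (evaluation mode)."""
        img = np.asarray(image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError("expected an (H, W, 3) RGB image")
        x = prepare_image(img)[None]
        return self.forward_batch(x, train=False)[0, :, :, 0].astype(np.float64)

    # -- serialization ----------------------------------------------------
    def state_arrays(self):
        arrays = {p.name: p.value for p in self.params()}
        for blk_name in ("f1", "f1_stride", "f2", "f3", "f4", "mk1_stride", "mk2_stride", "mk3_stride", "dec3", "dec2", "dec1", "dec0"):
            bn = getattr(self, blk_name).bn
            arrays[f"{blk_name}.running_mean"] = bn.running_mean
            arrays[f"{blk_name}.running_var"] = bn.running_var
        for mk_name in ("mk1", "mk2", "mk3"):
            bn = getattr(self, mk_name).bn
            arrays[f"{mk_name}.running_mean"] = bn.running_mean
            arrays[f"{mk_name}.running_var"] = bn.running_var
        return arrays

    def save(self, path) -> None:
        np.savez(path, __config__=json.dumps(asdict(self.config)), **self.state_arrays())

    @classmethod
    def load(cls, path) -> "MSMKU":
        data = np.load(path, allow_pickle=False)
        cfg = NetworkConfig(**json.loads(str(data["__config__"])))
        net = cls(cfg)
        by_name = {p.name: p for p in net.params()}
        for key in data.files:
            if key == "__config__":
                continue
            if key in by_name:
                by_name[key].value = data[key].astype(net.dtype)
                by_name[key].grad = np.zeros_like(by_name[key].value)
            elif key.endswith(".running_mean") or key.endswith(".running_var"):
                blk, attr = key.rsplit(".", 1)
                setattr(getattr(net, blk).bn, attr, data[key].astype(net.dtype))
        return net


def prepare_image(image: np.ndarray, dtype=np.float32) -> np.ndarray:
    """(H, W, 3) image -> float array scaled to [0, 1] (NHWC layout)."""
    img = np.asarray(image)
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(dtype) / 255.0
    return np.ascontiguousarray(img.astype(dtype, copy=False))


def build_msmku(config: NetworkConfig, dtype=np.float32) -> MSMKU:
    """Construct an MSMKU with seeded parameter initialisation."""
    return MSMKU(config, dtype=dtype)
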