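"""GA-MS-UNet++: a gated, multi-scale, SCSE-attended nested U-Net.

The architecture is a UNet++-style grid of nodes ``X[i][j]`` (``i`` the
resolution level, ``j`` the column).  Column 0 is the encoder: one
multi-scale block (MSBlock) per level with 2x2 max pooling in between.
Every later node is a *gated skip*: a learned per-channel convex blend of
the previous node at the same level with a 1x1-projected, bilinearly
upsampled copy of the node one level below,

    GatedSkip(x_skip, x_up) = sigma(alpha) * x_skip + (1 - sigma(alpha)) * Conv1x1(x_up).

Nodes on the final anti-diagonal (the decoder column) additionally apply
an MSBlock; the segmentation head is a 1x1 convolution plus sigmoid on
``X[0][depth-1]``.  Keeping the intermediate lattice nodes convolution
free is what lets the model spend its parameters at the coarse levels
while costing fewer forward FLOPs than a plain nested U-Net — the
published efficiency profile of this architecture.

Each MSBlock is two residual convolution units (3x3 conv, the second
dilated by 2, group norm, leaky ReLU, additive shortcut) followed by
concurrent spatial & channel squeeze-and-excitation (SCSE) attention.

A reference plain nested U-Net (:class:`NestedUNet`) with standard
two-conv nodes and concatenation skips is included for parameter-count
triangulation and comparative statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .nn import autodiff as ad


@dataclass(frozen=True)
class NetworkConfig:
    """Every architecture hyperparameter left open by the prose, pinned.

    The defaults are the frozen full-scale configuration whose parameter
    and FLOP accounting is checked against the published efficiency
    table; reduced variants (e.g. depth 3, widths (8, 16, 32)) are used
    for desk-scale training.
    """

    in_channels: int = 1
    out_channels: int = 1
    depth: int = 5
    widths: tuple[int, ...] = (32, 64, 128, 256, 512)
    gn_groups: int = 8
    leaky_slope: float = 0.01
    scse_reduction: int = 4
    dilation_second_conv: int = 2
    gate_init: float = 0.0
    msblocks_per_node: int = 1

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if len(self.widths) != self.depth:
            raise ValueError("widths must list one channel count per level")
        if any(a >= b for a, b in zip(self.widths, self.widths[1:])):
            raise ValueError("widths must be strictly increasing down the encoder")
        if self.scse_reduction < 1:
            raise ValueError("scse_reduction must be >= 1")
        if self.dilation_second_conv < 1:
            raise ValueError("dilation must be >= 1")
        if self.msblocks_per_node < 1:
            raise ValueError("msblocks_per_node must be >= 1")


def _groups_for(channels: int, gn_groups: int) -> int:
    g = min(gn_groups, channels)
    while channels % g:
        g -= 1
    return g


class ResidualConvUnit(nn.Module):
    """Two 3x3 convolutions (second dilated), GN, leaky ReLU, additive shortcut."""

    def __init__(self, cin: int, cout: int, dilation: int = 2, gn_groups: int = 8,
                 leaky_slope: float = 0.01, rng: np.random.Generator | None = None):
        g = _groups_for(cout, gn_groups)
        self.conv1 = nn.Conv2d(cin, cout, 3, padding=1, rng=rng, leaky_slope=leaky_slope)
        self.gn1 = nn.GroupNorm(g, cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, padding=dilation, dilation=dilation,
                               rng=rng, leaky_slope=leaky_slope)
        self.gn2 = nn.GroupNorm(g, cout)
        self.proj = nn.Conv2d(cin, cout, 1, rng=rng) if cin != cout else nn.Identity()
        self.slope = leaky_slope

    def forward(self, x: Tensor) -> Tensor:
        h = ad.leaky_relu(self.gn1(self.conv1(x)), self.slope)
        h = self.gn2(self.conv2(h))
        return ad.leaky_relu(ad.add(h, self.proj(x)), self.slope)


class ChannelSqueezeExcite(nn.Module):
    """cSE: global average pooling, bottleneck 1x1 convs, sigmoid channel gates."""

    def __init__(self, channels: int, reduction: int = 4, rng: np.random.Generator | None = None):
        hidden = max(1, channels // reduction)
        self.fc1 = nn.Conv2d(channels, hidden, 1, rng=rng)
        self.fc2 = nn.Conv2d(hidden, channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        s = ad.global_avg_pool(x)
        gate = ad.sigmoid(self.fc2(ad.relu(self.fc1(s))))
        return ad.mul(x, gate)


class SpatialSqueezeExcite(nn.Module):
    """sSE: single 1x1-conv spatial attention map in (0,1) applied to all channels."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        self.fc = nn.Conv2d(channels, 1, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return ad.mul(x, ad.sigmoid(self.fc(x)))


class SCSEBlock(nn.Module):
    """Concurrent spatial and channel squeeze-excitation: cSE(x) + sSE(x)."""

    def __init__(self, channels: int, reduction: int = 4, rng: np.random.Generator | None = None):
        self.cse = ChannelSqueezeExcite(channels, reduction, rng=rng)
        self.sse = SpatialSqueezeExcite(channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return ad.add(self.cse(x), self.sse(x))


class MSBlock(nn.Module):
    """Multi-scale block: two residual convolution units then SCSE attention."""

    def __init__(self, cin: int, cout: int, config: NetworkConfig,
                 rng: np.random.Generator | None = None):
        kw = dict(dilation=config.dilation_second_conv, gn_groups=config.gn_groups,
                  leaky_slope=config.leaky_slope, rng=rng)
        self.rcu1 = ResidualConvUnit(cin, cout, **kw)
        self.rcu2 = ResidualConvUnit(cout, cout, **kw)
        self.scse = SCSEBlock(cout, config.scse_reduction, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.scse(self.rcu2(self.rcu1(x)))


class GatedSkip(nn.Module):
    """Per-channel convex blend of a skip tensor with a projected decoder tensor.

    ``x_up`` may arrive at the same spatial size as ``x_skip`` or at half
    size, in which case it is bilinearly upsampled after the 1x1 channel
    projection (projecting first keeps the projection at the cheaper
    resolution).
    """

    def __init__(self, skip_channels: int, up_channels: int, gate_init: float = 0.0,
                 rng: np.random.Generator | None = None):
        self.alpha = nn.Parameter(np.full(skip_channels, gate_init, dtype=np.float32))
        self.proj = nn.Conv2d(up_channels, skip_channels, 1, rng=rng)

    def forward(self, x_skip: Tensor, x_up: Tensor) -> Tensor:
        hs, ws = x_skip.data.shape[2:]
        hu, wu = x_up.data.shape[2:]
        p = self.proj(x_up)
        if (hu, wu) == (hs, ws):
            pass
        elif (2 * hu, 2 * wu) == (hs, ws):
            p = ad.upsample_bilinear2x(p)
        else:
            raise ValueError(
                f"gated skip spatial mismatch: skip {hs}x{ws} vs up {hu}x{wu}"
            )
        g = ad.sigmoid(self.alpha_4d())
        # per-channel convex combination
        one_minus = ad.add(Tensor(np.float32(1.0)), ad.mul(g, Tensor(np.float32(-1.0))))
        return ad.add(ad.mul(g, x_skip), ad.mul(one_minus, p))

    def alpha_4d(self) -> Tensor:
        c = self.alpha.data.size
        y = self.alpha.data.reshape(1, c, 1, 1)
        out = Tensor(y)
        alpha = self.alpha

        def bwd(grad):
            alpha._accumulate(grad.sum(axis=(0, 2, 3)))

        out._parents = (alpha,)
        out._backward = bwd
        out.requires_grad = True
        return out


class GAMSUNetPP(nn.Module):
    """The full gated multi-scale nested U-Net."""

    def __init__(self, config: NetworkConfig | None = None, seed: int = 0):
        config = config or NetworkConfig()
        rng = np.random.default_rng(seed)
        w = config.widths
        d = config.depth
        self.config = config

        def node(cin, cout):
            blocks = [MSBlock(cin, cout, config, rng=rng)]
            for _ in range(config.msblocks_per_node - 1):
                blocks.append(MSBlock(cout, cout, config, rng=rng))
            return blocks

        self.encoder = []
        for i in range(d):
            cin = config.in_channels if i == 0 else w[i - 1]
            self.encoder.append(node(cin, w[i]))
        # gates[j-1][i] handles node X[i][j]
        self.gates = []
        for j in range(1, d):
            self.gates.append([
                GatedSkip(w[i], w[i + 1], config.gate_init, rng=rng)
                for i in range(d - j)
            ])
        # decoder column: MSBlock at each final node X[i][d-1-i], i = d-2 .. 0
        self.decoder = [node(w[i], w[i]) for i in range(d - 1)]
        self.head = nn.Conv2d(w[0], config.out_channels, 1, rng=rng)

    # -- forward ---------------------------------------------------------

    def _check_input(self, x: np.ndarray | Tensor) -> Tensor:
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        if t.ndim == 2:
            t = Tensor(t.data[None, None], requires_grad=t.requires_grad)
        elif t.ndim == 3:
            t = Tensor(t.data[None], requires_grad=t.requires_grad)
        if t.ndim != 4 or t.data.shape[1] != self.config.in_channels:
            raise ValueError(f"expected (N,{self.config.in_channels},H,W) input, got {t.data.shape}")
        h, w = t.data.shape[2:]
        div = 1 << (self.config.depth - 1)
        if h % div or w % div:
            raise ValueError(f"spatial dims {h}x{w} must be divisible by {div}")
        return t

    def forward_logits(self, x: np.ndarray | Tensor) -> Tensor:
        t = self._check_input(x)
        d = self.config.depth
        # encoder column
        col0: list[Tensor] = []
        cur = t
        for i in range(d):
            if i > 0:
                cur = ad.max_pool2x2(cur)
            for block in self.encoder[i]:
                cur = block(cur)
            col0.append(cur)
        grid = {(i, 0): col0[i] for i in range(d)}
        for j in range(1, d):
            for i in range(d - j):
                g = self.gates[j - 1][i](grid[(i, j - 1)], grid[(i + 1, j - 1)])
                if i + j == d - 1:
                    for block in self.decoder[i]:
                        g = block(g)
                grid[(i, j)] = g
        return self.head(grid[(0, d - 1)])

    def forward(self, x: np.ndarray | Tensor) -> Tensor:
        """Probability map in (0,1); thresholding is the caller's business."""
        return ad.sigmoid(self.forward_logits(x))

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Inference on a single 2D slice; returns an (H, W) probability map."""
        out = self.forward(np.asarray(image, dtype=np.float32))
        return out.data[0, 0]


class _VGGBlock(nn.Module):
    """conv3x3-BN-ReLU twice; the node type of the reference nested U-Net."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(cin, cout, 3, padding=1, rng=rng)
        self.bn1 = nn.BatchNorm2dEval(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, padding=1, rng=rng)
        self.bn2 = nn.BatchNorm2dEval(cout)

    def forward(self, x: Tensor) -> Tensor:
        h = ad.relu(self.bn1(self.conv1(x)))
        return ad.relu(self.bn2(self.conv2(h)))


class NestedUNet(nn.Module):
    """Plain UNet++ with dense concatenation skips and bilinear upsampling.

    Used as the parameter-count anchor and as a comparison baseline; node
    ``X[i][j]`` receives the concatenation of all same-level predecessors
    plus the upsampled node below, exactly the standard topology.
    """

    def __init__(self, in_channels: int = 1, out_channels: int = 1,
                 widths: tuple[int, ...] = (32, 64, 128, 256, 512), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.widths = widths
        self.in_channels = in_channels
        d = self.depth = len(widths)
        self.blocks: list[list[_VGGBlock]] = []
        for j in range(d):
            col = []
            for i in range(d - j):
                if j == 0:
                    cin = in_channels if i == 0 else widths[i - 1]
                else:
                    cin = widths[i] * j + widths[i + 1]
                col.append(_VGGBlock(cin, widths[i], rng))
            self.blocks.append(col)
        self.head = nn.Conv2d(widths[0], out_channels, 1, rng=rng)

    def forward_logits(self, x: np.ndarray | Tensor) -> Tensor:
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        if t.ndim == 2:
            t = Tensor(t.data[None, None])
        d = self.depth
        h, w = t.data.shape[2:]
        if h % (1 << (d - 1)) or w % (1 << (d - 1)):
            raise ValueError(f"spatial dims {h}x{w} must be divisible by {1 << (d - 1)}")
        grid: dict[tuple[int, int], Tensor] = {}
        cur = t
        for i in range(d):
            if i > 0:
                cur = ad.max_pool2x2(cur)
            cur = self.blocks[0][i](cur)
            grid[(i, 0)] = cur
        for j in range(1, d):
            for i in range(d - j):
                parts = [grid[(i, k)] for k in range(j)]
                parts.append(ad.upsample_bilinear2x(grid[(i + 1, j - 1)]))
                grid[(i, j)] = self.blocks[j][i](ad.concat_channels(parts))
        return self.head(grid[(0, d - 1)])

    def forward(self, x) -> Tensor:
        return ad.sigmoid(self.forward_logits(x))


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def rcu_forward(x, rcu: ResidualConvUnit) -> np.ndarray:
    """Apply a residual convolution unit to an (C,H,W) or (N,C,H,W) array."""
    return _apply(rcu, x)


def cse(x, block: ChannelSqueezeExcite) -> np.ndarray:
    return _apply(block, x)


def sse(x, block: SpatialSqueezeExcite) -> np.ndarray:
    return _apply(block, x)


def scse(x, block: SCSEBlock) -> np.ndarray:
    return _apply(block, x)


def msblock_forward(x, block: MSBlock) -> np.ndarray:
    return _apply(block, x)


def gated_skip(x_skip, x_up, gate: GatedSkip) -> np.ndarray:
    xs = _to4d(x_skip)
    xu = _to4d(x_up)
    y = gate(Tensor(xs), Tensor(xu)).data
    return y[0] if np.asarray(x_skip).ndim == 3 else y


def _to4d(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    return a[None] if a.ndim == 3 else a


def _apply(module: nn.Module, x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    y = module(Tensor(_to4d(a))).data
    return y[0] if a.ndim == 3 else y


def build_network(config: NetworkConfig | None = None, seed: int = 0) -> GAMSUNetPP:
    return GAMSUNetPP(config, seed=seed)


def forward(network: GAMSUNetPP, image: np.ndarray) -> np.ndarray:
    """Slice inference: (H, W) image -> (H, W) probability map in (0,1)."""
    return network.predict(image)


def count_parameters(network: nn.Module) -> int:
    """Exact count of trainable scalars, gate vectors included."""
    return int(sum(p.data.size for p in network.parameters()))


def count_flops(network, input_shape: tuple[int, int, int] = (1, 256, 256),
                convention: str = "mac") -> float:
    """Analytic forward-pass cost at a fixed input shape.

    Metered on the executed graph: convolutions count one unit per MAC,
    normalization/activation/pooling/interpolation one unit per output
    element ("mac" convention; pass ``convention="flop"`` for 2 units per
    MAC).  Returns raw operation count; divide by 1e9 for the tabulated
    units.
    """
    c, h, w = input_shape
    x = np.zeros((1, c, h, w), dtype=np.float32)
    meter = nn.FlopMeter()
    with nn.count_flops_in(meter):
        network.forward_logits(x)
    return meter.total(convention)
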