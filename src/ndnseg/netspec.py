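"""Declarative network construction and dilation-scheme analysis.

The segmentation network is a 3-D encoder-decoder with three max-pooling
levels.  The first two encoder levels use residual blocks nested with
dilations (RnD): three serial dilated convolutions (default rates 1, 2, 5,
kernel 3) wrapped in a residual connection, which expands the receptive
field of the shallow layers without pooling while hybrid-dilated-convolution
(HDC) rate selection avoids the gridding effect.  Every level is followed
by a squeeze-and-excitation (SE) channel-attention block.  Filter widths
double at each encoder level and halve at each decoder level.

Two analytic tools accompany the builders: :func:`validate_hdc` checks the
HDC rate conditions via the max-distance recurrence

    M_i = max(M_{i+1} - 2 r_i,  2 r_i - M_{i+1},  r_i),    M_n = r_n,

and :func:`gridding_coverage` is a brute-force oracle that enumerates the
1-D tap offsets actually reached by the stacked dilated kernels; a scheme
is hole-free iff the covered offsets form a contiguous integer interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np

from .nn import (
    BatchNorm,
    Conv3d,
    Dense,
    GlobalAvgPool,
    MaxPool2,
    Module,
    Param,
    ReLU,
    Sequential,
    Sigmoid,
    UpsampleNearest2,
    count_parameters,
)

__all__ = [
    "DilationScheme",
    "HdcReport",
    "NetworkSpec",
    "validate_hdc",
    "gridding_coverage",
    "receptive_field",
    "build_residual_block",
    "build_se_block",
    "build_rnd_block",
    "build_ndn",
    "count_parameters",
    "ResidualBlock",
    "SEBlock",
    "RnDBlock",
    "NDN",
]


@dataclass(frozen=True)
class DilationScheme:
    """Ordered dilation rates for the serial convolutions of an RnD block."""

    rates: tuple[int, ...] = (1, 2, 5)
    kernel: int = 3

    def __post_init__(self) -> None:
        if len(self.rates) == 0:
            raise ValueError("dilation scheme needs at least one rate")
        if any(r < 1 for r in self.rates):
            raise ValueError(f"dilation rates must be >= 1, got {self.rates}")
        if self.kernel < 3 or self.kernel % 2 == 0:
            raise ValueError(f"kernel must be odd and >= 3, got {self.kernel}")


@dataclass(frozen=True)
class HdcReport:
    """Outcome of the HDC rate check for one scheme."""

    rates: tuple[int, ...]
    kernel: int
    max_distances: tuple[int, ...]
    coprime_ok: bool
    distance_ok: bool

    @property
    def valid(self) -> bool:
        return self.coprime_ok and self.distance_ok


def validate_hdc(scheme: DilationScheme) -> HdcReport:
    """Check the two HDC conditions for a dilation scheme.

    Condition 1 (coprimality): no pair of rates may share a divisor > 1
    (pairs involving rate 1 trivially pass).  Condition 2 (coverage):
    the max-distance recurrence evaluated backward from ``M_n = r_n``
    must satisfy ``M_i < K`` for every ``i < n``.  ``M_n`` itself equals
    ``r_n`` by definition and is not compared against ``K``: doing so would
    reject the canonical (1, 2, 5) scheme.
    """
    rates, K = scheme.rates, scheme.kernel
    n = len(rates)
    m = [0] * n
    m[-1] = rates[-1]
    for i in range(n - 2, -1, -1):
        m_next = m[i + 1]
        m[i] = max(m_next - 2 * rates[i], 2 * rates[i] - m_next, rates[i])
    coprime_ok = all(math.gcd(a, b) == 1 for a, b in combinations(rates, 2))
    if n == 1:
        # the recurrence has nothing to check for a lone layer, but a single
        # dilated convolution with r > 1 always leaves holes
        distance_ok = rates[0] == 1
    else:
        distance_ok = all(m[i] < K for i in range(n - 1))
    return HdcReport(
        rates=tuple(rates),
        kernel=K,
        max_distances=tuple(m),
        coprime_ok=coprime_ok,
        distance_ok=distance_ok,
    )


def gridding_coverage(scheme: DilationScheme) -> set[int]:
    """Brute-force 1-D tap coverage of the stacked dilated kernels.

    Each dilated convolution reaches offsets ``{-r(K-1)/2, ..., +r(K-1)/2}``
    in steps of ``r``; stacking composes tap sets by Minkowski sum.  The
    returned set is the offsets of input positions that influence the
    central output position.
    """
    half = (scheme.kernel - 1) // 2
    covered = {0}
    for r in scheme.rates:
        taps = range(-half * r, half * r + 1, r)
        covered = {c + t for c in covered for t in taps}
    return covered


def is_hole_free(scheme: DilationScheme) -> bool:
    """True iff the brute-force coverage is a contiguous integer interval."""
    cov = gridding_coverage(scheme)
    return cov == set(range(min(cov), max(cov) + 1))


def receptive_field(stack: list[tuple[int, int, int]]) -> int:
    """Analytic receptive field of a stack of (kernel, dilation, stride) layers.

    ``RF = 1 + sum over layers of (K - 1) * r * (product of preceding strides)``.
    """
    rf = 1
    jump = 1
    for kernel, dilation, stride in stack:
        rf += (kernel - 1) * dilation * jump
        jump *= stride
    return rf


# ---------------------------------------------------------------------------
# blocks


class ResidualBlock(Module):
    """Two conv3-BN-ReLU layers with an additive shortcut.

    The shortcut is the identity when channel counts match, otherwise a
    1x1x1 projection convolution; the block preserves spatial shape.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None):
        rng = np.random.default_rng(rng)
        self.path = Sequential(
            Conv3d(c_in, c_out, kernel=3, rng=rng, name="res.conv1"),
            BatchNorm(c_out, name="res.bn1"),
            ReLU(),
            Conv3d(c_out, c_out, kernel=3, rng=rng, name="res.conv2"),
            BatchNorm(c_out, name="res.bn2"),
            ReLU(),
        )
        self.shortcut = (
            None if c_in == c_out else Conv3d(c_in, c_out, kernel=1, rng=rng, name="res.proj")
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        short = x if self.shortcut is None else self.shortcut.forward(x, train=train)
        return self.path.forward(x, train=train) + short

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g_path = self.path.backward(grad)
        g_short = grad if self.shortcut is None else self.shortcut.backward(grad)
        return g_path + g_short

    def parameters(self) -> list[Param]:
        params = self.path.parameters()
        if self.shortcut is not None:
            params += self.shortcut.parameters()
        return params


class SEBlock(Module):
    """Squeeze-and-excitation channel attention.

    Squeeze: global average pool to one value per channel.  Excitation: a
    C -> ceil(C/reduction) dense layer with ReLU, then back to C with a
    sigmoid.  The resulting per-channel weights are broadcast over space
    (conceptually reshaped to (1, 1, 1, C)) and multiplied onto the input.
    """

    def __init__(self, channels: int, reduction: int = 16, rng: np.random.Generator | None = None):
        if reduction < 1:
            raise ValueError("reduction must be >= 1")
        rng = np.random.default_rng(rng)
        hidden = max(1, math.ceil(channels / reduction))
        self.gap = GlobalAvgPool()
        self.fc1 = Dense(channels, hidden, rng=rng, name="se.fc1")
        self.relu = ReLU()
        self.fc2 = Dense(hidden, channels, rng=rng, name="se.fc2")
        self.sigmoid = Sigmoid()

    def channel_weights(self, x: np.ndarray) -> np.ndarray:
        """Inference-path per-channel attention weights, shape (B, C)."""
        s = self.gap.forward(x)
        return self.sigmoid.forward(self.fc2.forward(self.relu.forward(self.fc1.forward(s))))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        s = self.gap.forward(x, train=train)
        s = self.fc1.forward(s, train=train)
        s = self.relu.forward(s, train=train)
        s = self.fc2.forward(s, train=train)
        s = self.sigmoid.forward(s, train=train)
        if train:
            self._x, self._s = x, s
        return x * s[:, None, None, None, :]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g_s = (grad * self._x).sum(axis=(1, 2, 3))
        g_x = grad * self._s[:, None, None, None, :]
        g = self.sigmoid.backward(g_s)
        g = self.fc2.backward(g)
        g = self.relu.backward(g)
        g = self.fc1.backward(g)
        return g_x + self.gap.backward(g)

    def parameters(self) -> list[Param]:
        return self.fc1.parameters() + self.fc2.parameters()


class RnDBlock(Module):
    """Residual block nested with serial dilated convolutions.

    Three (by default) dilated convolutions with HDC-validated rates, each
    followed by BN then ReLU, wrapped in a residual connection (projection
    on channel mismatch).  Spatial shape is preserved by symmetric padding.
    Construction refuses schemes that fail the HDC check unless
    ``allow_invalid_scheme`` is set.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        scheme: DilationScheme = DilationScheme(),
        rng: np.random.Generator | None = None,
        allow_invalid_scheme: bool = False,
    ):
        report = validate_hdc(scheme)
        if not report.valid and not allow_invalid_scheme:
            raise ValueError(f"dilation scheme fails the HDC conditions: {report}")
        self.scheme = scheme
        rng = np.random.default_rng(rng)
        layers: list[Module] = []
        c_prev = c_in
        for j, rate in enumerate(scheme.rates):
            layers += [
                Conv3d(c_prev, c_out, kernel=scheme.kernel, dilation=rate, rng=rng,
                       name=f"rnd.conv{j + 1}"),
                BatchNorm(c_out, name=f"rnd.bn{j + 1}"),
                ReLU(),
            ]
            c_prev = c_out
        self.path = Sequential(*layers)
        self.shortcut = (
            None if c_in == c_out else Conv3d(c_in, c_out, kernel=1, rng=rng, name="rnd.proj")
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        short = x if self.shortcut is None else self.shortcut.forward(x, train=train)
        return self.path.forward(x, train=train) + short

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g_path = self.path.backward(grad)
        g_short = grad if self.shortcut is None else self.shortcut.backward(grad)
        return g_path + g_short

    def parameters(self) -> list[Param]:
        params = self.path.parameters()
        if self.shortcut is not None:
            params += self.shortcut.parameters()
        return params

    @property
    def receptive_span(self) -> int:
        return receptive_field([(self.scheme.kernel, r, 1) for r in self.scheme.rates])


def build_residual_block(
    c_in: int, c_out: int, rng: np.random.Generator | None = None
) -> ResidualBlock:
    return ResidualBlock(c_in, c_out, rng=rng)


def build_se_block(
    channels: int, reduction: int = 16, rng: np.random.Generator | None = None
) -> SEBlock:
    return SEBlock(channels, reduction=reduction, rng=rng)


def build_rnd_block(
    c_in: int,
    c_out: int,
    scheme: DilationScheme = DilationScheme(),
    rng: np.random.Generator | None = None,
    allow_invalid_scheme: bool = False,
) -> RnDBlock:
    return RnDBlock(c_in, c_out, scheme=scheme, rng=rng, allow_invalid_scheme=allow_invalid_scheme)


# ---------------------------------------------------------------------------
# full network


@dataclass
class NetworkSpec:
    """Declarative description of the segmentation network."""

    in_channels: int = 4
    classes: int = 4
    base_filters: int = 16
    depth: int = 3  # number of max-pooling levels
    rnd_levels: int = 2  # encoder levels using RnD blocks (the rest residual)
    scheme: DilationScheme = field(default_factory=DilationScheme)
    se_reduction: int = 16

    def __post_init__(self) -> None:
        if self.depth != 3:
            raise ValueError("the architecture is defined for depth 3")
        if self.base_filters < 1 or self.classes < 2 or self.in_channels < 1:
            raise ValueError("invalid channel configuration")

    @property
    def level_widths(self) -> tuple[int, ...]:
        return tuple(self.base_filters * 2**i for i in range(self.depth))

    @property
    def bottleneck_width(self) -> int:
        return self.base_filters * 2**self.depth


class NDN(Module):
    """Encoder-decoder segmentation network with RnD and SE blocks.

    Encoder levels 1-2: RnD block -> SE -> max pool.  Level 3: residual
    block -> SE -> max pool.  Bottleneck: residual -> SE.  Decoder levels:
    nearest-neighbor upsample + 1x1x1 channel-halving conv -> concatenation
    with the encoder skip -> residual block -> SE.  A final 1x1x1
    convolution maps to class logits; apply :func:`softmax` (or
    ``predict_proba``) for probabilities.  Filter widths double per encoder
    level and halve per decoder level.
    """

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator | None = None):
        rng = np.random.default_rng(rng)
        self.spec = spec
        widths = spec.level_widths
        self.enc_blocks: list[Module] = []
        c_prev = spec.in_channels
        for lvl in range(spec.depth):
            if lvl < spec.rnd_levels:
                self.enc_blocks.append(RnDBlock(c_prev, widths[lvl], scheme=spec.scheme, rng=rng))
            else:
                self.enc_blocks.append(ResidualBlock(c_prev, widths[lvl], rng=rng))
            c_prev = widths[lvl]
        self.enc_se = [SEBlock(w, spec.se_reduction, rng=rng) for w in widths]
        self.pools = [MaxPool2() for _ in range(spec.depth)]
        self.bottleneck = ResidualBlock(widths[-1], spec.bottleneck_width, rng=rng)
        self.bottleneck_se = SEBlock(spec.bottleneck_width, spec.se_reduction, rng=rng)

        self.upsamples = [UpsampleNearest2() for _ in range(spec.depth)]
        self.up_convs: list[Module] = []
        self.dec_blocks: list[Module] = []
        self.dec_se: list[Module] = []
        c_prev = spec.bottleneck_width
        for lvl in range(spec.depth - 1, -1, -1):
            self.up_convs.append(Conv3d(c_prev, widths[lvl], kernel=1, rng=rng, name="up.proj"))
            self.dec_blocks.append(ResidualBlock(2 * widths[lvl], widths[lvl], rng=rng))
            self.dec_se.append(SEBlock(widths[lvl], spec.se_reduction, rng=rng))
            c_prev = widths[lvl]
        self.head = Conv3d(spec.base_filters, spec.classes, kernel=1, rng=rng, name="head")

    def _check_shape(self, x: np.ndarray) -> None:
        factor = 2**self.spec.depth
        for ax, name in zip(range(1, 4), "xyz"):
            if x.shape[ax] % factor:
                raise ValueError(
                    f"axis {name} has extent {x.shape[ax]}, not divisible by {factor}"
                )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._check_shape(x)
        skips = []
        h = x
        for lvl in range(self.spec.depth):
            h = self.enc_blocks[lvl].forward(h, train=train)
            h = self.enc_se[lvl].forward(h, train=train)
            skips.append(h)
            h = self.pools[lvl].forward(h, train=train)
        h = self.bottleneck.forward(h, train=train)
        h = self.bottleneck_se.forward(h, train=train)
        for j, lvl in enumerate(range(self.spec.depth - 1, -1, -1)):
            h = self.upsamples[j].forward(h, train=train)
            h = self.up_convs[j].forward(h, train=train)
            h = np.concatenate([h, skips[lvl]], axis=-1)
            h = self.dec_blocks[j].forward(h, train=train)
            h = self.dec_se[j].forward(h, train=train)
        return self.head.forward(h, train=train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        widths = self.spec.level_widths
        g = self.head.backward(grad)
        skip_grads: dict[int, np.ndarray] = {}
        for j in range(self.spec.depth - 1, -1, -1):
            lvl = self.spec.depth - 1 - j
            g = self.dec_se[j].backward(g)
            g = self.dec_blocks[j].backward(g)
            w = widths[lvl]
            skip_grads[lvl] = g[..., w:]
            g = self.up_convs[j].backward(g[..., :w])
            g = self.upsamples[j].backward(g)
        g = self.bottleneck_se.backward(g)
        g = self.bottleneck.backward(g)
        for lvl in range(self.spec.depth - 1, -1, -1):
            g = self.pools[lvl].backward(g)
            g = g + skip_grads[lvl]
            g = self.enc_se[lvl].backward(g)
            g = self.enc_blocks[lvl].backward(g)
        return g

    def parameters(self) -> list[Param]:
        params: list[Param] = []
        for m in (
            self.enc_blocks
            + self.enc_se
            + [self.bottleneck, self.bottleneck_se]
            + self.up_convs
            + self.dec_blocks
            + self.dec_se
            + [self.head]
        ):
            params += m.parameters()
        return params

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Inference softmax probabilities for a single (X, Y, Z, C) grid."""
        logits = self(x)
        return softmax(logits)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def build_ndn(spec: NetworkSpec, rng: np.random.Generator | None = None) -> NDN:
    return NDN(spec, rng=rng)


def hdc_coverage_survey(max_rate: int = 6, kernel: int = 3) -> list[dict]:
    """Compare the HDC conditions with the brute-force coverage oracle.

    Enumerates every ordered rate triple with rates up to ``max_rate`` and
    records, per triple, the HDC verdict and whether coverage is hole-free.
    Used to characterise exactly where the printed conditions and the
    geometric ground truth agree.
    """
    rows = []
    for rates in product(range(1, max_rate + 1), repeat=3):
        scheme = DilationScheme(rates=rates, kernel=kernel)
        report = validate_hdc(scheme)
        rows.append(
            {
                "rates": rates,
                "valid": report.valid,
                "coprime_ok": report.coprime_ok,
                "distance_ok": report.distance_ok,
                "hole_free": is_hole_free(scheme),
            }
        )
    return rows
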