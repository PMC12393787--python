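"""Global encoder: linear state-space scans over 2D token sequences.

The core primitive is the discrete linear state-space recurrence

    h_t = A h_{t-1} + B x_t,      y_t = C h_t + D x_t,   h_0 = 0,

applied to a feature map flattened into token sequences.  Because a 1D scan
only sees one traversal order, the 2D operator (SS2D) flattens the map along
four orders — row-major, reversed row-major, column-major, reversed
column-major — scans each with its own parameters, restores each result to
2D in its own order and merges by element-wise sum.  Visual state-space (VSS)
blocks wrap the scan with pre-norm residual connections, channel expansion
with multiplicative gating, and a feed-forward sublayer; patch merging
(2x2 neighbourhood concat + linear reduction) halves resolution and doubles
channels between stages, giving a 4-stage global feature hierarchy at
strides 4/8/16/32.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .types import FeatureMap
from .mpsk import _wrap, _unwrap

SCAN_ORDERS = ("row", "row_rev", "col", "col_rev")


@dataclass
class SSMParams:
    """Time-invariant parameters of one linear state-space system."""

    A: np.ndarray  # (N, N) state transition
    B: np.ndarray  # (N, D_in) input map
    C: np.ndarray  # (D_out, N) readout
    D: np.ndarray  # (D_out, D_in) feed-through
    h0: np.ndarray | None = None  # (N,), defaults to zeros

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, dtype=np.float64))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=np.float64))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=np.float64))
        self.D = np.atleast_2d(np.asarray(self.D, dtype=np.float64))
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be square")
        if self.B.shape[0] != n or self.C.shape[1] != n:
            raise ValueError("B rows and C columns must match the state dim")
        if self.D.shape != (self.C.shape[0], self.B.shape[1]):
            raise ValueError("D must be (D_out, D_in)")
        for m in (self.A, self.B, self.C, self.D):
            if not np.all(np.isfinite(m)):
                raise ValueError("SSM parameters must be finite")
        if self.h0 is not None:
            self.h0 = np.asarray(self.h0, dtype=np.float64)
            if self.h0.shape != (n,):
                raise ValueError("h0 must have shape (N,)")

    @property
    def state_dim(self) -> int:
        return self.A.shape[0]

    @property
    def d_in(self) -> int:
        return self.B.shape[1]

    @property
    def d_out(self) -> int:
        return self.C.shape[0]


@dataclass
class TokenSequence:
    """A flattened feature map: (N_seq, D) tokens plus its 2D provenance."""

    tokens: np.ndarray
    origin_shape: tuple[int, int]
    scan_order: str = "row"

    def __post_init__(self):
        self.tokens = np.atleast_2d(np.asarray(self.tokens, dtype=np.float64))
        h, w = self.origin_shape
        if self.scan_order not in SCAN_ORDERS:
            raise ValueError(f"scan_order must be one of {SCAN_ORDERS}")
        if self.tokens.shape[0] != h * w:
            raise ValueError(
                f"token count {self.tokens.shape[0]} != H*W = {h * w}")


def ssm_scan(x: TokenSequence, p: SSMParams) -> TokenSequence:
    """Literal recurrence h_t = A h_{t-1} + B x_t ; y_t = C h_t + D x_t."""
    if x.tokens.shape[1] != p.d_in:
        raise ValueError(
            f"token dim {x.tokens.shape[1]} != SSM input dim {p.d_in}")
    y = nn.ssm_scan_op(Tensor(x.tokens), Tensor(p.A), Tensor(p.B),
                       Tensor(p.C), Tensor(p.D), h0=p.h0)
    return TokenSequence(np.asarray(y.data), x.origin_shape, x.scan_order)


# -- flatten / unflatten for the four scan orders ---------------------------

def _flatten_tokens(t: Tensor, order: str) -> Tensor:
    """(B, H, W, C) -> (B, H*W, C) along the given traversal order."""
    B, H, W, C = t.shape
    if order == "row":
        return t.reshape(B, H * W, C)
    if order == "row_rev":
        return t.reshape(B, H * W, C).flip(1)
    if order == "col":
        return t.transpose(0, 2, 1, 3).reshape(B, H * W, C)
    if order == "col_rev":
        return t.transpose(0, 2, 1, 3).reshape(B, H * W, C).flip(1)
    raise ValueError(f"unknown scan order {order!r}")


def _unflatten_tokens(t: Tensor, order: str, hw: tuple[int, int]) -> Tensor:
    """(B, H*W, C) -> (B, H, W, C), inverse of :func:`_flatten_tokens`."""
    H, W = hw
    B, _, C = t.shape
    if order == "row":
        return t.reshape(B, H, W, C)
    if order == "row_rev":
        return t.flip(1).reshape(B, H, W, C)
    if order == "col":
        return t.reshape(B, W, H, C).transpose(0, 2, 1, 3)
    if order == "col_rev":
        return t.flip(1).reshape(B, W, H, C).transpose(0, 2, 1, 3)
    raise ValueError(f"unknown scan order {order!r}")


def flatten_2d(f: FeatureMap, order: str) -> TokenSequence:
    """Flatten a (C, H, W) feature map into tokens along a scan order."""
    t = Tensor(f.values.transpose(1, 2, 0)[None])
    seq = _flatten_tokens(t, order)
    return TokenSequence(np.asarray(seq.data[0]), f.spatial, order)


def unflatten_2d(seq: TokenSequence, stride: int = 1) -> FeatureMap:
    t = Tensor(seq.tokens[None])
    m = _unflatten_tokens(t, seq.scan_order, seq.origin_shape)
    return FeatureMap(np.asarray(m.data[0]).transpose(2, 0, 1), stride=stride)


def ss2d(f: FeatureMap, params: dict[str, SSMParams]) -> FeatureMap:
    """Four-direction 2D scan: per-order scans restored to 2D, merged by sum."""
    missing = [o for o in SCAN_ORDERS if o not in params]
    if missing:
        raise ValueError(f"missing scan-order parameters: {missing}")
    out = np.zeros_like(f.values, dtype=np.float64)
    for order in SCAN_ORDERS:
        seq = flatten_2d(f, order)
        y = ssm_scan(seq, params[order])
        out = out + unflatten_2d(y, stride=f.stride).values
    return FeatureMap(out, stride=f.stride)


# -- learned modules --------------------------------------------------------

@dataclass
class VSSConfig:
    embed_dim: int = 96
    depths: tuple[int, int, int, int] = (2, 2, 2, 2)
    state_dim: int = 16
    expansion: float = 2.0
    norm_epsilon: float = 1e-5
    mlp_ratio: float = 2.0

    def __post_init__(self):
        if self.embed_dim % 2:
            raise ValueError("embed_dim must be even")
        if len(self.depths) != 4 or min(self.depths) < 1:
            raise ValueError("depths must be 4 values >= 1")


class PatchEmbed(nn.Module):
    """Map a 1-channel image slice to stride-4 embedded features."""

    def __init__(self, embed_dim: int, rng: np.random.Generator,
                 in_channels: int = 1, eps: float = 1e-5):
        super().__init__()
        self.proj = nn.Conv2d(in_channels, embed_dim, 4, rng, stride=4, padding=0)
        self.norm = nn.LayerNorm(embed_dim, eps=eps)

    def forward(self, x: Tensor) -> Tensor:
        H, W = x.shape[2], x.shape[3]
        if H % 4 or W % 4:
            raise ValueError(
                f"input spatial dims must be divisible by 4, got {H}x{W}")
        y = self.proj(x)                          # (B, C, H/4, W/4)
        t = y.transpose(0, 2, 3, 1)
        t = self.norm(t)
        return t.transpose(0, 3, 1, 2)


def patch_embed(image: np.ndarray, module: PatchEmbed) -> FeatureMap:
    """Embed a single 2D slice; returns a stride-4 FeatureMap."""
    x = np.asarray(image, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    out = module(Tensor(x[None]))
    return _unwrap(out, 4)


class SS2DLayer(nn.Module):
    """Gated four-direction scan mixer.

    in_proj expands C -> 2*Ci (scan path and gate); the scan path runs the
    grouped four-direction state-space scan (diagonal feed-through); the sum
    of the four restored maps is modulated by SiLU(gate) and projected back.
    """

    def __init__(self, channels: int, cfg: VSSConfig, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        ci = int(round(cfg.expansion * channels))
        n = cfg.state_dim
        self.ci, self.n = ci, n
        self.in_proj = nn.Linear(channels, 2 * ci, rng)
        eye = np.eye(n)[None].repeat(4, axis=0)
        self.register_parameter("A", 0.5 * eye + rng.normal(0, 0.05 / n, (4, n, n)))
        self.register_parameter("B", rng.normal(0, 1.0 / np.sqrt(ci), (4, n, ci)))
        self.register_parameter("C", rng.normal(0, 1.0 / np.sqrt(n), (4, ci, n)))
        self.register_parameter("D", np.ones((4, ci)))
        self.out_proj = nn.Linear(ci, channels, rng)

    def forward(self, t: Tensor) -> Tensor:
        # t: (B, H, W, C) tokens
        B, H, W, _ = t.shape
        xz = self.in_proj(t)
        x, gate = xz[:, :, :, :self.ci], xz[:, :, :, self.ci:]
        x = x.silu()
        seqs = [_flatten_tokens(x, o) for o in SCAN_ORDERS]
        stacked = nn.concat([s.reshape(1, B, H * W, self.ci) for s in seqs], axis=0)
        ys = nn.ssm_scan_grouped(stacked, self.A, self.B, self.C, self.D)
        merged = None
        for i, o in enumerate(SCAN_ORDERS):
            m = _unflatten_tokens(ys[i], o, (H, W))
            merged = m if merged is None else merged + m
        out = merged * gate.silu()
        return self.out_proj(out)


class VSSBlock(nn.Module):
    """Pre-norm residual unit: x + SS2D(LN(x)), then x + MLP(LN(x))."""

    def __init__(self, channels: int, cfg: VSSConfig, rng: np.random.Generator):
        super().__init__()
        self.norm1 = nn.LayerNorm(channels, eps=cfg.norm_epsilon)
        self.mixer = SS2DLayer(channels, cfg, rng)
        self.norm2 = nn.LayerNorm(channels, eps=cfg.norm_epsilon)
        hidden = int(round(cfg.mlp_ratio * channels))
        self.mlp_in = nn.Linear(channels, hidden, rng)
        self.mlp_out = nn.Linear(hidden, channels, rng)

    def forward(self, t: Tensor) -> Tensor:
        t = t + self.mixer(self.norm1(t))
        return t + self.mlp_out(self.mlp_in(self.norm2(t)).silu())


class PatchMerge(nn.Module):
    """2x2 neighbourhood concat + linear reduction: (H,W,C) -> (H/2,W/2,2C)."""

    def __init__(self, channels: int, rng: np.random.Generator, eps: float = 1e-5):
        super().__init__()
        self.norm = nn.LayerNorm(4 * channels, eps=eps)
        self.reduce = nn.Linear(4 * channels, 2 * channels, rng, bias=False)

    def forward(self, t: Tensor) -> Tensor:
        B, H, W, C = t.shape
        if H % 2 or W % 2:
            raise ValueError(f"patch merging needs even spatial dims, got {H}x{W}")
        quads = nn.concat([t[:, 0::2, 0::2], t[:, 1::2, 0::2],
                           t[:, 0::2, 1::2], t[:, 1::2, 1::2]], axis=3)
        return self.reduce(self.norm(quads))


class VSSEncoder(nn.Module):
    """Four stages of VSS blocks with patch merging between stages."""

    def __init__(self, cfg: VSSConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        stages, merges = [], []
        c = cfg.embed_dim
        for s, depth in enumerate(cfg.depths):
            stages.append(nn.Sequential(*[
                VSSBlock(c, cfg, rng) for _ in range(depth)]))
            if s < 3:
                merges.append(PatchMerge(c, rng, eps=cfg.norm_epsilon))
                c *= 2
        self.stages = nn.Sequential(*stages)
        self.merges = nn.Sequential(*merges)

    def forward(self, f0: Tensor) -> list[Tensor]:
        # f0: (B, C, H, W) at stride 4
        t = f0.transpose(0, 2, 3, 1)
        outs = []
        for s in range(4):
            t = self.stages.mods[s](t)
            outs.append(t.transpose(0, 3, 1, 2))
            if s < 3:
                t = self.merges.mods[s](t)
        return outs


def encoder_forward(f0: FeatureMap, module: VSSEncoder) -> list[FeatureMap]:
    """Run the global encoder on stride-4 features; returns 4 stage maps."""
    if f0.stride != 4:
        raise ValueError(f"encoder expects stride-4 input, got stride {f0.stride}")
    if f0.channels != module.cfg.embed_dim:
        raise ValueError(
            f"encoder expects {module.cfg.embed_dim} channels, got {f0.channels}")
    outs = module(_wrap(f0))
    return [_unwrap(o, 4 * 2 ** s) for s, o in enumerate(outs)]
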