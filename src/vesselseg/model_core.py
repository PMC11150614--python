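"""Dual-branch cross-attention segmentation network.

The encoder couples two heterogeneous representations of the same
image: a hierarchical CNN producing feature maps (C x H' x W') and a
transformer producing a token sequence ((L+1) x J, class token first).
A shared convolutional trunk runs to stride 16; there the token
sequence is created by a 3x3 stride-1 projection of the stride-16
feature map (so each token's receptive field is one non-overlapping
16 x 16 input patch, and no positional embedding is needed).  The two
branches then proceed in parallel, exchanging information through
bidirectional fusion blocks between steps, and a U-shaped decoder over
the multi-scale CNN maps emits a full-resolution vessel probability
map.

Inputs are reflect-padded up to the next multiple of 32 and predictions
cropped back, so any H, W >= 32 works (including 118 x 118 training
patches).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor, concat

__all__ = [
    "FeatureMap",
    "TokenSequence",
    "ModelConfig",
    "ProbabilityMap",
    "ConvBottleneck",
    "TransformerBlock",
    "PatchEmbed",
    "FuseCnnToTrans",
    "FuseTransToCnn",
    "VesselSegNet",
    "build_model",
    "predict_proba",
    "transformer_block_param_count",
    "save_checkpoint",
    "load_checkpoint",
]

VALID_STRIDES = (4, 8, 16, 32)


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------

@dataclass
class FeatureMap:
    """Batched CNN activation map with its downsampling factor."""

    values: Tensor               # (N, C, H', W')
    stride: int

    def __post_init__(self):
        if self.values.ndim != 4:
            raise ValueError("FeatureMap values must be (N, C, H', W')")
        if self.stride not in VALID_STRIDES:
            raise ValueError(f"stride must be one of {VALID_STRIDES}")

    @property
    def channels(self) -> int:
        return self.values.shape[1]

    @property
    def spatial(self) -> tuple:
        return self.values.shape[2], self.values.shape[3]


@dataclass
class TokenSequence:
    """Batched token sequence; row 0 of each item is the class token."""

    values: Tensor               # (N, L+1, J)
    grid_h: int
    grid_w: int

    def __post_init__(self):
        if self.values.ndim != 3:
            raise ValueError("TokenSequence values must be (N, L+1, J)")
        if self.grid_h * self.grid_w != self.values.shape[1] - 1:
            raise ValueError("grid does not match token count")

    @property
    def n_tokens(self) -> int:
        return self.values.shape[1]

    @property
    def embed_dim(self) -> int:
        return self.values.shape[2]

    def spatial_grid(self) -> Tensor:
        """Drop the class token and reshape to (N, J, grid_h, grid_w)."""
        n, _, j = self.values.shape
        spatial = self.values[:, 1:, :]
        return spatial.transpose(0, 2, 1).reshape(n, j, self.grid_h, self.grid_w)


@dataclass
class ProbabilityMap:
    """Per-pixel vessel probability, aligned to the input image."""

    values: np.ndarray           # (H, W) in [0, 1]

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.min() < 0 or v.max() > 1:
            raise ValueError("probability map must be 2-D with values in [0, 1]")


# backbone trunk definitions: stem width, per-stage channels (strides
# 4/8/16/32) and bottleneck counts
BACKBONES = {
    "resnet50": {"stem": 64, "channels": (256, 512, 1024, 2048),
                 "blocks": (3, 4, 6, 3)},
    "tiny": {"stem": 16, "channels": (32, 64, 128, 160),
             "blocks": (1, 1, 1, 1)},
}


@dataclass
class ModelConfig:
    backbone_name: str = "resnet50"
    n_trans_blocks: int = 12
    embed_dim: int = 384
    n_heads: int = 6
    mlp_ratio: int = 4
    patch_stride: int = 16
    decoder_channels: list = field(default_factory=lambda: [256, 128, 64, 32])
    enable_trans_branch: bool = True
    enable_cnn_branch: bool = True
    enable_fusion: bool = True
    out_classes: int = 1

    def __post_init__(self):
        if self.backbone_name not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone_name!r}")
        if self.n_trans_blocks < 1:
            raise ValueError("n_trans_blocks must be >= 1")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.patch_stride != 16:
            raise ValueError("patch_stride is fixed at 16")
        if not (self.enable_trans_branch or self.enable_cnn_branch):
            raise ValueError("at least one branch must be enabled")
        if self.out_classes != 1:
            raise ValueError("out_classes is fixed at 1 (vessel probability)")
        if len(self.decoder_channels) != 4:
            raise ValueError("decoder_channels must list 4 stage widths")

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """CPU-scale preset used by the desk experiments and tests."""
        base = dict(backbone_name="tiny", n_trans_blocks=2, embed_dim=64,
                    n_heads=2, decoder_channels=[64, 48, 32, 16])
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        import yaml
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


# ----------------------------------------------------------------------
# blocks
# ----------------------------------------------------------------------

class ConvBottleneck(nn.Module):
    """Pre-activation residual bottleneck.

    Down-projection 1x1, spatial 3x3 (optionally strided), up-projection
    1x1, with a residual shortcut (1x1-projected when channels or
    resolution change).  Zeroing the final projection makes the block
    the identity when the shortcut is the identity.
    """

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1):
        super().__init__()
        mid = max(out_ch // 4, 4)
        self.bn1 = nn.BatchNorm2d(in_ch)
        self.conv_down = nn.Conv2d(in_ch, mid, 1, bias=False)
        self.bn2 = nn.BatchNorm2d(mid)
        self.conv_spatial = nn.Conv2d(mid, mid, 3, stride=stride, padding=1, bias=False)
        self.bn3 = nn.BatchNorm2d(mid)
        self.conv_up = nn.Conv2d(mid, out_ch, 1)
        if in_ch != out_ch or stride != 1:
            self.shortcut = nn.Conv2d(in_ch, out_ch, 1, stride=stride)
        else:
            self.shortcut = None
        self._stride = stride

    def forward_tensor(self, x: Tensor) -> Tensor:
        h = self.bn1(x).relu()
        sc = x if self.shortcut is None else self.shortcut(h)
        h = self.conv_down(h)
        h = self.bn2(h).relu()
        h = self.conv_spatial(h)
        h = self.bn3(h).relu()
        h = self.conv_up(h)
        return sc + h

    def forward(self, x):
        if isinstance(x, FeatureMap):
            out = self.forward_tensor(x.values)
            return FeatureMap(out, x.stride * self._stride)
        return self.forward_tensor(x)


class MultiHeadSelfAttention(nn.Module):
    def __init__(self, dim: int, n_heads: int):
        super().__init__()
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = nn.Linear(dim, 3 * dim)
        self.attn_out = nn.Linear(dim, dim)
        self.last_attn: np.ndarray | None = None  # (N, heads, L+1, L+1)

    def forward(self, x: Tensor) -> Tensor:
        n, l1, j = x.shape
        h, d = self.n_heads, self.head_dim
        qkv = self.qkv(x)                                    # (N, L1, 3J)
        q = qkv[:, :, 0:j].reshape(n, l1, h, d).transpose(0, 2, 1, 3)
        k = qkv[:, :, j:2 * j].reshape(n, l1, h, d).transpose(0, 2, 1, 3)
        v = qkv[:, :, 2 * j:].reshape(n, l1, h, d).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d))
        attn = scores.softmax(axis=-1)
        self.last_attn = attn.data
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(n, l1, j)
        return self.attn_out(out)


class Mlp(nn.Module):
    """Up-projection, GELU, down-projection."""

    def __init__(self, dim: int, hidden: int):
        super().__init__()
        self.fc_up = nn.Linear(dim, hidden)
        self.fc_down = nn.Linear(hidden, dim)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc_down(self.fc_up(x).gelu())


class TransformerBlock(nn.Module):
    """Pre-norm transformer unit: LN -> MHSA -> +residual, LN -> MLP -> +residual."""

    def __init__(self, dim: int, n_heads: int, mlp_ratio: int = 4):
        super().__init__()
        self.norm1 = nn.LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads)
        self.norm2 = nn.LayerNorm(dim)
        self.mlp = Mlp(dim, dim * mlp_ratio)

    def forward_tensor(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.mlp(self.norm2(x))

    def forward(self, t):
        if isinstance(t, TokenSequence):
            return TokenSequence(self.forward_tensor(t.values), t.grid_h, t.grid_w)
        return self.forward_tensor(t)


class PatchEmbed(nn.Module):
    """Tokenise the stride-16 feature map: 3x3 stride-1 projection.

    Each output token corresponds to one non-overlapping 16x16 input
    patch; a learned class token is prepended and no positional
    embedding is added.
    """

    def __init__(self, in_ch: int, embed_dim: int):
        super().__init__()
        self.proj = nn.Conv2d(in_ch, embed_dim, 3, stride=1, padding=1)
        self.cls_token = nn.Parameter(
            nn.layers.trunc_normal((1, 1, embed_dim)))

    def forward(self, x: FeatureMap) -> TokenSequence:
        if x.stride != 16:
            raise ValueError(f"patch embedding expects a stride-16 map, got {x.stride}")
        n = x.values.shape[0]
        y = self.proj(x.values)                       # (N, J, gh, gw)
        _, j, gh, gw = y.shape
        tokens = y.reshape(n, j, gh * gw).transpose(0, 2, 1)
        cls = self.cls_token + Tensor(np.zeros((n, 1, j), dtype=np.float32))
        return TokenSequence(concat([cls, tokens], axis=1), gh, gw)


class FuseCnnToTrans(nn.Module):
    """Additive fusion of a CNN feature map into the token sequence.

    1x1 channel projection, average-pooling down to the token grid,
    addition onto the spatial tokens (class token untouched), then
    LayerNorm over every token.
    """

    def __init__(self, in_ch: int, embed_dim: int):
        super().__init__()
        self.proj = nn.Conv2d(in_ch, embed_dim, 1)
        # zero-init: fusion starts as the identity (up to normalisation)
        # and learns its contribution, instead of perturbing both
        # branches with noise at the start of training
        self.proj.weight.data[...] = 0.0
        self.norm = nn.LayerNorm(embed_dim)

    def forward(self, x: FeatureMap, t: TokenSequence) -> TokenSequence:
        h, w = x.spatial
        if h % t.grid_h or w % t.grid_w:
            raise ValueError(
                f"feature map {h}x{w} not an integer multiple of token grid "
                f"{t.grid_h}x{t.grid_w}")
        factor = h // t.grid_h
        if w // t.grid_w != factor:
            raise ValueError("anisotropic pooling factors are not supported")
        n = x.values.shape[0]
        j = t.embed_dim
        pooled = F.avg_pool2d(self.proj(x.values), factor) if factor > 1 \
            else self.proj(x.values)
        add = pooled.reshape(n, j, t.grid_h * t.grid_w).transpose(0, 2, 1)
        zeros = Tensor(np.zeros((n, 1, j), dtype=np.float32))
        fused = t.values + concat([zeros, add], axis=1)
        return TokenSequence(self.norm(fused), t.grid_h, t.grid_w)


class FuseTransToCnn(nn.Module):
    """Additive fusion of the token sequence into a CNN feature map.

    The class token is dropped; spatial tokens are reshaped to their
    grid, bilinearly up-sampled to the map's resolution, 1x1-projected
    to the map's channel count, added, then BatchNorm-regularised.
    """

    def __init__(self, embed_dim: int, out_ch: int):
        super().__init__()
        self.proj = nn.Conv2d(embed_dim, out_ch, 1)
        self.proj.weight.data[...] = 0.0   # see FuseCnnToTrans
        self.norm = nn.BatchNorm2d(out_ch)

    def forward(self, t: TokenSequence, x: FeatureMap) -> FeatureMap:
        h, w = x.spatial
        grid = t.spatial_grid()
        if (h, w) != (t.grid_h, t.grid_w):
            grid = F.upsample_bilinear(grid, h, w)
        fused = self.norm(x.values + self.proj(grid))
        return FeatureMap(fused, x.stride)


class DecoderStage(nn.Module):
    """2x up-sampling, skip concatenation, 3x3 conv, BN, ReLU."""

    def __init__(self, in_ch: int, skip_ch: int, out_ch: int):
        super().__init__()
        self.conv = nn.Conv2d(in_ch + skip_ch, out_ch, 3, padding=1, bias=False)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        x = F.upsample_bilinear(x, skip.shape[2], skip.shape[3])
        x = concat([x, skip], axis=1)
        return self.bn(self.conv(x)).relu()


class Decoder(nn.Module):
    """U-shaped head over strides 32 -> 16 -> 8 -> 4 -> 1.

    After the final 4x up-sampling the (standardised) input image is
    concatenated back in as a full-resolution detail skip — the encoder
    starts at stride 4, and vessels are only a few pixels wide.
    """

    def __init__(self, enc_channels, dec_channels, out_classes: int = 1):
        super().__init__()
        c4, c8, c16, c32 = enc_channels
        d16, d8, d4, d1 = dec_channels
        self.up16 = DecoderStage(c32, c16, d16)
        self.up8 = DecoderStage(d16, c8, d8)
        self.up4 = DecoderStage(d8, c4, d4)
        self.head_conv = nn.Conv2d(d4 + 3, d1, 3, padding=1, bias=False)
        self.head_bn = nn.BatchNorm2d(d1)
        self.head_out = nn.Conv2d(d1, out_classes, 1)

    def forward(self, x32, x16, x8, x4, img) -> Tensor:
        d = self.up16(x32, x16)
        d = self.up8(d, x8)
        d = self.up4(d, x4)
        d = F.upsample_bilinear(d, img.shape[2], img.shape[3])
        d = concat([d, img], axis=1)
        d = self.head_bn(self.head_conv(d)).relu()
        return self.head_out(d)        # logits (N, 1, H, W)


# ----------------------------------------------------------------------
# the network
# ----------------------------------------------------------------------

class VesselSegNet(nn.Module):
    """Shared trunk + parallel CNN/transformer branches + fused decoder."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        bb = BACKBONES[config.backbone_name]
        c4, c8, c16, c32 = bb["channels"]
        n1, n2, n3, n4 = bb["blocks"]
        stem_ch = bb["stem"]

        # stem: two stride-2 convs to stride 4
        self.stem_conv1 = nn.Conv2d(3, stem_ch, 3, stride=2, padding=1, bias=False)
        self.stem_bn1 = nn.BatchNorm2d(stem_ch)
        self.stem_conv2 = nn.Conv2d(stem_ch, stem_ch, 3, stride=2, padding=1, bias=False)
        self.stem_bn2 = nn.BatchNorm2d(stem_ch)

        def stage(in_ch, out_ch, n_blocks, stride):
            blocks = [ConvBottleneck(in_ch, out_ch, stride)]
            blocks += [ConvBottleneck(out_ch, out_ch) for _ in range(n_blocks - 1)]
            return nn.ModuleList(blocks)

        self.stage1 = stage(stem_ch, c4, n1, 1)     # stride 4
        self.stage2 = stage(c4, c8, n2, 2)          # stride 8
        self.stage3 = stage(c8, c16, n3, 2)         # stride 16

        n_steps = config.n_trans_blocks
        if config.enable_cnn_branch:
            self.cnn_branch = nn.ModuleList(
                [ConvBottleneck(c16, c16) for _ in range(n_steps)])
        if config.enable_trans_branch:
            self.patch_embed = PatchEmbed(c16, config.embed_dim)
            self.trans_blocks = nn.ModuleList(
                [TransformerBlock(config.embed_dim, config.n_heads,
                                  config.mlp_ratio) for _ in range(n_steps)])
        both = config.enable_cnn_branch and config.enable_trans_branch
        if both and config.enable_fusion:
            # fusion couples every step except the initial one
            self.fuse_in = nn.ModuleList(
                [FuseCnnToTrans(c16, config.embed_dim) for _ in range(n_steps - 1)])
            self.fuse_out = nn.ModuleList(
                [FuseTransToCnn(config.embed_dim, c16) for _ in range(n_steps - 1)])
        if config.enable_trans_branch and not (both and config.enable_fusion):
            # tokens reach the decoder through a dedicated projection
            self.token_proj = nn.Conv2d(config.embed_dim, c16, 1)

        self.stage4 = stage(c16, c32, n4, 2)        # stride 32
        self.decoder = Decoder((c4, c8, c16, c32), config.decoder_channels,
                               config.out_classes)

    # -- forward -----------------------------------------------------------
    def _stem(self, x: Tensor) -> Tensor:
        x = self.stem_bn1(self.stem_conv1(x)).relu()
        return self.stem_bn2(self.stem_conv2(x)).relu()

    @staticmethod
    def _run_stage(stage, x: Tensor) -> Tensor:
        for block in stage:
            x = block(x)
        return x

    def forward(self, x: Tensor) -> Tensor:
        """Map (N, 3, H, W) standardised images to (N, 1, H, W) logits.

        H and W must be multiples of 32; use :func:`predict_proba` for
        arbitrary sizes.
        """
        cfg = self.config
        n, c, h, w = x.shape
        if c != 3:
            raise ValueError("input must be RGB (N, 3, H, W)")
        if h % 32 or w % 32:
            raise ValueError("spatial dims must be multiples of 32")

        x4 = self._run_stage(self.stage1, self._stem(x))
        x8 = self._run_stage(self.stage2, x4)
        x16 = self._run_stage(self.stage3, x8)

        both = cfg.enable_cnn_branch and cfg.enable_trans_branch
        fused = both and cfg.enable_fusion
        cnn = FeatureMap(x16, 16) if cfg.enable_cnn_branch else None
        tokens = self.patch_embed(FeatureMap(x16, 16)) \
            if cfg.enable_trans_branch else None

        for i in range(cfg.n_trans_blocks):
            if cnn is not None:
                cnn = self.cnn_branch[i](cnn)
            if fused and i >= 1:
                tokens = self.fuse_in[i - 1](cnn, tokens)
            if tokens is not None:
                tokens = self.trans_blocks[i](tokens)
            if fused and i >= 1:
                cnn = self.fuse_out[i - 1](tokens, cnn)

        if fused or (cnn is not None and tokens is None):
            d16 = cnn.values
        else:
            token_map = tokens.spatial_grid()
            gh, gw = tokens.grid_h, tokens.grid_w
            if (gh, gw) != (x16.shape[2], x16.shape[3]):
                token_map = F.upsample_bilinear(token_map, x16.shape[2], x16.shape[3])
            token_map = self.token_proj(token_map)
            d16 = cnn.values + token_map if cnn is not None else token_map

        x32 = self._run_stage(self.stage4, d16)
        return self.decoder(x32, d16, x8, x4, x)


def build_model(config: ModelConfig, seed: int = 0) -> VesselSegNet:
    """Build a network with seeded, deterministic initialisation."""
    nn.manual_seed(seed)
    return VesselSegNet(config)


def transformer_block_param_count(embed_dim: int, n_heads: int,
                                  mlp_ratio: int = 4) -> int:
    """Closed-form parameter count of one transformer block."""
    j = embed_dim
    hidden = j * mlp_ratio
    norm = 2 * j
    attn = (j * 3 * j + 3 * j) + (j * j + j)
    mlp = (j * hidden + hidden) + (hidden * j + j)
    return 2 * norm + attn + mlp


# ----------------------------------------------------------------------
# whole-image inference helper
# ----------------------------------------------------------------------

def _pad_to_multiple(img: np.ndarray, multiple: int = 32) -> np.ndarray:
    h, w = img.shape[-2:]
    th = max(int(np.ceil(h / multiple)) * multiple, multiple)
    tw = max(int(np.ceil(w / multiple)) * multiple, multiple)
    return F.pad_reflect(img, th, tw)


def predict_proba(model: VesselSegNet, images: np.ndarray) -> list:
    """Run standardised image batches of any size through the network.

    ``images``: (N, 3, H, W) float array, already standardised.  Pads by
    reflection to the next multiple of 32, runs the model in eval mode
    without building a graph, applies the logistic squashing and crops
    back.  Returns a list of :class:`ProbabilityMap`.
    """
    if images.ndim != 4 or images.shape[1] != 3:
        raise ValueError("expected standardised (N, 3, H, W) input")
    h, w = images.shape[2], images.shape[3]
    was_training = model.training
    model.eval()
    try:
        padded = _pad_to_multiple(images.astype(np.float32))
        with nn.no_grad():
            logits = model(Tensor(padded))
            probs = logits.sigmoid().data[:, 0, :h, :w]
    finally:
        if was_training:
            model.train()
    return [ProbabilityMap(np.clip(p, 0.0, 1.0)) for p in probs]


# ----------------------------------------------------------------------
# checkpoints
# ----------------------------------------------------------------------

def save_checkpoint(model: VesselSegNet, path) -> None:
    """Serialised weights (.npz) with an embedded-config JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(asdict(model.config), indent=2))


def load_checkpoint(path) -> VesselSegNet:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    config = ModelConfig(**json.loads(sidecar.read_text()))
    model = build_model(config)
    with np.load(path) as data:
        model.load_state_dict(dict(data))
    return model
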