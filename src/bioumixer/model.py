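"""BioUMixer: a U-like hierarchical residual fusion network for image regression.

The network maps an RGB canopy image to a d_emb-dimensional embedding ``v``
(consumed by the SCDR loss) and a scalar biomass prediction ``ŷ``.  Structure:

    patch embed → [stage 0: FeatureBlock, BioBlock] → SimAM → merge ↓
                → [stage 1: ...]                    → SimAM → merge ↓
                → [stage 2: ...]                    → SimAM → mixer head

* **FeatureBlock** — ConvNeXt-style residual block: depthwise 3×3 →
  BatchNorm → 1×1 expansion (×4) → GELU → global response normalization →
  1×1 reduction → DropPath → add input.
* **BioBlock** — sandwich layout: pointwise FFN → depthwise token mixer with
  SimAM attention → pointwise FFN, every sub-layer residual (ReLU FFNs).
* **SimAM** — parameter-free 3-D attention: each position is weighted by a
  sigmoid of a closed-form energy derived from its deviation from the
  channel's spatial mean.
* **U-like hierarchical residual** — long skips pairing blocks of identical
  kind across stages (stage *i* feeds stage *S−1−i*); the early feature map
  is average-pooled to the late resolution, 1×1-projected when channel
  counts differ, and fused by addition.

Each of the three module families can be toggled off (replaced by the
identity) to reproduce the ablation cases; the patch embedding, downsampling
merges, stage-transition attention and mixer head form the always-present
main module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor


@dataclass
class AblationToggles:
    """Table-style module switches: the five canonical ablation cases."""

    skips: bool = True
    feature_block: bool = True
    bio_block: bool = True


ABLATION_CASES = {
    "case1": AblationToggles(skips=False, feature_block=False, bio_block=False),
    "case2": AblationToggles(skips=False, feature_block=True, bio_block=True),
    "case3": AblationToggles(skips=True, feature_block=False, bio_block=True),
    "case4": AblationToggles(skips=True, feature_block=True, bio_block=False),
    "case5": AblationToggles(skips=True, feature_block=True, bio_block=True),
}


@dataclass
class ModelConfig:
    input_size: int = 224
    patch_size: int = 4
    stage_widths: tuple = (32, 64, 128)
    blocks_per_stage: tuple = (2, 2, 2)
    embedding_dim: int = 128
    drop_path_rate: float = 0.0
    simam_lambda: float = 1e-4
    ffn_ratio: int = 4              # FeatureBlock pointwise expansion
    bio_ffn_ratio: int = 2          # BioBlock FFN expansion
    token_hidden: int = 64          # mixer token-MLP width
    channel_hidden: int = 256       # mixer channel-MLP width
    head_hidden: int = 64           # prediction-MLP width
    skip_projection: str = "conv1x1"
    toggles: AblationToggles = field(default_factory=AblationToggles)

    def __post_init__(self):
        if isinstance(self.toggles, dict):
            self.toggles = AblationToggles(**self.toggles)
        self.stage_widths = tuple(self.stage_widths)
        self.blocks_per_stage = tuple(self.blocks_per_stage)
        if any(w <= 0 for w in self.stage_widths):
            raise ValueError("stage widths must be positive")
        if len(self.stage_widths) != len(self.blocks_per_stage):
            raise ValueError("stage_widths and blocks_per_stage lengths differ")
        total_down = self.patch_size * 2 ** (len(self.stage_widths) - 1)
        if self.input_size % total_down:
            raise ValueError(
                f"input_size {self.input_size} not divisible by the cumulative "
                f"downsampling factor {total_down}"
            )
        if not 0.0 <= self.drop_path_rate < 1.0:
            raise ValueError("drop_path_rate must be in [0, 1)")
        if self.simam_lambda <= 0:
            raise ValueError("simam_lambda must be > 0")
        if self.skip_projection not in ("conv1x1", "identity"):
            raise ValueError(f"unknown skip_projection {self.skip_projection!r}")

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """Desk-scale preset: 64×64 input, one block of each kind per stage."""
        defaults = dict(input_size=64, stage_widths=(32, 64, 128),
                        blocks_per_stage=(1, 1, 1), embedding_dim=128)
        defaults.update(overrides)
        return cls(**defaults)


# ------------------------------------------------------------ functional ops
def grn(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Global response normalization.

    Per channel, the spatial L2 norm is divided by the cross-channel mean of
    those norms; the input is rescaled by that ratio through a learnable
    affine with a residual:  out = γ·(x·N) + β + x.  Zero-initialised γ, β
    make the layer an exact identity at the start of training.
    """
    C = x.shape[1]
    gx = ad.sqrt((x**2).sum(axis=(2, 3), keepdims=True) + eps * eps)  # (B,C,1,1)
    nx = gx / (gx.mean(axis=1, keepdims=True) + eps)
    return x * nx * gamma.reshape((1, C, 1, 1)) + beta.reshape((1, C, 1, 1)) + x


def simam(x: Tensor, lam: float) -> Tensor:
    """Parameter-free 3-D attention.

    For each channel with spatial mean μ and unbiased spatial variance σ̂²,
    every position gets energy y = (x−μ)²/(4(σ̂²+λ)) + 0.5 and is rescaled by
    sigmoid(y).  A spatially constant channel therefore shrinks uniformly by
    sigmoid(0.5), and λ→∞ drives all weights to that same limit.
    """
    if lam <= 0:
        raise ValueError("simam lambda must be > 0")
    B, C, H, W = x.shape
    n = H * W
    if n <= 1:
        raise ValueError("simam requires spatial size > 1 (variance undefined)")
    mu = x.mean(axis=(2, 3), keepdims=True)
    d = x - mu
    var = (d**2).sum(axis=(2, 3), keepdims=True) * (1.0 / (n - 1))
    energy = d**2 / (4.0 * (var + lam)) + 0.5
    return x * ad.sigmoid(energy)


def u_skip_fuse(early: Tensor, late: Tensor, proj: nn.Module | None = None) -> Tensor:
    """Fuse an early feature map into a later one: pool to the late spatial
    size, optionally 1×1-project the channels, then add."""
    eh, lh = early.shape[-2], late.shape[-2]
    if eh > lh:
        if eh % lh:
            raise ValueError(f"irreconcilable spatial dims {eh} vs {lh}")
        early = ad.avg_pool2d(early, eh // lh)
    elif lh > eh:
        if lh % eh:
            raise ValueError(f"irreconcilable spatial dims {eh} vs {lh}")
        early = ad.upsample_nearest2d(early, lh // eh)
    if proj is not None:
        early = proj(early)
    elif early.shape[1] != late.shape[1]:
        raise ValueError("channel mismatch without a projection")
    return late + early


# ------------------------------------------------------------------- blocks
class PatchEmbed(nn.Module):
    """Non-overlapping p×p patch projection (reshape + linear)."""

    def __init__(self, patch: int, c_in: int, c_out: int, rng):
        super().__init__()
        self.patch = patch
        self.proj = nn.Linear(c_in * patch * patch, c_out, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        p = self.patch
        if H % p or W % p:
            raise ValueError(f"input {H}×{W} not divisible by patch size {p}")
        h, w = H // p, W // p
        t = x.reshape((B, C, h, p, w, p)).transpose((0, 2, 4, 1, 3, 5)).reshape((B * h * w, C * p * p))
        t = self.proj(t)
        return t.reshape((B, h, w, -1)).transpose((0, 3, 1, 2))


class PatchMerge(nn.Module):
    """2×2 downsampling merge with a channel change (reshape + linear)."""

    def __init__(self, c_in: int, c_out: int, rng):
        super().__init__()
        self.proj = nn.Linear(c_in * 4, c_out, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        h, w = H // 2, W // 2
        t = x.reshape((B, C, h, 2, w, 2)).transpose((0, 2, 4, 1, 3, 5)).reshape((B * h * w, C * 4))
        t = self.proj(t)
        return t.reshape((B, h, w, -1)).transpose((0, 3, 1, 2))


class FeatureBlock(nn.Module):
    """ConvNeXt-style residual block with GRN and stochastic depth."""

    def __init__(self, channels: int, cfg: ModelConfig, rng):
        super().__init__()
        self.dw = nn.DepthwiseConv3x3(channels, rng)
        self.norm = nn.BatchNorm2d(channels)
        hidden = channels * cfg.ffn_ratio
        self.expand = nn.Conv1x1(channels, hidden, rng)
        self.grn_gamma = nn.parameter(np.zeros(hidden))
        self.grn_beta = nn.parameter(np.zeros(hidden))
        self.reduce = nn.Conv1x1(hidden, channels, rng)
        self.drop_path = nn.DropPath(cfg.drop_path_rate)
        self.drop_path.rng = np.random.default_rng(rng.integers(2**31))

    def forward(self, x: Tensor) -> Tensor:
        h = self.dw(x)
        h = self.norm(h)
        h = ad.gelu(self.expand(h))
        h = grn(h, self.grn_gamma, self.grn_beta)
        h = self.reduce(h)
        return x + self.drop_path(h)


class BioBlock(nn.Module):
    """Sandwich layout: FFN → depthwise token mixer with SimAM → FFN."""

    def __init__(self, channels: int, cfg: ModelConfig, rng):
        super().__init__()
        hidden = channels * cfg.bio_ffn_ratio
        self.ffn1_up = nn.Conv1x1(channels, hidden, rng)
        self.ffn1_down = nn.Conv1x1(hidden, channels, rng)
        self.mixer = nn.DepthwiseConv3x3(channels, rng)
        self.ffn2_up = nn.Conv1x1(channels, hidden, rng)
        self.ffn2_down = nn.Conv1x1(hidden, channels, rng)
        self.simam_lambda = cfg.simam_lambda
        self.use_simam = True

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.ffn1_down(ad.relu(self.ffn1_up(x)))
        h = self.mixer(x)
        if self.use_simam:
            h = simam(h, self.simam_lambda)
        x = x + h
        x = x + self.ffn2_down(ad.relu(self.ffn2_up(x)))
        return x


class MixerHead(nn.Module):
    """Token/channel-mixing block over the final map, then the MLP head.

    Exposes the pooled d_emb embedding ``v`` (input of the prediction MLP)
    alongside the scalar output ``ŷ``.
    """

    def __init__(self, channels: int, n_tokens: int, cfg: ModelConfig, rng):
        super().__init__()
        self.norm1 = nn.LayerNorm(channels)
        self.token_up = nn.Linear(n_tokens, cfg.token_hidden, rng)
        self.token_down = nn.Linear(cfg.token_hidden, n_tokens, rng)
        self.norm2 = nn.LayerNorm(channels)
        self.chan_up = nn.Linear(channels, cfg.channel_hidden, rng)
        self.chan_down = nn.Linear(cfg.channel_hidden, channels, rng)
        self.embed = nn.Linear(channels, cfg.embedding_dim, rng)
        self.head_hidden = nn.Linear(cfg.embedding_dim, cfg.head_hidden, rng)
        self.head_out = nn.Linear(cfg.head_hidden, 1, rng)

    def forward(self, x: Tensor):
        B, C, H, W = x.shape
        tokens = x.reshape((B, C, H * W)).transpose((0, 2, 1))  # (B, T, C)
        h = self.norm1(tokens).transpose((0, 2, 1))             # (B, C, T)
        h = self.token_down(ad.gelu(self.token_up(h))).transpose((0, 2, 1))
        tokens = tokens + h
        tokens = tokens + self.chan_down(ad.gelu(self.chan_up(self.norm2(tokens))))
        pooled = tokens.mean(axis=1)                            # (B, C)
        v = self.embed(pooled)                                  # (B, d_emb)
        y = self.head_out(ad.gelu(self.head_hidden(v)))
        return v, y.reshape((B,))


# -------------------------------------------------------------------- model
class BioUMixer(nn.Module):
    """The full hierarchical residual fusion network.

    ``forward`` returns ``(embedding (B, d_emb), prediction (B,))``.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        widths = config.stage_widths
        t = config.toggles
        self.patch_embed = PatchEmbed(config.patch_size, 3, widths[0], rng)
        self.feature_blocks: list = []
        self.bio_blocks: list = []
        self.merges: list = []
        for s, w in enumerate(widths):
            fb = [FeatureBlock(w, config, rng) if t.feature_block else nn.Identity()
                  for _ in range(config.blocks_per_stage[s])]
            bb = [BioBlock(w, config, rng) if t.bio_block else nn.Identity()
                  for _ in range(config.blocks_per_stage[s])]
            self.feature_blocks.append(fb)
            self.bio_blocks.append(bb)
            if s + 1 < len(widths):
                self.merges.append(PatchMerge(w, widths[s + 1], rng))
        # long-skip projections: stage s → stage S−1−s, one per block kind/index
        self.skip_projs: dict = {}
        self._skip_pairs = []
        S = len(widths)
        if t.skips:
            for s in range(S // 2):
                tgt = S - 1 - s
                if tgt == s:
                    continue
                n = min(config.blocks_per_stage[s], config.blocks_per_stage[tgt])
                for kind in ("feature", "bio"):
                    if kind == "feature" and not t.feature_block:
                        continue
                    if kind == "bio" and not t.bio_block:
                        continue
                    for i in range(n):
                        key = f"{kind}_{s}_{tgt}_{i}"
                        if config.skip_projection == "conv1x1" and widths[s] != widths[tgt]:
                            proj = nn.Conv1x1(widths[s], widths[tgt], rng)
                        else:
                            proj = None
                        self.skip_projs[key] = proj
                        self._skip_pairs.append((kind, s, tgt, i, key))
        # register projections for parameter discovery
        self._skip_proj_modules = [p for p in self.skip_projs.values() if p is not None]
        final_hw = config.input_size // config.patch_size // 2 ** (S - 1)
        self.head = MixerHead(widths[-1], final_hw * final_hw, config, rng)

    def forward(self, x) -> tuple:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        h = self.patch_embed(x)
        stored: dict = {}
        incoming: dict = {}
        for kind, s, tgt, i, key in self._skip_pairs:
            incoming.setdefault((kind, tgt, i), []).append((kind, s, i, key))
        S = len(self.config.stage_widths)
        for s in range(S):
            for i in range(self.config.blocks_per_stage[s]):
                for kind, blocks in (("feature", self.feature_blocks), ("bio", self.bio_blocks)):
                    for src_kind, src_s, src_i, key in incoming.get((kind, s, i), []):
                        early = stored.get((src_kind, src_s, src_i))
                        if early is not None:
                            h = u_skip_fuse(early, h, self.skip_projs[key])
                    h = blocks[s][i](h)
                    stored[(kind, s, i)] = h
            h = simam(h, self.config.simam_lambda)  # stage-transition attention
            if s + 1 < S:
                h = self.merges[s](h)
        v, y = self.head(h)
        if not (np.isfinite(v.data).all() and np.isfinite(y.data).all()):
            raise FloatingPointError("non-finite values in model output")
        return v, y


def build_model(config: ModelConfig, seed: int = 0) -> BioUMixer:
    """Construct a BioUMixer with all shapes derived from ``config``."""
    return BioUMixer(config, seed)
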