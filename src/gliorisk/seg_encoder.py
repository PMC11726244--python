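"""Compact 3D U-Net for tumor segmentation and its frozen-encoder feature tap.

The transfer-learning step mirrors common practice with segmentation
networks: train (or load) a U-Net on tumor masks, freeze it, and read out the
deepest encoder activations, adaptive-average-pooled to a small grid and
flattened, as a fixed-length descriptor of the volume ("DL-MRI features").
Under the full-size default configuration (5 levels, 32 base channels,
growth 2, pooled grid 2x2x2) the descriptor has 512 x 8 = 4096 entries for a
[96, 192, 192] input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .types import ImageVolume, TumorMask

__all__ = [
    "UNetConfig",
    "SegTrainConfig",
    "DLFeatureVector",
    "UNet3D",
    "build_unet",
    "train_segmentation",
    "segment",
    "extract_features",
    "save_weights",
    "load_weights",
    "encoder_hash",
]


@dataclass
class UNetConfig:
    n_levels: int = 5
    base_channels: int = 32
    channel_growth: int = 2
    pooled_grid: tuple[int, int, int] = (2, 2, 2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("encoder must downsample: n_levels >= 2 required")
        if self.base_channels < 1 or self.channel_growth < 1:
            raise ValueError("base_channels and channel_growth must be >= 1")
        if any(int(g) < 1 for g in self.pooled_grid):
            raise ValueError("pooled_grid entries must be >= 1")

    @property
    def deepest_channels(self) -> int:
        return self.base_channels * self.channel_growth ** (self.n_levels - 1)

    @property
    def feature_dim(self) -> int:
        return self.deepest_channels * int(np.prod(self.pooled_grid))

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "UNetConfig":
        """Small configuration for CPU-scale experiments (feature_dim 128)."""
        return cls(n_levels=3, base_channels=4, channel_growth=2, pooled_grid=(2, 2, 2), seed=seed)


@dataclass
class SegTrainConfig:
    epochs: int = 14
    lr: float = 5e-3
    batch_size: int = 2
    seed: int = 0


@dataclass
class DLFeatureVector:
    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


class UNet3D:
    """Encoder-decoder with skip connections; 2-class voxelwise head."""

    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        g = config.channel_growth
        ch = [config.base_channels * g**l for l in range(config.n_levels)]
        self.channels = ch
        self.enc = []
        c_prev = 1
        for c in ch:
            self.enc.append((nn.Conv3d(c_prev, c, rng), nn.Conv3d(c, c, rng)))
            c_prev = c
        self.up = []
        self.dec = []
        for l in range(config.n_levels - 2, -1, -1):
            self.up.append(nn.Conv3d(ch[l + 1], ch[l], rng))
            self.dec.append((nn.Conv3d(2 * ch[l], ch[l], rng), nn.Conv3d(ch[l], ch[l], rng)))
        self.head = nn.Conv1x1(ch[0], 2, rng)
        self._cache = None

    # -- parameter plumbing -------------------------------------------------
    def encoder_parameters(self):
        out = []
        for a, b in self.enc:
            out += a.parameters() + b.parameters()
        return out

    def parameters(self):
        out = self.encoder_parameters()
        for u in self.up:
            out += u.parameters()
        for a, b in self.dec:
            out += a.parameters() + b.parameters()
        out += self.head.parameters()
        return out

    # -- forward / backward -------------------------------------------------
    def _check_shape(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[0] != 1:
            raise ValueError(f"expected input of shape (1, D, H, W), got {x.shape}")
        f = 2 ** (self.config.n_levels - 1)
        if any(s % f for s in x.shape[1:]):
            raise ValueError(
                f"spatial dims {x.shape[1:]} must be divisible by {f} "
                f"for a {self.config.n_levels}-level encoder"
            )

    def encoder_forward(self, x: np.ndarray):
        self._check_shape(x)
        skips, pools = [], []
        h = x.astype(np.float32, copy=False)
        for l, (ca, cb) in enumerate(self.enc):
            a1 = nn.relu(ca.forward(h))
            a2 = nn.relu(cb.forward(a1))
            skips.append((a1, a2))
            if l < self.config.n_levels - 1:
                h, cache = nn.maxpool2(a2)
                pools.append(cache)
            else:
                h = a2
        return h, skips, pools

    def forward(self, x: np.ndarray) -> np.ndarray:
        h, skips, pools = self.encoder_forward(x)
        dec_cache = []
        for i, (upconv, (da, db)) in enumerate(zip(self.up, self.dec)):
            level = self.config.n_levels - 2 - i
            u = nn.relu(upconv.forward(nn.upsample2(h)))
            skip = skips[level][1]
            cat = np.concatenate([skip, u], axis=0)
            d1 = nn.relu(da.forward(cat))
            d2 = nn.relu(db.forward(d1))
            dec_cache.append((u, d1, d2, skip.shape[0]))
            h = d2
        logits = self.head.forward(h)
        self._cache = (skips, pools, dec_cache)
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        skips, pools, dec_cache = self._cache
        dh = self.head.backward(dlogits)
        dskip_pending = {}
        for i in range(len(self.dec) - 1, -1, -1):
            upconv, (da, db) = self.up[i], self.dec[i]
            level = self.config.n_levels - 2 - i
            u, d1, d2, n_skip = dec_cache[i]
            dd2 = nn.relu_backward(dh, d2)
            dd1 = nn.relu_backward(db.backward(dd2), d1)
            dcat = da.backward(dd1)
            dskip, du = dcat[:n_skip], dcat[n_skip:]
            dskip_pending[level] = dskip
            dup = upconv.backward(nn.relu_backward(du, u))
            dh = nn.upsample2_backward(dup)
        # encoder
        for l in range(self.config.n_levels - 1, -1, -1):
            ca, cb = self.enc[l]
            a1, a2 = skips[l]
            if l == self.config.n_levels - 1:
                da2 = dh
            else:
                da2 = nn.maxpool2_backward(dh, pools[l]) + dskip_pending.get(l, 0.0)
            da1 = nn.relu_backward(cb.backward(nn.relu_backward(da2, a2)), a1)
            dh = ca.backward(da1)


def build_unet(config: UNetConfig) -> UNet3D:
    """Deterministically initialized U-Net for the given configuration."""
    return UNet3D(config)


def _as_array(v) -> np.ndarray:
    if isinstance(v, (ImageVolume, TumorMask)):
        return np.asarray(v.voxels)
    return np.asarray(v)


def dice_ce_loss(logits: np.ndarray, target: np.ndarray, eps: float = 1.0):
    """Soft Dice (foreground) + voxelwise cross-entropy; returns (loss, dlogits)."""
    g = target.astype(np.float64)
    z = logits.astype(np.float64)
    margin = np.clip(z[1] - z[0], -30, 30)
    p1 = 1.0 / (1.0 + np.exp(-margin))
    n = p1.size
    ce = -np.mean(g * np.log(np.maximum(p1, 1e-12)) + (1 - g) * np.log(np.maximum(1 - p1, 1e-12)))
    dmargin = (p1 - g) / n

    inter, sp, sg = (p1 * g).sum(), p1.sum(), g.sum()
    den = sp + sg + eps
    dice = (2 * inter + eps) / den
    ddice_dp = (2 * g * den - (2 * inter + eps)) / den**2
    dmargin += -ddice_dp * p1 * (1 - p1)

    dlogits = np.stack([-dmargin, dmargin]).astype(logits.dtype)
    return float(ce + 1.0 - dice), dlogits


def train_segmentation(volumes, masks, config: UNetConfig | UNet3D, train_cfg: SegTrainConfig):
    """Train the U-Net on (volume, mask) pairs; returns (model, per-epoch loss log)."""
    vols = [_as_array(v)[None] if _as_array(v).ndim == 3 else _as_array(v) for v in volumes]
    msks = [_as_array(m) for m in masks]
    if len(vols) < 10:
        raise ValueError(f"need >= 10 training phantoms, got {len(vols)}")
    if all(m.sum() == 0 for m in msks):
        raise ValueError("all training masks are empty")
    model = config if isinstance(config, UNet3D) else build_unet(config)
    opt = nn.Adam(model.parameters(), lr=train_cfg.lr)
    rng = np.random.default_rng(train_cfg.seed)
    loss_log = []
    n = len(vols)
    for _epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            opt.zero_grad()
            for i in idx:
                logits = model.forward(vols[i].astype(np.float32))
                loss, dlogits = dice_ce_loss(logits, msks[i])
                model.backward(dlogits / len(idx))
                epoch_losses.append(loss)
            opt.step()
        loss_log.append(float(np.mean(epoch_losses)))
    return model, loss_log


def segment(model: UNet3D, vol) -> TumorMask:
    """Voxelwise argmax segmentation of a framed volume."""
    arr = _as_array(vol)
    x = arr[None] if arr.ndim == 3 else arr
    logits = model.forward(x.astype(np.float32))
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite logits in segmentation head")
    pred = (logits[1] > logits[0]).astype(np.uint8)
    spacing = vol.spacing_mm if isinstance(vol, (ImageVolume, TumorMask)) else (1.0, 1.0, 1.0)
    return TumorMask(pred, spacing)


def extract_features(model: UNet3D, vol, subject_id: str = "") -> DLFeatureVector:
    """Frozen-encoder feature tap.

    Deepest encoder activations -> adaptive average pool onto the configured
    grid -> flatten.  A pure function of (weights, volume).
    """
    arr = _as_array(vol)
    x = arr[None] if arr.ndim == 3 else arr
    bottleneck, _, _ = model.encoder_forward(x.astype(np.float32))
    if not np.all(np.isfinite(bottleneck)):
        raise FloatingPointError(
            f"non-finite activations in encoder bottleneck (level {model.config.n_levels - 1})"
        )
    pooled = nn.adaptive_avg_pool(bottleneck, model.config.pooled_grid)
    vec = pooled.ravel()
    assert vec.size == model.config.feature_dim
    return DLFeatureVector(values=vec, subject_id=subject_id)


def encoder_hash(model: UNet3D) -> str:
    """Hash of encoder weights; used to verify the freezing contract."""
    return nn.params_hash(model.encoder_parameters())


# ---------------------------------------------------------------------------
# checkpointing (single .npz file with a JSON header)

_CKPT_VERSION = 1


def save_weights(model: UNet3D, path: str | Path) -> Path:
    path = Path(path)
    header = {
        "version": _CKPT_VERSION,
        "n_levels": model.config.n_levels,
        "base_channels": model.config.base_channels,
        "channel_growth": model.config.channel_growth,
        "pooled_grid": list(model.config.pooled_grid),
        "seed": model.config.seed,
    }
    arrays = {f"p{i:04d}": p for i, (p, _) in enumerate(model.parameters())}
    np.savez(path, header=json.dumps(header), **arrays)
    return path


def load_weights(path: str | Path) -> UNet3D:
    with np.load(Path(path), allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        if header["version"] != _CKPT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header['version']}")
        cfg = UNetConfig(
            n_levels=header["n_levels"],
            base_channels=header["base_channels"],
            channel_growth=header["channel_growth"],
            pooled_grid=tuple(header["pooled_grid"]),
            seed=header["seed"],
        )
        model = build_unet(cfg)
        for i, (p, _) in enumerate(model.parameters()):
            p[...] = data[f"p{i:04d}"]
    return model
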