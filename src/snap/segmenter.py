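"""Binary taproot segmentation with a three-level encoder-decoder network.

The network has three contracting blocks (two 3x3 convolutions with batch
normalization and ReLU each, dropout in the encoder and bridge only),
2x2 max-pool downsampling, a bridge, and three expansive blocks using 2x2
transposed-convolution upsampling with skip concatenation; a final 1x1
convolution maps to a single sigmoid channel.  Channels double per level
(base 64: 64/128/256, bridge 512); with batch-normalization scale, offset
and moving statistics included, the full variant has exactly 7,708,609
parameters.

Training minimizes a soft Jaccard loss

    J(G, D) = 1 - (|G n D| + eps) / (|G u D| + eps)

with |G n D| = sum(G*D) and |G u D| = sum(G) + sum(D) - sum(G*D); Glorot
uniform initialization with zero biases, Adam (batch 4, lr 1e-3), and
flip/zoom/translate/rotate augmentation after an 80/20 image split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.measure import label as cc_label

from . import nn
from .augment import segmenter_augment
from .types import AnnotatedImage

log = logging.getLogger(__name__)


@dataclass
class SegmenterArch:
    depth: int = 3
    base_width: int = 64
    input_channels: int = 3
    dropout: float = 0.25
    narrow: bool = False  # constant-width variant (all blocks base_width, bridge 2x)

    def widths(self) -> list[int]:
        if self.narrow:
            return [self.base_width] * self.depth + [2 * self.base_width]
        return [self.base_width * 2 ** i for i in range(self.depth + 1)]


@dataclass
class SegmenterTrainConfig:
    batch_size: int = 4
    learning_rate: float = 1e-3
    iterations: int = 300
    split_fraction: float = 0.8
    flip_prob: float = 0.5
    zoom_max: float = 1.2
    translate_frac: float = 0.05
    rotation_deg: float = 15.0
    threshold: float = 0.5
    jaccard_eps: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


def jaccard_loss(G: np.ndarray, D: np.ndarray, eps: float = 1.0) -> float:
    """Soft Jaccard loss between ground truth G and prediction D in [0, 1]."""
    G = np.asarray(G, dtype=float)
    D = np.asarray(D, dtype=float)
    if G.shape != D.shape:
        raise ValueError(f"shape mismatch {G.shape} vs {D.shape}")
    inter = float((G * D).sum())
    union = float(G.sum() + D.sum() - inter)
    return 1.0 - (inter + eps) / (union + eps)


def _jaccard_grad(G: np.ndarray, D: np.ndarray, eps: float = 1.0) -> np.ndarray:
    """d loss / d D for the soft Jaccard loss."""
    inter = float((G * D).sum())
    union = float(G.sum() + D.sum() - inter)
    # d inter/dD = G ; d union/dD = 1 - G
    return -(G * (union + eps) - (inter + eps) * (1.0 - G)) / (union + eps) ** 2


class _EncBlock(nn.Layer):
    def __init__(self, c_in, c_out, dropout, rng, with_dropout):
        layers = [
            nn.Conv2d(c_in, c_out, k=3, rng=rng), nn.BatchNorm2d(c_out), nn.ReLU(),
            nn.Conv2d(c_out, c_out, k=3, rng=rng), nn.BatchNorm2d(c_out), nn.ReLU(),
        ]
        if with_dropout and dropout > 0:
            layers.append(nn.Dropout(dropout, rng=rng))
        self.seq = nn.Sequential(*layers)

    def params(self):
        return self.seq.params()

    def buffers(self):
        return self.seq.buffers()

    def forward(self, x, train=False):
        return self.seq.forward(x, train=train)

    def backward(self, grad):
        return self.seq.backward(grad)


class SegmenterModel:
    def __init__(self, arch: SegmenterArch, seed: int = 0):
        self.arch = arch
        rng = np.random.default_rng(seed)
        w = arch.widths()
        c_in = arch.input_channels
        self.encoders = []
        for i in range(arch.depth):
            self.encoders.append(_EncBlock(c_in, w[i], arch.dropout, rng, True))
            c_in = w[i]
        self.pools = [nn.MaxPool2x2() for _ in range(arch.depth)]
        self.bridge = _EncBlock(c_in, w[-1], arch.dropout, rng, True)
        self.ups = []
        self.decoders = []
        c = w[-1]
        for i in reversed(range(arch.depth)):
            self.ups.append(nn.ConvTranspose2x2(c, w[i], rng=rng))
            self.decoders.append(_EncBlock(2 * w[i], w[i], arch.dropout, rng, False))
            c = w[i]
        self.final = nn.Conv2d(c, 1, k=1, rng=rng, pad=0)
        self.out_act = nn.Sigmoid()

    def _modules(self):
        return self.encoders + [self.bridge] + self.ups + self.decoders + [self.final]

    def params(self):
        return [p for m in self._modules() for p in m.params()]

    def buffers(self):
        return [b for m in self._modules() for b in m.buffers()]

    @property
    def parameter_count(self) -> int:
        """All parameters including batch-normalization moving statistics."""
        n = sum(p.size for p in self.params())
        n += sum(int(b.size) for b in self.buffers())
        return n

    def _pad_input(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        div = 2 ** self.arch.depth
        h, w = x.shape[1:3]
        ph = (div - h % div) % div
        pw = (div - w % div) % div
        if ph or pw:
            log.info("input %dx%d padded symmetrically to a multiple of %d", h, w, div)
            x = np.pad(x, ((0, 0), (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2),
                           (0, 0)), mode="edge")
        return x, (ph, pw)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, H, W, C) in [0,1] -> (N, H, W) probability map."""
        x, (ph, pw) = self._pad_input(x.astype(np.float32))
        skips = []
        for enc, pool in zip(self.encoders, self.pools):
            x = enc.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bridge.forward(x, train)
        self._concat_channels = []
        for up, dec, skip in zip(self.ups, self.decoders, reversed(skips)):
            x = up.forward(x, train)
            self._concat_channels.append((skip.shape[-1], x.shape[-1]))
            x = np.concatenate([skip, x], axis=-1)
            x = dec.forward(x, train)
        y = self.out_act.forward(self.final.forward(x, train), train)[..., 0]
        if ph or pw:
            h = y.shape[1] - ph
            w = y.shape[2] - pw
            y = y[:, ph // 2:ph // 2 + h, pw // 2:pw // 2 + w]
        self._pad = (ph, pw)
        return y

    def backward(self, grad: np.ndarray) -> None:
        ph, pw = self._pad
        if ph or pw:
            grad = np.pad(grad, ((0, 0), (ph // 2, ph - ph // 2),
                                 (pw // 2, pw - pw // 2)))
        g = self.final.backward(self.out_act.backward(grad[..., None].astype(np.float32)))
        # decoders[j] consumed the skip from encoders[depth-1-j]; walk them in
        # reverse application order and collect per-encoder skip gradients
        skip_grads: dict[int, np.ndarray] = {}
        for j in reversed(range(len(self.decoders))):
            g = self.decoders[j].backward(g)
            c_skip, _ = self._concat_channels[j]
            skip_grads[len(self.encoders) - 1 - j] = g[..., :c_skip]
            g = self.ups[j].backward(np.ascontiguousarray(g[..., c_skip:]))
        g = self.bridge.backward(g)
        for i in reversed(range(len(self.encoders))):
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            g = self.encoders[i].backward(g)


def build_segmenter(arch: SegmenterArch | None = None, seed: int = 0) -> SegmenterModel:
    return SegmenterModel(arch or SegmenterArch(), seed=seed)


def count_parameters_closed_form(arch: SegmenterArch) -> int:
    """Analytic layer-by-layer count: conv k^2*cin*cout + cout, BN 4c,
    transposed conv 4*cin*cout + cout, final 1x1 cin+1."""
    w = arch.widths()
    total = 0

    def conv(k, cin, cout):
        return k * k * cin * cout + cout

    def block(cin, cout):
        return conv(3, cin, cout) + 4 * cout + conv(3, cout, cout) + 4 * cout

    cin = arch.input_channels
    for i in range(arch.depth):
        total += block(cin, w[i])
        cin = w[i]
    total += block(cin, w[-1])
    c = w[-1]
    for i in reversed(range(arch.depth)):
        total += 4 * c * w[i] + w[i]          # transposed conv 2x2
        total += block(2 * w[i], w[i])
        c = w[i]
    total += conv(1, c, 1)
    return total


def train_segmenter(dataset: list[AnnotatedImage], cfg: SegmenterTrainConfig,
                    arch: SegmenterArch | None = None) -> tuple[SegmenterModel, dict]:
    """Minimize the soft Jaccard loss on an 80/20 split made before augmentation."""
    usable = [im for im in dataset if im.taproot_mask is not None]
    if len(usable) < 2:
        raise ValueError("need at least 2 images with taproot masks")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(usable))
    n_train = max(1, int(round(cfg.split_fraction * len(usable))))
    train_set = [usable[i] for i in order[:n_train]]
    test_set = [usable[i] for i in order[n_train:]]
    if sum(int(im.taproot_mask.sum()) for im in train_set) == 0:
        raise ValueError("all-background masks in the training split")

    model = build_segmenter(arch or SegmenterArch(base_width=8), seed=cfg.seed)
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    trace = []
    for it in range(cfg.iterations):
        idx = rng.integers(0, len(train_set), size=cfg.batch_size)
        opt.zero_grad()
        batch_loss = 0.0
        for i in idx:
            im = train_set[i]
            pixels, mask = segmenter_augment(
                rng, im.pixels, im.taproot_mask, flip_p=cfg.flip_prob,
                zoom_max=cfg.zoom_max, translate_frac=cfg.translate_frac,
                rot_deg=cfg.rotation_deg)
            x = pixels.astype(np.float32)[None] / 255.0
            g = mask.astype(np.float32)[None]
            d = model.forward(x, train=True)
            loss = jaccard_loss(g, d, eps=cfg.jaccard_eps)
            if not np.isfinite(loss):
                raise ArithmeticError(f"non-finite loss at iteration {it}")
            batch_loss += loss
            model.backward(_jaccard_grad(g, d, eps=cfg.jaccard_eps).astype(np.float32))
        opt.step()
        trace.append(batch_loss / cfg.batch_size)
        if (it + 1) % 50 == 0:
            log.info("segmenter iter %d/%d loss %.4f", it + 1, cfg.iterations, trace[-1])
    return model, {
        "loss_trace": trace,
        "train_ids": [im.image_id for im in train_set],
        "test_ids": [im.image_id for im in test_set],
    }


def segment_taproot(model: SegmenterModel, image: np.ndarray, threshold: float = 0.5,
                    largest_component_only: bool = True) -> np.ndarray:
    """Probability map thresholded to a binary mask (optionally largest CC only)."""
    x = np.asarray(image, dtype=np.float32)[None] / 255.0
    prob = model.forward(x, train=False)[0]
    mask = (prob >= threshold).astype(np.uint8) if threshold > 0 else np.ones_like(
        prob, dtype=np.uint8)
    if threshold >= 1:
        mask = np.zeros_like(mask)
    if largest_component_only and mask.any():
        lab = cc_label(mask, connectivity=2)
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        mask = (lab == sizes.argmax()).astype(np.uint8)
    return mask


def save_segmenter(model: SegmenterModel, path: str | Path) -> None:
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    arrays.update({f"b{i}": b for i, b in enumerate(model.buffers())})
    meta = {"depth": model.arch.depth, "base_width": model.arch.base_width,
            "input_channels": model.arch.input_channels,
            "dropout": model.arch.dropout, "narrow": model.arch.narrow}
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_segmenter(path: str | Path) -> SegmenterModel:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(bytes(data["__meta__"]).decode())
    model = build_segmenter(SegmenterArch(**meta))
    for i, p in enumerate(model.params()):
        p.value[...] = data[f"p{i}"]
    for i, b in enumerate(model.buffers()):
        b[...] = data[f"b{i}"]
    return model
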