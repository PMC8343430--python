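"""Dense single-class nodule detector.

A pyramid backbone feeds two weight-shared subnetworks: a classification
head ending in a per-anchor sigmoid and a box-regression head predicting
four offsets per anchor.  Training uses focal loss for classification,

    FL(p_t) = -alpha_t (1 - p_t)^gamma log(p_t),

with alpha_t = alpha for foreground anchors and 1 - alpha for background,
and smooth-L1 loss on box offsets with transition point 1/9.  The final
classification bias is initialized to -log((1 - pi)/pi) so every anchor
starts with foreground confidence pi (default 0.01), which keeps the focal
loss of the dense background finite at the first iterations.

Whole-image inference runs on 256 x 256 tiles (images are padded on the
right/bottom to multiples of 256), tile detections are mapped back to
image coordinates, merged, and de-duplicated with non-maximum suppression.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .anchors import AnchorConfig, default_anchors
from .augment import detector_augment
from .types import AnnotatedImage, BoundingBox, Detection

log = logging.getLogger(__name__)

TILE = 256
EPS = 1e-7


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FocalLossParams:
    alpha: float = 0.25
    gamma: float = 2.0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass(frozen=True)
class BoxLossParams:
    transition: float = 1.0 / 9.0

    def __post_init__(self):
        if self.transition <= 0:
            raise ValueError("transition must be > 0")


def focal_loss(p, y, params: FocalLossParams = FocalLossParams()):
    """Per-element focal loss on probabilities; y is 0/1."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities outside [0, 1]")
    pc = np.clip(p, EPS, 1 - EPS)
    pt = np.where(y == 1, pc, 1 - pc)
    at = np.where(y == 1, params.alpha, 1 - params.alpha)
    return -at * (1 - pt) ** params.gamma * np.log(pt)


def smooth_l1(x, params: BoxLossParams = BoxLossParams()):
    """Standard smooth-L1: 0.5 x^2 / t for |x| <= t, |x| - 0.5 t otherwise."""
    x = np.asarray(x, dtype=float)
    t = params.transition
    ax = np.abs(x)
    return np.where(ax <= t, 0.5 * x * x / t, ax - 0.5 * t)


def _focal_grad_logits(logits, targets, alpha, gamma):
    """Focal loss value and gradient w.r.t. logits; targets in {1, 0, -1=ignore}."""
    z = np.clip(logits, -30, 30)
    p = 1.0 / (1.0 + np.exp(-z))
    pc = np.clip(p, EPS, 1 - EPS)
    pos = targets == 1
    neg = targets == 0
    loss = np.zeros_like(p)
    grad = np.zeros_like(p)
    lp, lq = np.log(pc), np.log(1 - pc)
    loss[pos] = (-alpha * (1 - pc) ** gamma * lp)[pos]
    loss[neg] = (-(1 - alpha) * pc ** gamma * lq)[neg]
    grad[pos] = (alpha * gamma * pc * (1 - pc) ** gamma * lp
                 - alpha * (1 - pc) ** (gamma + 1))[pos]
    grad[neg] = ((1 - alpha) * pc ** (gamma + 1)
                 - (1 - alpha) * gamma * (1 - pc) * pc ** gamma * lq)[neg]
    return loss, grad


def _smooth_l1_grad(x, t):
    return np.where(np.abs(x) <= t, x / t, np.sign(x))


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------

@dataclass
class DetectorTrainConfig:
    anchor_config: AnchorConfig | None = None
    prior_pi: float = 0.01
    subnet_init_sigma: float = 0.001
    learning_rate: float = 1e-3
    iterations: int = 300
    batch_size: int = 8
    input_scale: int = 256
    split_fraction: float = 0.8
    flip_prob: float = 0.5
    rot_shear_rad: float = 0.1
    scale_translate: float = 0.1
    pos_iou: float = 0.5
    neg_iou: float = 0.4
    focal: FocalLossParams = field(default_factory=FocalLossParams)
    box_loss: BoxLossParams = field(default_factory=BoxLossParams)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.input_scale % 32 != 0:
            raise ValueError("input_scale must be a multiple of 32")


class _Upsample2xNearest(nn.Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, grad):
        n, h, w, c = self._shape
        g = grad.reshape(n, h, 2, w, 2, c)
        return g.sum(axis=(2, 4)).astype(np.float32)


class _ConvBNReLU(nn.Layer):
    def __init__(self, c_in, c_out, k=3, stride=1, rng=None, pad="same"):
        self.seq = nn.Sequential(
            nn.Conv2d(c_in, c_out, k=k, stride=stride, rng=rng,
                      pad=(k // 2 if stride != 1 else pad)),
            nn.BatchNorm2d(c_out),
            nn.ReLU(),
        )

    def params(self):
        return self.seq.params()

    def buffers(self):
        return self.seq.buffers()

    def forward(self, x, train=False):
        return self.seq.forward(x, train=train)

    def backward(self, grad):
        return self.seq.backward(grad)


class _Bottleneck(nn.Layer):
    """ResNet bottleneck: 1x1 reduce, 3x3, 1x1 expand, additive shortcut."""

    def __init__(self, c_in, c_mid, c_out, stride=1, rng=None):
        self.conv1 = nn.Conv2d(c_in, c_mid, k=1, rng=rng, pad=0)
        self.bn1 = nn.BatchNorm2d(c_mid)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(c_mid, c_mid, k=3, stride=stride, rng=rng,
                               pad=1 if stride != 1 else "same")
        self.bn2 = nn.BatchNorm2d(c_mid)
        self.relu2 = nn.ReLU()
        self.conv3 = nn.Conv2d(c_mid, c_out, k=1, rng=rng, pad=0)
        self.bn3 = nn.BatchNorm2d(c_out)
        self.relu3 = nn.ReLU()
        self.shortcut = None
        if stride != 1 or c_in != c_out:
            self.shortcut = nn.Sequential(
                nn.Conv2d(c_in, c_out, k=1, stride=stride, rng=rng, pad=0),
                nn.BatchNorm2d(c_out),
            )

    def params(self):
        ps = (self.conv1.params() + self.bn1.params() + self.conv2.params()
              + self.bn2.params() + self.conv3.params() + self.bn3.params())
        if self.shortcut:
            ps += self.shortcut.params()
        return ps

    def buffers(self):
        bs = self.bn1.buffers() + self.bn2.buffers() + self.bn3.buffers()
        if self.shortcut:
            bs += self.shortcut.buffers()
        return bs

    def forward(self, x, train=False):
        y = self.relu1(self.bn1(self.conv1(x, train), train), train)
        y = self.relu2(self.bn2(self.conv2(y, train), train), train)
        y = self.bn3(self.conv3(y, train), train)
        s = self.shortcut.forward(x, train) if self.shortcut else x
        return self.relu3(y + s, train)

    def backward(self, grad):
        g = self.relu3.backward(grad)
        gm = self.bn3.backward(g)
        gm = self.conv3.backward(gm)
        gm = self.relu2.backward(gm)
        gm = self.bn2.backward(gm)
        gm = self.conv2.backward(gm)
        gm = self.relu1.backward(gm)
        gm = self.bn1.backward(gm)
        gm = self.conv1.backward(gm)
        gs = self.shortcut.backward(g) if self.shortcut else g
        return gm + gs


class TinyBackbone(nn.Layer):
    """Three stride-2 stages producing one stride-8 feature map (32 channels)."""

    out_channels = 32
    strides = (8,)

    def __init__(self, rng):
        self.blocks = nn.Sequential(
            _ConvBNReLU(3, 8, rng=rng), nn.MaxPool2x2(),
            _ConvBNReLU(8, 16, rng=rng), nn.MaxPool2x2(),
            _ConvBNReLU(16, 32, rng=rng), nn.MaxPool2x2(),
        )

    def params(self):
        return self.blocks.params()

    def buffers(self):
        return self.blocks.buffers()

    def forward(self, x, train=False):
        return [self.blocks.forward(x, train=train)]

    def backward(self, grads):
        return self.blocks.backward(grads[0])


class ResNet50FPN(nn.Layer):
    """50-layer residual pyramid backbone with a 256-channel feature pyramid.

    Emits P3..P7 (strides 8..128).
    """

    out_channels = 256
    strides = (8, 16, 32, 64, 128)

    def __init__(self, rng):
        self.stem = _ConvBNReLU(3, 64, k=7, stride=2, rng=rng, pad="same")
        self.stem.seq.layers[0].pad = 3
        self.pool = nn.MaxPool2x2()

        def stage(n, c_in, c_mid, c_out, stride):
            blocks = [_Bottleneck(c_in, c_mid, c_out, stride=stride, rng=rng)]
            blocks += [_Bottleneck(c_out, c_mid, c_out, rng=rng) for _ in range(n - 1)]
            return blocks

        self.c2 = stage(3, 64, 64, 256, 1)
        self.c3 = stage(4, 256, 128, 512, 2)
        self.c4 = stage(6, 512, 256, 1024, 2)
        self.c5 = stage(3, 1024, 512, 2048, 2)
        self.lat3 = nn.Conv2d(512, 256, k=1, rng=rng, pad=0)
        self.lat4 = nn.Conv2d(1024, 256, k=1, rng=rng, pad=0)
        self.lat5 = nn.Conv2d(2048, 256, k=1, rng=rng, pad=0)
        self.out3 = nn.Conv2d(256, 256, k=3, rng=rng)
        self.out4 = nn.Conv2d(256, 256, k=3, rng=rng)
        self.out5 = nn.Conv2d(256, 256, k=3, rng=rng)
        self.p6 = nn.Conv2d(2048, 256, k=3, stride=2, rng=rng, pad=1)
        self.p7_relu = nn.ReLU()
        self.p7 = nn.Conv2d(256, 256, k=3, stride=2, rng=rng, pad=1)
        self.up4 = _Upsample2xNearest()
        self.up3 = _Upsample2xNearest()

    def _modules(self):
        return ([self.stem] + self.c2 + self.c3 + self.c4 + self.c5
                + [self.lat3, self.lat4, self.lat5, self.out3, self.out4,
                   self.out5, self.p6, self.p7])

    def params(self):
        return [p for m in self._modules() for p in m.params()]

    def buffers(self):
        return [b for m in self._modules() for b in m.buffers()]

    def forward(self, x, train=False):
        y = self.pool.forward(self.stem.forward(x, train), train)
        for b in self.c2:
            y = b.forward(y, train)
        c3 = y
        for b in self.c3:
            c3 = b.forward(c3, train)
        c4 = c3
        for b in self.c4:
            c4 = b.forward(c4, train)
        c5 = c4
        for b in self.c5:
            c5 = b.forward(c5, train)
        m5 = self.lat5.forward(c5, train)
        m4 = self.lat4.forward(c4, train) + self.up4.forward(m5, train)
        m3 = self.lat3.forward(c3, train) + self.up3.forward(m4, train)
        p3 = self.out3.forward(m3, train)
        p4 = self.out4.forward(m4, train)
        p5 = self.out5.forward(m5, train)
        p6 = self.p6.forward(c5, train)
        p7 = self.p7.forward(self.p7_relu.forward(p6, train), train)
        return [p3, p4, p5, p6, p7]

    def backward(self, grads):
        g3, g4, g5, g6, g7 = grads
        g6 = g6 + self.p7_relu.backward(self.p7.backward(g7))
        gc5_from_p6 = self.p6.backward(g6)
        m3g = self.out3.backward(g3)
        m4g = self.out4.backward(g4) + self.up3.backward(m3g)
        m5g = self.out5.backward(g5) + self.up4.backward(m4g)
        gc3 = self.lat3.backward(m3g)
        gc4 = self.lat4.backward(m4g)
        gc5 = self.lat5.backward(m5g) + gc5_from_p6
        for b in reversed(self.c5):
            gc5 = b.backward(gc5)
        gc4 = gc4 + gc5
        for b in reversed(self.c4):
            gc4 = b.backward(gc4)
        gc3 = gc3 + gc4
        for b in reversed(self.c3):
            gc3 = b.backward(gc3)
        g = gc3
        for b in reversed(self.c2):
            g = b.backward(g)
        return self.stem.backward(self.pool.backward(g))


class _Head(nn.Layer):
    """Weight-shared detection subnetwork applied to every pyramid level."""

    def __init__(self, c_in, width, n_layers, n_out, rng, sigma, final_bias):
        layers = []
        c = c_in
        for _ in range(n_layers):
            layers += [nn.Conv2d(c, width, k=3, rng=rng, init="normal",
                                 init_sigma=sigma), nn.ReLU()]
            c = width
        self.body = nn.Sequential(*layers)
        self.final = nn.Conv2d(c, n_out, k=3, rng=rng, init="normal",
                               init_sigma=sigma, bias_init=final_bias)

    def params(self):
        return self.body.params() + self.final.params()

    def forward(self, x, train=False):
        return self.final.forward(self.body.forward(x, train), train)

    def backward(self, grad):
        return self.body.backward(self.final.backward(grad))


@dataclass
class DetectorModel:
    arch: str
    anchor_config: AnchorConfig
    backbone: nn.Layer
    cls_head: _Head
    reg_head: _Head
    head_width: int
    head_layers: int

    def params(self):
        return self.backbone.params() + self.cls_head.params() + self.reg_head.params()

    def buffers(self):
        return self.backbone.buffers()

    @property
    def parameter_count(self) -> int:
        n = sum(p.size for p in self.params())
        n += sum(int(b.size) for b in self.buffers())
        return n

    @property
    def strides(self):
        return self.backbone.strides

    def anchors_for(self, shape_hw: tuple[int, int],
                    level_shapes: list[tuple[int, int]]) -> np.ndarray:
        """(A_total, 4) anchor boxes (x0, y0, x1, y1) for the given map shapes."""
        cfg = self.anchor_config
        out = []
        for (fh, fw), stride, base in zip(level_shapes, self.strides, cfg.base_sizes):
            shapes = cfg.shapes(base)  # (a, 2) width/height
            cx = (np.arange(fw) + 0.5) * stride
            cy = (np.arange(fh) + 0.5) * stride
            gx, gy = np.meshgrid(cx, cy)
            centers = np.stack([gx, gy], axis=-1).reshape(-1, 1, 2)  # (fh*fw, 1, 2)
            wh = shapes.reshape(1, -1, 2)
            boxes = np.concatenate([centers - wh / 2, centers + wh / 2], axis=-1)
            out.append(boxes.reshape(-1, 4))
        return np.concatenate(out, axis=0)


def build_detector(anchor_config: AnchorConfig | None = None, arch: str = "tiny",
                   seed: int = 0, prior_pi: float = 0.01,
                   subnet_init_sigma: float = 0.001) -> DetectorModel:
    """Construct the detector; ``tiny`` is the desk-scale single-level variant."""
    rng = np.random.default_rng(seed)
    final_bias = -np.log((1 - prior_pi) / prior_pi)
    if arch == "full":
        cfg = anchor_config or default_anchors()
        if len(cfg.base_sizes) != 5:
            raise ValueError("full detector needs a 5-level anchor configuration")
        backbone = ResNet50FPN(rng)
        width, layers = 256, 4
    elif arch == "tiny":
        cfg = anchor_config or default_anchors(base_sizes=(16.0,), strides=(8,))
        if len(cfg.base_sizes) != 1:
            raise ValueError("tiny detector uses a single pyramid level")
        backbone = TinyBackbone(rng)
        width, layers = 32, 2
    else:
        raise ValueError(f"unknown arch {arch!r}")
    a = cfg.anchors_per_location
    cls_head = _Head(backbone.out_channels, width, layers, a, rng,
                     subnet_init_sigma, final_bias)
    reg_head = _Head(backbone.out_channels, width, layers, 4 * a, rng,
                     subnet_init_sigma, 0.0)
    return DetectorModel(arch=arch, anchor_config=cfg, backbone=backbone,
                         cls_head=cls_head, reg_head=reg_head,
                         head_width=width, head_layers=layers)


# --------------------------------------------------------------------------
# target assignment and box coding
# --------------------------------------------------------------------------

def _iou_matrix(anchors: np.ndarray, gt: np.ndarray) -> np.ndarray:
    ix0 = np.maximum(anchors[:, None, 0], gt[None, :, 0])
    iy0 = np.maximum(anchors[:, None, 1], gt[None, :, 1])
    ix1 = np.minimum(anchors[:, None, 2], gt[None, :, 2])
    iy1 = np.minimum(anchors[:, None, 3], gt[None, :, 3])
    inter = np.clip(ix1 - ix0, 0, None) * np.clip(iy1 - iy0, 0, None)
    a_area = (anchors[:, 2] - anchors[:, 0]) * (anchors[:, 3] - anchors[:, 1])
    g_area = (gt[:, 2] - gt[:, 0]) * (gt[:, 3] - gt[:, 1])
    union = a_area[:, None] + g_area[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)


def _assign(anchors: np.ndarray, gt: np.ndarray, pos_iou: float, neg_iou: float):
    """Returns (labels {1,0,-1}, matched gt index per anchor)."""
    n = anchors.shape[0]
    labels = np.zeros(n, dtype=np.int8)
    matched = np.full(n, -1, dtype=np.int64)
    if len(gt) == 0:
        return labels, matched
    iou = _iou_matrix(anchors, gt)
    best_gt = iou.argmax(axis=1)
    best_iou = iou[np.arange(n), best_gt]
    labels[best_iou >= pos_iou] = 1
    labels[(best_iou >= neg_iou) & (best_iou < pos_iou)] = -1
    matched[:] = best_gt
    # force-match the best anchor for every ground-truth box
    best_anchor = iou.argmax(axis=0)
    labels[best_anchor] = 1
    matched[best_anchor] = np.arange(len(gt))
    matched[labels != 1] = -1
    return labels, matched


def _encode(anchors: np.ndarray, gt: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    acx = anchors[:, 0] + aw / 2
    acy = anchors[:, 1] + ah / 2
    gw = gt[:, 2] - gt[:, 0]
    gh = gt[:, 3] - gt[:, 1]
    gcx = gt[:, 0] + gw / 2
    gcy = gt[:, 1] + gh / 2
    return np.stack([(gcx - acx) / aw, (gcy - acy) / ah,
                     np.log(gw / aw), np.log(gh / ah)], axis=1)


def _decode(anchors: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    acx = anchors[:, 0] + aw / 2
    acy = anchors[:, 1] + ah / 2
    cx = acx + deltas[:, 0] * aw
    cy = acy + deltas[:, 1] * ah
    w = aw * np.exp(np.clip(deltas[:, 2], -6, 6))
    h = ah * np.exp(np.clip(deltas[:, 3], -6, 6))
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def _forward_heads(model: DetectorModel, feats, train):
    """Per-level head outputs flattened to (A_total, .) plus level shapes."""
    a = model.anchor_config.anchors_per_location
    cls_maps, reg_maps, shapes = [], [], []
    for f in feats:
        cls = model.cls_head.forward(f, train)
        reg = model.reg_head.forward(f, train)
        n, fh, fw, _ = cls.shape
        shapes.append((fh, fw))
        cls_maps.append(cls.reshape(n, fh * fw * a))
        reg_maps.append(reg.reshape(n, fh * fw * a, 4))
    return cls_maps, reg_maps, shapes


def train_detector(dataset: list[AnnotatedImage], cfg: DetectorTrainConfig,
                   arch: str = "tiny") -> tuple[DetectorModel, dict]:
    """Train on an 80/20 image split (made before augmentation).

    Returns the trained model and a dict with the loss trace and the split.
    """
    if len(dataset) < 2:
        raise ValueError("need at least 2 annotated images")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(dataset))
    n_train = max(1, int(round(cfg.split_fraction * len(dataset))))
    train_set = [dataset[i] for i in order[:n_train]]
    test_set = [dataset[i] for i in order[n_train:]]
    if sum(len(im.boxes) for im in train_set) == 0:
        raise ValueError("no boxes in the training split")

    model = build_detector(cfg.anchor_config, arch=arch, seed=cfg.seed,
                           prior_pi=cfg.prior_pi,
                           subnet_init_sigma=cfg.subnet_init_sigma)
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    trace = []
    anchor_cache: dict[tuple[int, int], np.ndarray] = {}

    for it in range(cfg.iterations):
        idx = rng.integers(0, len(train_set), size=cfg.batch_size)
        opt.zero_grad()
        total_loss = 0.0
        for i in idx:
            im = train_set[i]
            pixels, boxes = detector_augment(
                rng, im.pixels, im.boxes, flip_p=cfg.flip_prob,
                rot_shear_rad=cfg.rot_shear_rad, scale_translate=cfg.scale_translate)
            x = pixels.astype(np.float32)[None] / 255.0
            feats = model.backbone.forward(x, train=True)
            cls_maps, reg_maps, shapes = _forward_heads(model, feats, train=True)
            key = (im.shape, tuple(shapes))
            if key not in anchor_cache:
                anchor_cache[key] = model.anchors_for(im.shape, shapes)
            anchors = anchor_cache[key]
            gt = np.array([b.as_tuple() for b in boxes]).reshape(-1, 4)
            labels, matched = _assign(anchors, gt, cfg.pos_iou, cfg.neg_iou)
            n_pos = max(1, int((labels == 1).sum()))

            logits = np.concatenate([c[0] for c in cls_maps])
            closs, cgrad = _focal_grad_logits(logits, labels,
                                              cfg.focal.alpha, cfg.focal.gamma)
            loss = closs.sum() / n_pos
            cgrad = cgrad / n_pos

            regs = np.concatenate([r[0] for r in reg_maps], axis=0)
            rgrad = np.zeros_like(regs)
            pos = labels == 1
            if pos.any() and len(gt):
                targets = _encode(anchors[pos], gt[matched[pos]])
                resid = regs[pos] - targets
                loss += smooth_l1(resid, cfg.box_loss).sum() / n_pos
                rgrad[pos] = _smooth_l1_grad(resid, cfg.box_loss.transition) / n_pos
            if not np.isfinite(loss):
                raise ArithmeticError(f"non-finite loss at iteration {it} image {im.image_id}")
            total_loss += float(loss)

            # backward: per-level head gradients, then the backbone
            a = model.anchor_config.anchors_per_location
            feat_grads = []
            offset = 0
            for f, (fh, fw) in zip(feats, shapes):
                na = fh * fw * a
                gc = cgrad[offset:offset + na].reshape(1, fh, fw, a).astype(np.float32)
                gr = rgrad[offset:offset + na].reshape(1, fh, fw, 4 * a).astype(np.float32)
                offset += na
                gf = model.cls_head.backward(gc)
                gf = gf + model.reg_head.backward(gr)
                feat_grads.append(gf)
            model.backbone.backward(feat_grads)
        opt.step()
        trace.append(total_loss / cfg.batch_size)
        if (it + 1) % 50 == 0:
            log.info("detector iter %d/%d loss %.4f", it + 1, cfg.iterations, trace[-1])

    return model, {
        "loss_trace": trace,
        "train_ids": [im.image_id for im in train_set],
        "test_ids": [im.image_id for im in test_set],
    }


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------

def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float = 0.5) -> list[int]:
    """Greedy non-maximum suppression; returns kept indices, score-descending."""
    order = np.argsort(-scores)
    keep = []
    while len(order):
        i = order[0]
        keep.append(int(i))
        if len(order) == 1:
            break
        rest = order[1:]
        iou = _iou_matrix(boxes[rest], boxes[i:i + 1])[:, 0]
        order = rest[iou <= iou_threshold]
    return keep


def _pad_to_tiles(image: np.ndarray, tile: int = TILE) -> np.ndarray:
    h, w = image.shape[:2]
    ph = (tile - h % tile) % tile
    pw = (tile - w % tile) % tile
    if ph == 0 and pw == 0:
        return image
    return np.pad(image, ((0, ph), (0, pw), (0, 0)), mode="edge")


def tile_grid(shape_hw: tuple[int, int], tile: int = TILE) -> list[tuple[int, int]]:
    h, w = shape_hw
    ph = int(np.ceil(h / tile)) * tile
    pw = int(np.ceil(w / tile)) * tile
    return [(y, x) for y in range(0, ph, tile) for x in range(0, pw, tile)]


def detect_nodules(model: DetectorModel, image: np.ndarray,
                   score_threshold: float = 0.3, nms_iou: float = 0.5,
                   tile: int = TILE) -> list[Detection]:
    """Tiled whole-image inference with global NMS and clipping."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("image must be a non-empty HxWx3 raster")
    h0, w0 = image.shape[:2]
    padded = _pad_to_tiles(image, tile)
    all_boxes, all_scores = [], []
    for y, x in tile_grid((h0, w0), tile):
        patch = padded[y:y + tile, x:x + tile].astype(np.float32)[None] / 255.0
        feats = model.backbone.forward(patch, train=False)
        cls_maps, reg_maps, shapes = _forward_heads(model, feats, train=False)
        anchors = model.anchors_for((tile, tile), shapes)
        logits = np.concatenate([c[0] for c in cls_maps])
        scores = 1.0 / (1.0 + np.exp(-np.clip(logits, -30, 30)))
        deltas = np.concatenate([r[0] for r in reg_maps], axis=0)
        keep = scores >= score_threshold
        if not keep.any():
            continue
        boxes = _decode(anchors[keep], deltas[keep])
        boxes[:, [0, 2]] += x
        boxes[:, [1, 3]] += y
        all_boxes.append(boxes)
        all_scores.append(scores[keep])
    if not all_boxes:
        return []
    boxes = np.concatenate(all_boxes)
    scores = np.concatenate(all_scores)
    keep = nms(boxes, scores, nms_iou)
    boxes, scores = boxes[keep], scores[keep]
    boxes[:, [0, 2]] = np.clip(boxes[:, [0, 2]], 0, w0)
    boxes[:, [1, 3]] = np.clip(boxes[:, [1, 3]], 0, h0)
    out = []
    for b, s in zip(boxes, scores):
        if b[2] - b[0] >= 1 and b[3] - b[1] >= 1:
            out.append(Detection(BoundingBox(*map(float, b)), float(min(s, 1.0))))
    return out


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def save_detector(model: DetectorModel, path: str | Path) -> None:
    path = Path(path)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    arrays.update({f"b{i}": b for i, b in enumerate(model.buffers())})
    meta = {
        "arch": model.arch,
        "anchor_config": {
            "scales": list(model.anchor_config.scales),
            "ratios": list(model.anchor_config.ratios),
            "base_sizes": list(model.anchor_config.base_sizes),
            "strides": list(model.anchor_config.strides),
        },
    }
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_detector(path: str | Path) -> DetectorModel:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(bytes(data["__meta__"]).decode())
    ac = meta["anchor_config"]
    cfg = AnchorConfig(scales=tuple(ac["scales"]), ratios=tuple(ac["ratios"]),
                       base_sizes=tuple(ac["base_sizes"]), strides=tuple(ac["strides"]))
    model = build_detector(cfg, arch=meta["arch"])
    for i, p in enumerate(model.params()):
        p.value[...] = data[f"p{i}"]
    for i, b in enumerate(model.buffers()):
        b[...] = data[f"b{i}"]
    return model
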