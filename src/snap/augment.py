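"""Random geometric augmentation shared by the detector and segmenter trainers."""

from __future__ import annotations

import numpy as np
from skimage.transform import AffineTransform, warp

from .types import BoundingBox


def _centered(tf: AffineTransform, h: int, w: int) -> AffineTransform:
    shift = AffineTransform(translation=(-w / 2, -h / 2))
    unshift = AffineTransform(translation=(w / 2, h / 2))
    return AffineTransform(matrix=unshift.params @ tf.params @ shift.params)


def _apply(image: np.ndarray, tf: AffineTransform, mask: np.ndarray | None):
    out = warp(image.astype(np.float32) / 255.0, tf.inverse, order=1, mode="edge")
    out = (out * 255.0).astype(np.uint8)
    m = None
    if mask is not None:
        m = warp(mask.astype(float), tf.inverse, order=0, mode="constant", cval=0)
        m = (m > 0.5).astype(np.uint8)
    return out, m


def _transform_boxes(boxes: list[BoundingBox], tf: AffineTransform,
                     h: int, w: int) -> list[BoundingBox]:
    out = []
    for b in boxes:
        corners = np.array([[b.x_min, b.y_min], [b.x_max, b.y_min],
                            [b.x_min, b.y_max], [b.x_max, b.y_max]])
        t = tf(corners)
        x0, y0 = t[:, 0].min(), t[:, 1].min()
        x1, y1 = t[:, 0].max(), t[:, 1].max()
        x0, x1 = np.clip([x0, x1], 0, w)
        y0, y1 = np.clip([y0, y1], 0, h)
        if x1 - x0 >= 2 and y1 - y0 >= 2:
            out.append(BoundingBox(float(x0), float(y0), float(x1), float(y1)))
    return out


def _flips(rng: np.random.Generator, h: int, w: int, p: float) -> AffineTransform:
    sx = -1.0 if rng.random() < p else 1.0
    sy = -1.0 if rng.random() < p else 1.0
    return _centered(AffineTransform(scale=(sx, sy)), h, w)


def detector_augment(rng: np.random.Generator, image: np.ndarray,
                     boxes: list[BoundingBox], flip_p: float = 0.5,
                     rot_shear_rad: float = 0.1, scale_translate: float = 0.1):
    """Flips (50%), rotation/shear up to 0.1 rad, scale/translation up to 10%."""
    h, w = image.shape[:2]
    tf = _flips(rng, h, w, flip_p)
    rot = rng.uniform(-rot_shear_rad, rot_shear_rad)
    shear = rng.uniform(-rot_shear_rad, rot_shear_rad)
    scale = 1.0 + rng.uniform(-scale_translate, scale_translate)
    tx = rng.uniform(-scale_translate, scale_translate) * w
    ty = rng.uniform(-scale_translate, scale_translate) * h
    aff = _centered(AffineTransform(rotation=rot, shear=shear,
                                    scale=(scale, scale)), h, w)
    aff = AffineTransform(matrix=AffineTransform(translation=(tx, ty)).params @ aff.params)
    tf = AffineTransform(matrix=aff.params @ tf.params)
    out, _ = _apply(image, tf, None)
    return out, _transform_boxes(boxes, tf, h, w)


def segmenter_augment(rng: np.random.Generator, image: np.ndarray, mask: np.ndarray,
                      flip_p: float = 0.5, zoom_max: float = 1.2,
                      translate_frac: float = 0.05, rot_deg: float = 15.0):
    """Flips, zoom up to 120%, translation up to 5%, rotation up to 15 degrees."""
    h, w = image.shape[:2]
    tf = _flips(rng, h, w, flip_p)
    zoom = rng.uniform(1.0, zoom_max)
    rot = np.deg2rad(rng.uniform(-rot_deg, rot_deg))
    tx = rng.uniform(-translate_frac, translate_frac) * w
    ty = rng.uniform(-translate_frac, translate_frac) * h
    aff = _centered(AffineTransform(rotation=rot, scale=(zoom, zoom)), h, w)
    aff = AffineTransform(matrix=AffineTransform(translation=(tx, ty)).params @ aff.params)
    tf = AffineTransform(matrix=aff.params @ tf.params)
    return _apply(image, tf, mask)
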