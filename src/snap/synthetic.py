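"""Synthetic washed-root scene generator with exact ground truth.

Scenes emulate the structure of washed-root tray photographs: a uniform
blue tray background with an illumination gradient, one curved taproot
running top to bottom, thinner lateral roots branching off it, near-circular
nodules attached to the roots, and optional smaller, paler cyst-like
distractor objects that are rendered but never labelled as nodules.

Every scene carries exact ground truth: tight nodule bounding boxes, a
binary taproot mask that is by construction the rasterization of the
taproot centerline with its width profile, per-nodule on-taproot labels,
and the ordered centerline polyline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .types import AnnotatedImage, BoundingBox

log = logging.getLogger(__name__)

_REFERENCE_WIDTH = 1024  # px; length-valued defaults below are stated at this canvas width


@dataclass
class SceneParams:
    """Scene generation parameters.

    All length-valued defaults are calibrated for a 1024-wide canvas and
    are rescaled proportionally by :meth:`for_canvas`.
    """

    image_size: tuple[int, int] = (768, 1024)  # (height, width)
    # taproot geometry
    taproot_amplitude: float = 40.0      # px lateral deviation of the centerline
    taproot_wavelength: float = 900.0    # px vertical wavelength of the deviation
    taproot_top_width: float = 22.0      # px width at the soil line (top)
    taproot_taper: float = 0.65          # fraction of top width lost by the bottom
    # laterals
    n_laterals: int = 8
    lateral_width: float = 5.0
    # nodules: counts are negative-binomial, radii log-normal
    # at the 1024-wide reference canvas of a 50 cm tray, 1 px is ~0.5 mm, so
    # typical 2-5 mm nodules have pixel radii ~2-6; median 5 px = ~5 mm diameter
    nodule_count_mean: float = 40.0
    nodule_count_dispersion: float = 2.0
    nodule_radius_median: float = 5.0
    nodule_radius_log_sd: float = 0.30
    taproot_zone_fraction: float = 0.5
    # distractors (cyst-like objects)
    n_distractors: int = 2
    # appearance
    background_color: tuple[int, int, int] = (68, 105, 155)
    root_color: tuple[int, int, int] = (205, 185, 152)
    nodule_color: tuple[int, int, int] = (150, 110, 72)
    distractor_color: tuple[int, int, int] = (218, 208, 152)
    illumination_gradient: float = 0.15
    noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.nodule_count_mean < 0 or self.n_laterals < 0 or self.n_distractors < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.taproot_zone_fraction <= 1.0:
            raise ValueError("taproot_zone_fraction must lie in [0, 1]")
        for name in ("taproot_wavelength", "taproot_top_width",
                     "nodule_radius_median", "nodule_radius_log_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def for_canvas(cls, height: int, width: int, **overrides) -> "SceneParams":
        """Defaults rescaled so geometry keeps its proportions on any canvas."""
        s = width / _REFERENCE_WIDTH
        base = cls()
        scaled = dict(
            image_size=(height, width),
            taproot_amplitude=base.taproot_amplitude * s,
            taproot_wavelength=base.taproot_wavelength * s,
            taproot_top_width=max(3.0, base.taproot_top_width * s),
            lateral_width=max(2.0, base.lateral_width * s),
            nodule_radius_median=max(3.0, base.nodule_radius_median * s),
        )
        scaled.update(overrides)
        return replace(base, **scaled)


@dataclass
class SyntheticScene:
    annotated: AnnotatedImage
    on_taproot: list[bool]
    distractor_boxes: list[BoundingBox] = field(default_factory=list)
    taproot_polyline: np.ndarray | None = None  # (N, 2) of (x, y), top to bottom
    nodule_radii: list[float] = field(default_factory=list)  # sampled radii, px


class GenerationError(RuntimeError):
    pass


def _taproot_centerline(p: SceneParams, rng) -> tuple[np.ndarray, np.ndarray]:
    h, w = p.image_size
    y = np.arange(h, dtype=np.float64)
    phase = rng.uniform(0, 2 * np.pi)
    x0 = w / 2 + rng.uniform(-0.05, 0.05) * w
    tilt = rng.uniform(-0.04, 0.04)
    x = x0 + tilt * y + p.taproot_amplitude * np.sin(2 * np.pi * y / p.taproot_wavelength + phase)
    margin = p.taproot_top_width
    return np.clip(x, margin, w - 1 - margin), y


def _taproot_halfwidth(p: SceneParams, y: np.ndarray) -> np.ndarray:
    h = p.image_size[0]
    width = p.taproot_top_width * (1.0 - p.taproot_taper * y / max(h - 1, 1))
    return np.maximum(width, 2.0) / 2.0


def _rasterize_taproot(p: SceneParams, cx: np.ndarray, hw: np.ndarray) -> np.ndarray:
    """Row-wise interval fill of the centerline with its width profile."""
    h, w = p.image_size
    mask = np.zeros((h, w), dtype=np.uint8)
    lo = np.clip(np.round(cx - hw).astype(int), 0, w - 1)
    hi = np.clip(np.round(cx + hw).astype(int), 0, w - 1)
    for y in range(h):
        mask[y, lo[y]:hi[y] + 1] = 1
    return mask


def _lateral_polyline(p: SceneParams, rng, cx: np.ndarray) -> np.ndarray:
    """A lateral root polyline starting on the taproot, bending downward."""
    h, w = p.image_size
    y0 = rng.uniform(0.08, 0.8) * h
    x0 = np.interp(y0, np.arange(h), cx)
    side = rng.choice([-1.0, 1.0])
    angle = rng.uniform(np.deg2rad(15), np.deg2rad(65))  # below horizontal
    length = rng.uniform(0.15, 0.45) * w
    bend = rng.uniform(0.2, 0.9)
    t = np.arange(0.0, length, 1.0)
    x = x0 + side * np.cos(angle) * t
    y = y0 + np.sin(angle) * t + bend * (t / max(length, 1)) ** 2 * 0.3 * length
    keep = (x >= 1) & (x < w - 1) & (y >= 1) & (y < h - 1)
    pts = np.stack([x[keep], y[keep]], axis=1)
    return pts


def _stamp_disks(layer_mask: np.ndarray, pts: np.ndarray, radii: np.ndarray) -> None:
    h, w = layer_mask.shape
    for (x, y), r in zip(pts, radii):
        ri = int(np.ceil(r))
        x0, x1 = int(x) - ri, int(x) + ri + 1
        y0, y1 = int(y) - ri, int(y) + ri + 1
        xs = np.arange(max(x0, 0), min(x1, w))
        ys = np.arange(max(y0, 0), min(y1, h))
        if xs.size == 0 or ys.size == 0:
            continue
        gx, gy = np.meshgrid(xs, ys)
        inside = ((gx - x) ** 2 + (gy - y) ** 2) <= r * r
        layer_mask[gy[inside], gx[inside]] = 1


def _render_ellipse(h: int, w: int, cx: float, cy: float, a: float, b: float,
                    theta: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Filled rotated ellipse; returns (ys, xs, none) index arrays of its pixels."""
    rmax = max(a, b) + 2
    x0, x1 = max(int(cx - rmax), 0), min(int(cx + rmax) + 1, w)
    y0, y1 = max(int(cy - rmax), 0), min(int(cy + rmax) + 1, h)
    xs = np.arange(x0, x1)
    ys = np.arange(y0, y1)
    gx, gy = np.meshgrid(xs, ys)
    dx, dy = gx - cx, gy - cy
    c, s = np.cos(theta), np.sin(theta)
    u = (dx * c + dy * s) / a
    v = (-dx * s + dy * c) / b
    inside = u * u + v * v <= 1.0
    return gy[inside], gx[inside], inside


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Render one scene; deterministic given ``params.seed``."""
    p = params
    h, w = p.image_size
    rng = np.random.default_rng(p.seed)

    # --- background with illumination gradient ------------------------------
    bg = np.array(p.background_color, dtype=np.float64)
    img = np.ones((h, w, 3), dtype=np.float64) * bg
    if p.illumination_gradient > 0:
        ang = rng.uniform(0, 2 * np.pi)
        gx, gy = np.meshgrid(np.linspace(-0.5, 0.5, w), np.linspace(-0.5, 0.5, h))
        ramp = 1.0 + p.illumination_gradient * (np.cos(ang) * gx + np.sin(ang) * gy)
        img *= ramp[..., None]

    # --- roots --------------------------------------------------------------
    cx, yy = _taproot_centerline(p, rng)
    hw = _taproot_halfwidth(p, yy)
    taproot_mask = _rasterize_taproot(p, cx, hw)

    root_layer = np.zeros((h, w), dtype=np.uint8)
    lateral_lines: list[np.ndarray] = []
    for _ in range(p.n_laterals):
        pts = _lateral_polyline(p, rng, cx)
        if len(pts) < 5:
            continue
        lateral_lines.append(pts)
        frac = np.linspace(1.0, 0.35, len(pts))
        _stamp_disks(root_layer, pts, frac * p.lateral_width / 2.0)
    root_layer |= taproot_mask

    root_col = np.array(p.root_color, dtype=np.float64) * rng.uniform(0.95, 1.05)
    img[root_layer > 0] = root_col

    # --- nodules ------------------------------------------------------------
    mean, k = p.nodule_count_mean, p.nodule_count_dispersion
    if mean <= 0:
        n_nodules = 0
    else:
        n_nodules = int(rng.negative_binomial(k, k / (k + mean)))

    polyline = np.stack([cx, yy], axis=1)
    centers: list[tuple[float, float, float]] = []  # (x, y, r)
    boxes: list[BoundingBox] = []
    on_taproot: list[bool] = []
    max_r = min(h, w) / 4.0

    def _sample_radius():
        r = float(rng.lognormal(np.log(p.nodule_radius_median), p.nodule_radius_log_sd))
        while r > max_r:
            log.warning("nodule radius %.1f exceeds min(image dims)/4; resampled", r)
            r = float(rng.lognormal(np.log(p.nodule_radius_median), p.nodule_radius_log_sd))
        return r

    # the attachment class (taproot vs lateral) is drawn once per nodule so
    # the on-taproot count is exactly binomial; placement retries stay within
    # the drawn class and so cannot bias the fraction
    for _ in range(n_nodules):
        want_tap = bool(rng.random() < p.taproot_zone_fraction) or not lateral_lines
        for _attempt in range(500):
            if want_tap:
                i = int(rng.integers(int(0.03 * h), h))
                ax_, ay_ = cx[i], yy[i]
                local_hw = hw[i]
            else:
                line = lateral_lines[int(rng.integers(len(lateral_lines)))]
                j = int(rng.integers(len(line)))
                ax_, ay_ = line[j]
                local_hw = p.lateral_width / 2.0
            r = _sample_radius()
            # nodules bulge from the root flank: center offset about the
            # local half-width plus a fraction of the nodule radius
            off = local_hw * rng.uniform(0.2, 1.0) + r * rng.uniform(0.2, 0.7)
            ang = rng.uniform(0, 2 * np.pi)
            nx, ny = ax_ + off * np.cos(ang), ay_ + off * np.sin(ang)
            if not (r + 1 <= nx < w - r - 1 and r + 1 <= ny < h - r - 1):
                continue
            if any((nx - ox) ** 2 + (ny - oy) ** 2 < (r + orr) ** 2
                   for ox, oy, orr in centers):
                continue
            a = r * rng.uniform(0.85, 1.15)
            b = r * rng.uniform(0.85, 1.15)
            theta = rng.uniform(0, np.pi)
            ys, xs, _ = _render_ellipse(h, w, nx, ny, a, b, theta)
            if len(xs) == 0:
                continue
            col = np.array(p.nodule_color, dtype=np.float64) * rng.uniform(0.85, 1.1)
            img[ys, xs] = col
            boxes.append(BoundingBox(float(xs.min()), float(ys.min()),
                                     float(xs.max() + 1), float(ys.max() + 1)))
            on_taproot.append(want_tap)
            centers.append((nx, ny, r))
            break
        else:
            raise GenerationError(
                "could not place a nodule without overlap; nodule_count_mean "
                "or nodule_radius_median too large for the canvas"
            )

    # --- distractors (cyst-like): smaller, paler, never in the box list -----
    distractor_boxes: list[BoundingBox] = []
    for _ in range(p.n_distractors):
        for _try in range(200):
            if lateral_lines and rng.random() < 0.5:
                line = lateral_lines[int(rng.integers(len(lateral_lines)))]
                j = int(rng.integers(len(line)))
                ax_, ay_ = line[j]
            else:
                i = int(rng.integers(h))
                ax_, ay_ = cx[i], yy[i]
            r = 0.45 * p.nodule_radius_median * rng.uniform(0.7, 1.3)
            nx = ax_ + rng.uniform(-2, 2)
            ny = ay_ + rng.uniform(-2, 2)
            if not (r + 1 <= nx < w - r - 1 and r + 1 <= ny < h - r - 1):
                continue
            if any((nx - ox) ** 2 + (ny - oy) ** 2 < (r + orr) ** 2 for ox, oy, orr in centers):
                continue
            theta = rng.uniform(0, np.pi)
            ys, xs, _ = _render_ellipse(h, w, nx, ny, r, 0.65 * r, theta)
            if len(xs) == 0:
                continue
            col = np.array(p.distractor_color, dtype=np.float64) * rng.uniform(0.9, 1.05)
            img[ys, xs] = col
            distractor_boxes.append(BoundingBox(float(xs.min()), float(ys.min()),
                                                float(xs.max() + 1), float(ys.max() + 1)))
            centers.append((nx, ny, r))
            break

    # --- sensor noise -------------------------------------------------------
    if p.noise_sd > 0:
        img += rng.normal(0, p.noise_sd, size=img.shape)
    pixels = np.clip(img, 0, 255).astype(np.uint8)

    annotated = AnnotatedImage(
        image_id=f"scene_{p.seed:06d}",
        pixels=pixels,
        boxes=boxes,
        taproot_mask=taproot_mask,
        metadata={"seed": p.seed, "n_distractors": len(distractor_boxes)},
    )
    # polyline points snapped to pixel centers are taproot-mask foreground
    poly = np.stack([np.clip(np.round(cx), 0, w - 1), yy], axis=1)
    return SyntheticScene(annotated=annotated, on_taproot=on_taproot,
                          distractor_boxes=distractor_boxes, taproot_polyline=poly,
                          nodule_radii=[c[2] for c in centers[:len(boxes)]])


def derive_seed(master_seed: int, index: int) -> int:
    """Reproducible per-scene seed below 2**31."""
    return int((np.uint64(master_seed) * np.uint64(1000003) + np.uint64(index))
               % np.uint64(2 ** 31 - 1))


def _scene_with_retries(params: SceneParams, master_seed: int, index: int,
                        retries: int) -> SyntheticScene:
    """Generate scene ``index``; on an unplaceable draw, re-derive the seed.

    Retrying truncates the extreme upper tail of the count distribution
    (draws that physically cannot be packed on the canvas); each retry is
    logged. Determinism is preserved: the retry seeds are derived from the
    master seed.
    """
    last: GenerationError | None = None
    for attempt in range(retries + 1):
        seed = derive_seed(master_seed, index + (attempt * 7_654_321))
        try:
            return generate_scene(replace(params, seed=seed))
        except GenerationError as e:
            log.warning("scene %d seed %d unplaceable (%s); retrying", index, seed, e)
            last = e
    raise last


def generate_dataset(n: int, params: SceneParams, out_dir: str | Path,
                     overwrite: bool = False, retries: int = 3) -> pd.DataFrame:
    """Write ``n`` scenes (PNG + mask PNG + one VIA JSON + manifest CSV)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is non-empty; pass overwrite=True to replace")
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    annotations: dict[str, list[BoundingBox]] = {}
    rows = []
    for i in range(n):
        scene = _scene_with_retries(params, params.seed, i, retries)
        seed = scene.annotated.metadata["seed"]
        scene.annotated.image_id = f"scene_{i:04d}"
        img_id = scene.annotated.image_id
        io_formats.save_image(scene.annotated.pixels, out / "images" / f"{img_id}.png")
        io_formats.write_mask(scene.annotated.taproot_mask, out / "masks" / f"{img_id}.png")
        annotations[img_id] = scene.annotated.boxes
        seg = np.diff(scene.taproot_polyline, axis=0)
        rows.append({
            "image_id": img_id,
            "seed": seed,
            "n_nodules": len(scene.annotated.boxes),
            "n_on_taproot": int(sum(scene.on_taproot)),
            "n_distractors": len(scene.distractor_boxes),
            "taproot_length_px": float(np.hypot(seg[:, 0], seg[:, 1]).sum()),
        })
    io_formats.write_vgg_annotations(annotations, out / "annotations.json")
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def generate_scenes(n: int, params: SceneParams,
                    retries: int = 3) -> list[SyntheticScene]:
    """In-memory convenience: ``n`` scenes with per-scene derived seeds."""
    scenes = []
    for i in range(n):
        scene = _scene_with_retries(params, params.seed, i, retries)
        scene.annotated.image_id = f"scene_{i:04d}"
        scenes.append(scene)
    return scenes
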