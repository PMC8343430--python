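"""Anchor scale/aspect configuration strategies for the nodule detector.

Three strategies are provided:

* ``default_anchors`` — the standard dense-detector configuration: scales
  {2^0, 2^(1/3), 2^(2/3)} and aspect ratios {1:2, 1:1, 2:1} on a five-level
  pyramid (base sizes 32..512, strides 8..128).
* ``percentile_anchors`` — fit a normal distribution to annotated box sizes
  (sqrt of area) and to log aspect ratios, then take k equidistant
  percentiles p_i = i/(k+1) of each fit.
* ``optimize_anchors_de`` — differential-evolution search maximizing the
  mean best centered IoU between annotated boxes and the anchor shapes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import differential_evolution
from scipy.stats import norm

from .types import BoundingBox

log = logging.getLogger(__name__)

DEFAULT_BASE_SIZES = (32.0, 64.0, 128.0, 256.0, 512.0)
DEFAULT_STRIDES = (8, 16, 32, 64, 128)


@dataclass
class AnchorConfig:
    scales: tuple[float, ...]
    ratios: tuple[float, ...]  # height : width
    base_sizes: tuple[float, ...] = DEFAULT_BASE_SIZES
    strides: tuple[int, ...] = DEFAULT_STRIDES

    def __post_init__(self):
        self.scales = tuple(float(s) for s in self.scales)
        self.ratios = tuple(float(r) for r in self.ratios)
        if any(s <= 0 for s in self.scales) or any(r <= 0 for r in self.ratios):
            raise ValueError("scales and ratios must be > 0")
        if list(self.scales) != sorted(self.scales) or list(self.ratios) != sorted(self.ratios):
            raise ValueError("scales and ratios must be sorted ascending")
        if len(self.base_sizes) != len(self.strides):
            raise ValueError("base_sizes and strides must have equal length")

    @property
    def anchors_per_location(self) -> int:
        return len(self.scales) * len(self.ratios)

    def shapes(self, base_size: float | None = None) -> np.ndarray:
        """(n, 2) array of anchor (width, height) for one pyramid level.

        With ``base_size=None`` the shapes of every level are concatenated.
        """
        bases = [base_size] if base_size is not None else list(self.base_sizes)
        out = []
        for base in bases:
            for s in self.scales:
                for r in self.ratios:
                    side = base * s
                    out.append((side / np.sqrt(r), side * np.sqrt(r)))
        return np.asarray(out)

    def to_yaml(self, path) -> None:
        doc = {"scales": list(self.scales), "ratios": list(self.ratios),
               "base_sizes": list(self.base_sizes), "strides": list(self.strides)}
        with open(path, "w") as f:
            yaml.safe_dump(doc, f)

    @classmethod
    def from_yaml(cls, path) -> "AnchorConfig":
        with open(path) as f:
            doc = yaml.safe_load(f)
        return cls(scales=tuple(doc["scales"]), ratios=tuple(doc["ratios"]),
                   base_sizes=tuple(doc["base_sizes"]), strides=tuple(doc["strides"]))


@dataclass
class BoxStats:
    sizes: np.ndarray            # sqrt(area) per box
    aspects: np.ndarray          # height / width per box
    size_mu: float = field(init=False)
    size_sigma: float = field(init=False)
    log_aspect_mu: float = field(init=False)
    log_aspect_sigma: float = field(init=False)

    def __post_init__(self):
        if len(self.sizes) < 1:
            raise ValueError("need at least one box")
        self.size_mu = float(np.mean(self.sizes))
        self.size_sigma = float(np.std(self.sizes))
        la = np.log(self.aspects)
        self.log_aspect_mu = float(np.mean(la))
        self.log_aspect_sigma = float(np.std(la))

    @classmethod
    def from_boxes(cls, boxes: list[BoundingBox]) -> "BoxStats":
        sizes = np.array([np.sqrt(b.area) for b in boxes])
        aspects = np.array([b.height / b.width for b in boxes])
        return cls(sizes=sizes, aspects=aspects)


def default_anchors(base_sizes=DEFAULT_BASE_SIZES, strides=DEFAULT_STRIDES) -> AnchorConfig:
    return AnchorConfig(
        scales=(2 ** 0, 2 ** (1 / 3), 2 ** (2 / 3)),
        ratios=(0.5, 1.0, 2.0),
        base_sizes=tuple(base_sizes),
        strides=tuple(strides),
    )


def _equidistant_percentiles(k: int) -> np.ndarray:
    return np.arange(1, k + 1) / (k + 1)


def percentile_anchors(boxes: list[BoundingBox], n_scales: int = 3, n_ratios: int = 3,
                       base_sizes=DEFAULT_BASE_SIZES, strides=DEFAULT_STRIDES) -> AnchorConfig:
    """Normal-percentile anchor fit to the annotated box statistics."""
    if len(boxes) < 2:
        raise ValueError("need at least 2 boxes")
    stats = BoxStats.from_boxes(boxes)
    if stats.size_sigma == 0 and stats.log_aspect_sigma == 0:
        log.warning("all boxes identical; percentile anchors collapse to the mean")
    ps = _equidistant_percentiles(n_scales)
    if stats.size_sigma > 0:
        sizes = norm.ppf(ps, loc=stats.size_mu, scale=stats.size_sigma)
    else:
        sizes = np.full(n_scales, stats.size_mu)
    pr = _equidistant_percentiles(n_ratios)
    if stats.log_aspect_sigma > 0:
        la = norm.ppf(pr, loc=stats.log_aspect_mu, scale=stats.log_aspect_sigma)
    else:
        la = np.full(n_ratios, stats.log_aspect_mu)
    ratios = np.exp(la)
    bases = np.asarray(base_sizes)
    # each percentile size is matched to the nearest pyramid level's base size
    scales = np.array([s / bases[np.argmin(np.abs(bases - s))] for s in sizes])
    order = np.argsort(scales)
    rorder = np.argsort(ratios)
    return AnchorConfig(scales=tuple(scales[order]), ratios=tuple(ratios[rorder]),
                        base_sizes=tuple(base_sizes), strides=tuple(strides))


def anchor_box_overlap(config: AnchorConfig, boxes: list[BoundingBox]) -> float:
    """Mean over boxes of the best IoU against any anchor shape, both centered."""
    if not boxes:
        raise ValueError("boxes must be non-empty")
    shapes = config.shapes()  # (A, 2) widths/heights over all levels
    wh = np.array([(b.width, b.height) for b in boxes])  # (n, 2)
    inter = (np.minimum(wh[:, None, 0], shapes[None, :, 0])
             * np.minimum(wh[:, None, 1], shapes[None, :, 1]))
    areas = wh[:, 0] * wh[:, 1]
    aareas = shapes[:, 0] * shapes[:, 1]
    union = areas[:, None] + aareas[None, :] - inter
    return float((inter / union).max(axis=1).mean())


def optimize_anchors_de(boxes: list[BoundingBox], n_scales: int = 3, n_ratios: int = 3,
                        seed: int = 0, generations: int = 100, population: int = 20,
                        base_sizes=DEFAULT_BASE_SIZES, strides=DEFAULT_STRIDES,
                        scale_bounds=(0.25, 4.0), log_ratio_bound=1.5) -> AnchorConfig:
    """Differential-evolution anchor search maximizing mean best centered IoU.

    The default configuration is seeded into the initial population, so the
    optimized configuration never scores below the default.
    """
    if len(boxes) < 1:
        raise ValueError("boxes must be non-empty")
    if scale_bounds[0] >= scale_bounds[1] or log_ratio_bound <= 0:
        raise ValueError("degenerate search bounds")
    bounds = [tuple(scale_bounds)] * n_scales + [(-log_ratio_bound, log_ratio_bound)] * n_ratios

    def decode(x: np.ndarray) -> AnchorConfig:
        scales = np.sort(np.asarray(x[:n_scales], dtype=float))
        ratios = np.sort(np.exp(np.asarray(x[n_scales:], dtype=float)))
        return AnchorConfig(scales=tuple(scales), ratios=tuple(ratios),
                            base_sizes=tuple(base_sizes), strides=tuple(strides))

    def objective(x: np.ndarray) -> float:
        return -anchor_box_overlap(decode(x), boxes)

    rng = np.random.default_rng(seed)
    init = rng.uniform(low=[b[0] for b in bounds], high=[b[1] for b in bounds],
                       size=(max(population, 5), len(bounds)))
    dflt = default_anchors(base_sizes, strides)
    seed_vec = np.concatenate([
        np.resize(np.asarray(dflt.scales), n_scales),
        np.log(np.resize(np.asarray(dflt.ratios), n_ratios)),
    ])
    init[0] = np.clip(seed_vec, [b[0] for b in bounds], [b[1] for b in bounds])

    result = differential_evolution(
        objective, bounds, init=init, maxiter=generations, seed=seed,
        strategy="rand1bin", mutation=0.8, recombination=0.7, polish=False,
        tol=0, atol=0,
    )
    best = decode(result.x)
    log.info("DE anchor search: objective %.4f (default %.4f)",
             -result.fun, anchor_box_overlap(dflt, boxes))
    return best
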