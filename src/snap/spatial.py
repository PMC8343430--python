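"""Spatial quantification: taproot zone counts and along-taproot positions.

The predicted taproot mask is dilated by a disk; a detected nodule belongs
to the taproot zone iff its bounding-box center falls on a foreground pixel
of the dilated mask.  For positional statistics the mask is skeletonized to
a one-pixel medial curve, the longest endpoint-to-endpoint path is ordered
from its topmost end (the soil-line proxy), and each nodule is projected to
its nearest skeleton point, yielding an arc-length position along the root.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from skimage.morphology import dilation, disk, skeletonize

from .io_formats import N_POSITION_BINS
from .types import BoundingBox, Detection

log = logging.getLogger(__name__)


@dataclass
class TaprootGeometry:
    mask: np.ndarray
    dilated_mask: np.ndarray
    skeleton: np.ndarray      # (n, 2) ordered (x, y) pixel centers, top first
    arc_length: np.ndarray    # (n,) cumulative length along the skeleton, px

    @property
    def length_px(self) -> float:
        return float(self.arc_length[-1]) if len(self.arc_length) else 0.0


@dataclass
class NoduleRecord:
    box: BoundingBox
    score: float
    area: float
    on_taproot: bool | None
    arc_position: float | None
    normalized_position: float | None


@dataclass
class NoduleReport:
    image_id: str
    total_count: int
    taproot_zone_count: int | float  # nan when no mask was available
    records: list[NoduleRecord] = field(default_factory=list)
    mean_box_area: float = float("nan")
    median_box_area: float = float("nan")
    box_area_sd: float = float("nan")
    taproot_length_px: float = float("nan")
    position_histogram: np.ndarray | None = None  # counts in 10 equal bins


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    ys, xs = np.nonzero(skel)
    pts = set(zip(xs.tolist(), ys.tolist()))
    g = nx.Graph()
    g.add_nodes_from(pts)
    for x, y in pts:
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                if dx == dy == 0:
                    continue
                q = (x + dx, y + dy)
                if q in pts:
                    g.add_edge((x, y), q, weight=float(np.hypot(dx, dy)))
    return g


def _longest_path(g: nx.Graph) -> list[tuple[int, int]]:
    """Longest endpoint-to-endpoint shortest path on the largest component."""
    comp = max(nx.connected_components(g), key=len)
    sub = g.subgraph(comp)
    endpoints = [n for n in sub if sub.degree(n) == 1]
    if not endpoints:  # closed loop: fall back to ordering from the topmost pixel
        log.warning("skeleton has no endpoints (closed loop); ordering from min-y pixel")
        start = min(sub.nodes, key=lambda n: (n[1], n[0]))
        order = list(nx.dfs_preorder_nodes(sub, start))
        return order
    best_len, best_path = -1.0, None
    # double-sweep: farthest node from an arbitrary endpoint, then farthest from it
    lengths = nx.single_source_dijkstra_path_length(sub, endpoints[0], weight="weight")
    far = max(lengths, key=lengths.get)
    lengths2, paths2 = nx.single_source_dijkstra(sub, far, weight="weight")
    candidates = [n for n in endpoints if n in lengths2] or list(lengths2)
    for e in candidates:
        if lengths2[e] > best_len:
            best_len, best_path = lengths2[e], paths2[e]
    return best_path


def build_geometry(mask: np.ndarray, r_dilate: float = 20.0) -> TaprootGeometry:
    """Dilate the mask by a disk and extract the ordered skeleton polyline."""
    mask = (np.asarray(mask) > 0).astype(np.uint8)
    if mask.sum() == 0:
        raise ValueError("empty taproot mask")
    if r_dilate > 0:
        dilated = (dilation(mask, disk(int(round(r_dilate)))) > 0).astype(np.uint8)
    else:
        dilated = mask.copy()
    skel = skeletonize(mask.astype(bool))
    if not skel.any():  # tiny blob may thin to nothing; keep its centroid
        ys, xs = np.nonzero(mask)
        path = [(int(xs.mean()), int(ys.mean()))]
    else:
        path = _longest_path(_skeleton_graph(skel))
    # order from the endpoint with smallest y (top of image = soil line proxy)
    if len(path) > 1 and path[0][1] > path[-1][1]:
        path = path[::-1]
    pts = np.asarray(path, dtype=float)
    if len(pts) > 1:
        seg = np.hypot(*np.diff(pts, axis=0).T)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
    else:
        arc = np.zeros(1)
    return TaprootGeometry(mask=mask, dilated_mask=dilated, skeleton=pts, arc_length=arc)


def assign_taproot_zone(detections: list[Detection],
                        geometry: TaprootGeometry) -> tuple[list[bool], int]:
    """On-taproot flags by pixel membership of box centers in the dilated mask."""
    h, w = geometry.dilated_mask.shape
    flags = []
    for d in detections:
        cx, cy = d.box.center
        px, py = int(np.floor(cx)), int(np.floor(cy))
        if not (0 <= px < w and 0 <= py < h):
            log.warning("box center (%.1f, %.1f) outside image bounds", cx, cy)
            flags.append(False)
            continue
        flags.append(bool(geometry.dilated_mask[py, px]))
    return flags, sum(flags)


def project_to_skeleton(detections: list[Detection],
                        geometry: TaprootGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Arc positions (px from top) and normalized positions of box centers."""
    skel, arc = geometry.skeleton, geometry.arc_length
    n = len(detections)
    if len(skel) == 0 or geometry.length_px == 0:
        log.warning("zero-length skeleton; all arc positions defined as 0")
        return np.zeros(n), np.zeros(n)
    positions = np.empty(n)
    for i, d in enumerate(detections):
        cx, cy = d.box.center
        d2 = (skel[:, 0] - cx) ** 2 + (skel[:, 1] - cy) ** 2
        # ties resolved toward the smaller arc position (argmin takes the
        # first minimum and arc_length is strictly increasing along the path)
        positions[i] = arc[int(np.argmin(d2))]
    return positions, positions / geometry.length_px


@dataclass
class QuantifyConfig:
    r_dilate: float = 10.0               # ~2x the median nodule radius at 1024 px width
    scale_with_width: bool = False       # r_dilate is per 1024 px of image width
    n_bins: int = N_POSITION_BINS


def quantify(detections: list[Detection], mask: np.ndarray | None,
             config: QuantifyConfig | None = None, image_id: str = "") -> NoduleReport:
    """Compose zone assignment, skeleton projection and size statistics."""
    cfg = config or QuantifyConfig()
    areas = np.array([d.box.area for d in detections])
    report = NoduleReport(
        image_id=image_id,
        total_count=len(detections),
        taproot_zone_count=float("nan"),
    )
    if len(detections) > 0:
        report.mean_box_area = float(areas.mean())
        report.median_box_area = float(np.median(areas))
        report.box_area_sd = float(areas.std(ddof=1)) if len(areas) > 1 else 0.0
    if mask is None:
        report.records = [
            NoduleRecord(box=d.box, score=d.score, area=d.box.area,
                         on_taproot=None, arc_position=None, normalized_position=None)
            for d in detections
        ]
        return report

    r = cfg.r_dilate
    if cfg.scale_with_width:
        r = r * mask.shape[1] / 1024.0
    geometry = build_geometry(mask, r_dilate=r)
    flags, zone_count = assign_taproot_zone(detections, geometry)
    arcs, norms = project_to_skeleton(detections, geometry)
    report.taproot_zone_count = zone_count
    report.taproot_length_px = geometry.length_px
    report.records = [
        NoduleRecord(box=d.box, score=d.score, area=d.box.area, on_taproot=f,
                     arc_position=float(a), normalized_position=float(np_))
        for d, f, a, np_ in zip(detections, flags, arcs, norms)
    ]
    hist, _ = np.histogram(norms, bins=cfg.n_bins, range=(0.0, 1.0)) if len(norms) else (
        np.zeros(cfg.n_bins, dtype=int), None)
    report.position_histogram = hist
    return report
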