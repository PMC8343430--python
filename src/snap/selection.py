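"""Representative image selection by submodular facility-location maximization.

To pick which images are worth the cost of manual annotation, each image
is reduced to a feature vector (bilinear downsample -> shallow convolutional
autoencoder -> flatten -> PCA) and a subset R of size K is chosen greedily
to maximize the uncapacitated facility-location function

    f(R) = sum_{w in W} max_{r in R} sim(w, r),
    sim(w, r) = d_max - d(w, r),

where d is Euclidean distance in feature space and d_max is the maximum
pairwise distance over the whole set W (computed once, so sim >= 0 and f
is monotone submodular — the regime in which greedy forward selection
carries the (1 - 1/e) optimality guarantee).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist
from sklearn.decomposition import PCA
from skimage.transform import resize

from . import nn
from .types import AnnotatedImage

log = logging.getLogger(__name__)


@dataclass
class FeatureConfig:
    downsample_size: tuple[int, int] = (512, 512)
    latent_channels: int = 8       # autoencoder bottleneck channels
    pca_components: int | None = 400
    variance_target: float | None = None
    train_epochs: int = 20
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if (self.pca_components is None) == (self.variance_target is None):
            raise ValueError("set exactly one of pca_components / variance_target")
        if self.variance_target is not None and not 0 < self.variance_target < 1:
            raise ValueError("variance_target must lie in (0, 1)")
        if min(self.downsample_size) < 8:
            raise ValueError("downsample dims must be >= 8")


@dataclass
class FeatureMatrix:
    ids: list[str]
    vectors: np.ndarray  # (n, p)

    def __post_init__(self):
        v = np.asarray(self.vectors)
        if v.ndim != 2 or v.shape[0] != len(self.ids) or v.shape[0] < 1:
            raise ValueError("vectors must be (n_ids, p) with n >= 1")
        if not np.isfinite(v).all():
            raise ValueError("non-finite feature entries")


@dataclass
class SubsetSelection:
    indices: list[int]
    gains: list[float]
    K: int
    f_value: float
    ids: list[str] = field(default_factory=list)


class _ShallowAutoencoder:
    """One stride-2 conv encode layer with a mirrored 2x2 transposed-conv decode."""

    def __init__(self, latent_channels: int, seed: int):
        rng = np.random.default_rng(seed)
        self.encoder = nn.Conv2d(3, latent_channels, k=2, stride=2, pad=0, rng=rng)
        self.enc_act = nn.ReLU()
        self.decoder = nn.ConvTranspose2x2(latent_channels, 3, rng=rng)
        self.dec_act = nn.Sigmoid()

    def params(self):
        return self.encoder.params() + self.decoder.params()

    def encode(self, x):
        return self.enc_act.forward(self.encoder.forward(x), train=False)

    def train(self, x: np.ndarray, epochs: int, lr: float) -> list[float]:
        opt = nn.Adam(self.params(), lr=lr)
        losses = []
        for _ in range(max(epochs, 0)):
            opt.zero_grad()
            z = self.enc_act.forward(self.encoder.forward(x, train=True), train=True)
            y = self.dec_act.forward(self.decoder.forward(z, train=True), train=True)
            diff = (y - x).astype(np.float32)
            loss = float(np.mean(diff ** 2))
            losses.append(loss)
            g = (2.0 / diff.size) * diff
            g = self.decoder.backward(self.dec_act.backward(g))
            self.encoder.backward(self.enc_act.backward(g))
            opt.step()
        return losses


def _fix_component_signs(pca: PCA) -> None:
    """Make the largest-magnitude loading of each component positive (run-stable)."""
    for i, comp in enumerate(pca.components_):
        if comp[np.argmax(np.abs(comp))] < 0:
            pca.components_[i] = -comp


def extract_features(images: list[AnnotatedImage], config: FeatureConfig) -> FeatureMatrix:
    """Bilinear downsample -> autoencoder encode -> flatten -> PCA projection."""
    if len(images) < 2:
        raise ValueError("need at least 2 images")
    h, w = config.downsample_size
    batch = np.stack([
        resize(im.pixels, (h, w), order=1, preserve_range=True,
               anti_aliasing=False).astype(np.float32) / 255.0
        for im in images
    ])
    ae = _ShallowAutoencoder(config.latent_channels, config.seed)
    ae.train(batch, config.train_epochs, config.learning_rate)
    encoded = ae.encode(batch).reshape(len(images), -1).astype(np.float64)
    if not np.isfinite(encoded).all():
        raise ArithmeticError("non-finite activations in autoencoder encode stage")

    n, p = encoded.shape
    if config.pca_components is not None:
        k = config.pca_components
        feasible = min(n - 1, p)
        if k > feasible:
            log.warning("pca_components %d reduced to feasible maximum %d", k, feasible)
            k = feasible
        pca = PCA(n_components=k, svd_solver="full", random_state=config.seed)
    else:
        pca = PCA(n_components=config.variance_target, svd_solver="full",
                  random_state=config.seed)
    vectors = pca.fit_transform(encoded)
    _fix_component_signs(pca)
    vectors = (encoded - pca.mean_) @ pca.components_.T
    if not np.isfinite(vectors).all():
        raise ArithmeticError("non-finite values in PCA projection stage")
    return FeatureMatrix(ids=[im.image_id for im in images], vectors=vectors)


def max_pairwise_distance(features: FeatureMatrix) -> float:
    if len(features.ids) == 1:
        return 0.0
    return float(pdist(features.vectors).max())


def facility_location_value(features: FeatureMatrix, subset: list[int],
                            d_max: float | None = None) -> float:
    """f(R) = sum_w max_{r in R} (d_max - d(w, r)); f(empty) = 0."""
    if len(subset) == 0:
        return 0.0
    if len(set(subset)) != len(subset):
        raise ValueError("duplicate indices in subset")
    n = features.vectors.shape[0]
    if any(i < 0 or i >= n for i in subset):
        raise IndexError("subset index out of range")
    if d_max is None:
        d_max = max_pairwise_distance(features)
    d = cdist(features.vectors, features.vectors[list(subset)])
    return float((d_max - d.min(axis=1)).sum())


def greedy_select(features: FeatureMatrix, K: int) -> SubsetSelection:
    """Greedy forward selection; ties broken toward the lowest row index."""
    n = features.vectors.shape[0]
    if not 1 <= K <= n:
        raise ValueError(f"K={K} outside [1, {n}]")
    d_max = max_pairwise_distance(features)
    dist = cdist(features.vectors, features.vectors)  # (n, n)
    best = np.full(n, np.inf)  # min distance from each w to the current R
    selected: list[int] = []
    gains: list[float] = []
    f_value = 0.0
    for _ in range(K):
        cand_best = np.minimum(best[:, None], dist)  # (n, n_candidates)
        cand_f = (d_max - cand_best).sum(axis=0)
        cand_f[selected] = -np.inf
        gain = cand_f - f_value
        pick = int(np.argmax(gain))  # argmax returns the lowest index on ties
        selected.append(pick)
        gains.append(float(gain[pick]))
        best = cand_best[:, pick]
        f_value = float(cand_f[pick])
    return SubsetSelection(indices=selected, gains=gains, K=K, f_value=f_value,
                           ids=[features.ids[i] for i in selected])
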