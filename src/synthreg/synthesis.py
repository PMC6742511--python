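"""Contrast synthesis: Gaussian-derivative features of the histology image and
a regression forest predicting MRI intensity per pixel.

The forest is a bag of independently trained regression trees.  Each tree is
trained on its own resample of pixels; for every training pixel a displacement
Delta is drawn from the current variational posterior q (one draw per tree),
and the regression target is the MRI intensity at the displaced location,
M(x + Delta).  This per-tree displacement sampling is the stochastic M-step of
the variational EM loop: it is a valid stochastic optimiser of the expected
log-likelihood because q is a probability distribution over displacements,
and it doubles as an extra source of randomisation for the ensemble.

Prediction combines the T tree guesses g_t with a conjugate Inverse-Gamma
prior (shape a, scale b) on the per-pixel variance:

    mu      = mean_t g_t
    sigma^2 = (2 b + sum_t (g_t - mu)^2) / (2 a + T)

i.e. the prior acts as 2a pseudo-observations with sample variance b/a, so
the predictive variance never falls below 2b / (2a + T) and equals that bound
exactly when all trees agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from sklearn.tree import DecisionTreeRegressor

from .deformation import DisplacementLabelSet
from .io import Image2D

__all__ = [
    "FeatureStack",
    "ForestHyperparams",
    "SynthesisModel",
    "PredictionMaps",
    "extract_features",
    "sample_displacements",
    "fit",
    "predict",
]

FEATURE_SCALES_MM = (0.0, 2.0, 4.0)
DERIVATIVE_ORDERS = (0, 1, 2, 3)
# 3 scales x (1 + 2 + 3 + 4) axis-aligned partials + (x, y) location = 32
N_FEATURES = len(FEATURE_SCALES_MM) * sum(o + 1 for o in DERIVATIVE_ORDERS) + 2


@dataclass
class FeatureStack:
    """Per-pixel feature vectors, shape (H, W, 32)."""

    values: np.ndarray
    names: list

    @property
    def feature_count(self) -> int:
        return self.values.shape[-1]

    def flat(self) -> np.ndarray:
        return self.values.reshape(-1, self.values.shape[-1])


def _derivatives(img: np.ndarray, order: int, spacing: float) -> list:
    """All axis-aligned partial derivatives of a given total order (per mm)."""
    if order == 0:
        return [("", img)]
    out = []
    for nx in range(order, -1, -1):
        ny = order - nx
        d = img
        for _ in range(nx):
            d = np.gradient(d, spacing, axis=1)
        for _ in range(ny):
            d = np.gradient(d, spacing, axis=0)
        out.append(("x" * nx + "y" * ny, d))
    return out


def extract_features(image: Image2D) -> FeatureStack:
    """Gaussian derivatives (orders 0-3, scales 0/2/4 mm) plus location (mm).

    Scale 0 means no pre-smoothing, with derivatives taken by central finite
    differences; at scales 2 and 4 mm derivatives are Gaussian-derivative
    filter responses.  Location features are the pixel-centre coordinates in
    mm, letting the trees express spatially varying contrast mappings.
    """
    img = image.pixels
    spacing = image.spacing
    planes, names = [], []
    for scale in FEATURE_SCALES_MM:
        if scale == 0.0:
            for order in DERIVATIVE_ORDERS:
                for suffix, d in _derivatives(img, order, spacing):
                    planes.append(d)
                    names.append(f"s0_d{suffix or '0'}")
        else:
            sig = scale / spacing
            for order in DERIVATIVE_ORDERS:
                for nx in range(order, -1, -1):
                    ny = order - nx
                    d = gaussian_filter(img, sig, order=(ny, nx)) / spacing ** order
                    planes.append(d)
                    names.append(f"s{scale:g}_d{'x' * nx + 'y' * ny or '0'}")
    h, w = img.shape
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    planes += [jj * spacing, ii * spacing]
    names += ["loc_x", "loc_y"]
    stack = np.stack(planes, axis=-1)
    assert stack.shape[-1] == N_FEATURES
    return FeatureStack(stack, names)


@dataclass
class ForestHyperparams:
    """gamma = {a, b, T, min_leaf, n_split_features} of the synthesis model."""

    a: float = 2.0
    b: float = 50.0
    n_trees: int = 100
    min_leaf: int = 5
    n_split_features: int = 5

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("Inverse-Gamma hyperparameters a, b must be > 0")
        if self.n_trees < 1:
            raise ValueError("need at least one tree")

    @property
    def variance_floor(self) -> float:
        return 2.0 * self.b / (2.0 * self.a + self.n_trees)


@dataclass
class SynthesisModel:
    """A trained regression forest plus its hyperparameters."""

    trees: list
    hyper: ForestHyperparams
    feature_count: int = N_FEATURES

    @property
    def n_trees(self) -> int:
        return len(self.trees)


@dataclass
class PredictionMaps:
    """Per-pixel predictive mean and variance of the synthesised contrast."""

    mu: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        if self.mu.shape != self.var.shape:
            raise ValueError("mu and var must share a shape")
        if np.any(self.var <= 0):
            raise ValueError("predictive variance must be positive")


def sample_displacements(
    q: np.ndarray, labels: DisplacementLabelSet, rng: np.random.Generator
) -> np.ndarray:
    """Draw one displacement per row of ``q`` (shape (n, S)) by inverse CDF."""
    cdf = np.cumsum(q, axis=1)
    cdf /= cdf[:, -1:]
    u = rng.random((q.shape[0], 1))
    idx = (u > cdf).sum(axis=1)
    return labels.deltas[np.minimum(idx, labels.n_labels - 1)]


def _lookup_targets(M: np.ndarray, rows: np.ndarray, cols: np.ndarray):
    h, w = M.shape
    valid = (rows >= 0) & (rows <= h - 1) & (cols >= 0) & (cols <= w - 1)
    vals = map_coordinates(M, [rows, cols], order=1, mode="constant", cval=0.0)
    return vals, valid


def fit(
    features: Sequence[FeatureStack],
    mri: Sequence[Image2D],
    beliefs: Sequence[np.ndarray],
    labels: DisplacementLabelSet,
    hyper: ForestHyperparams,
    rng: np.random.Generator,
    image_bag_fraction: float = 0.66,
    pixel_bag_fraction: float = 0.66,
    pooled_pixel_budget: int = 25000,
    candidate_mask: Optional[Sequence[np.ndarray]] = None,
) -> SynthesisModel:
    """Train the forest on N image pairs given the current beliefs q.

    Bagging: with a single pair, each tree sees a ``pixel_bag_fraction``
    resample of the pixels; with several pairs each tree sees a
    ``image_bag_fraction`` subset of pairs and a pooled sample of
    ``pooled_pixel_budget`` pixels.  For each chosen pixel one displacement is
    drawn from q_nx per tree and the target is the bilinear MRI intensity at
    the displaced position; displaced positions falling outside the image are
    dropped from that tree's sample.
    """
    n_pairs = len(features)
    if n_pairs == 0:
        raise ValueError("no image pairs to train on")
    feats_flat = [f.flat() for f in features]
    q_flat = [np.asarray(q).reshape(-1, labels.n_labels) for q in beliefs]
    shapes = [m.pixels.shape for m in mri]
    cand = []
    for n in range(n_pairs):
        if candidate_mask is not None and candidate_mask[n] is not None:
            cand.append(np.flatnonzero(np.asarray(candidate_mask[n]).ravel()))
        else:
            cand.append(np.arange(feats_flat[n].shape[0]))

    trees = []
    for _ in range(hyper.n_trees):
        if n_pairs == 1:
            chosen_pairs = [0]
            n_pix = max(1, int(round(pixel_bag_fraction * cand[0].size)))
            per_pair = [n_pix]
        else:
            k = max(1, int(round(image_bag_fraction * n_pairs)))
            chosen_pairs = list(rng.choice(n_pairs, size=k, replace=False))
            per = max(1, pooled_pixel_budget // k)
            per_pair = [min(per, cand[n].size) for n in chosen_pairs]
        X_parts, y_parts = [], []
        for n, n_pix in zip(chosen_pairs, per_pair):
            idx = rng.choice(cand[n], size=n_pix, replace=True)
            deltas = sample_displacements(q_flat[n][idx], labels, rng)
            h, w = shapes[n]
            rows = idx // w + deltas[:, 1] / mri[n].spacing
            cols = idx % w + deltas[:, 0] / mri[n].spacing
            vals, valid = _lookup_targets(mri[n].pixels, rows, cols)
            X_parts.append(feats_flat[n][idx[valid]])
            y_parts.append(vals[valid])
        X = np.concatenate(X_parts)
        y = np.concatenate(y_parts)
        if X.shape[0] == 0:
            raise ValueError("all sampled training targets fell outside the image")
        tree = DecisionTreeRegressor(
            max_features=hyper.n_split_features,
            min_samples_leaf=hyper.min_leaf,
            random_state=int(rng.integers(0, 2 ** 31 - 1)),
        )
        tree.fit(X, y)
        trees.append(tree)
    return SynthesisModel(trees, hyper, feature_count=features[0].feature_count)


def predict(model: SynthesisModel, features: FeatureStack) -> PredictionMaps:
    """Per-pixel Gaussian prediction from the forest and the variance prior."""
    if features.feature_count != model.feature_count:
        raise ValueError("feature count does not match the fitted model")
    X = features.flat()
    guesses = np.stack([t.predict(X) for t in model.trees])  # (T, n_pix)
    T = model.n_trees
    hyper = model.hyper
    mu = guesses.mean(axis=0)
    var = (2.0 * hyper.b + ((guesses - mu) ** 2).sum(axis=0)) / (2.0 * hyper.a + T)
    shape = features.values.shape[:2]
    return PredictionMaps(mu.reshape(shape), var.reshape(shape))
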