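"""Variational EM for joint synthesis and registration.

The deformation field at each pixel is a hidden discrete variable over the
displacement label set.  A mean-field posterior q factorises over pixels;
the algorithm alternates:

* E-step: with the forest fixed, compute per-pixel predictive maps
  (mu, sigma^2) and run fixed-point sweeps of the mean-field update

      q_x(Delta_s)  propto  N(M(x + Delta_s); mu_x, sigma_x^2)
                            * exp(-beta1 ||Delta_s||^2)
                            * [landmark factor at histology landmark pixels]
                            * exp(-beta2 sum_{x' in B(x)} E_q ||Delta_s - Delta'||^2)

  The neighbour expectation needs only the first and second moments of each
  neighbour's q, so a sweep costs O(|Omega| * S).

* M-step: retrain the regression forest, sampling one displacement per pixel
  per tree from q (a stochastic optimiser of the expected log-likelihood).

Convergence is tracked on the prediction maps rather than on the forest
parameters, which fluctuate between iterations because of the randomised
training.  The stochastic M-step forfeits monotonicity guarantees; in
practice the loop settles within a handful of outer iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from . import synthesis
from .deformation import DisplacementLabelSet
from .io import Image2D, LandmarkSet, RunConfig, child_rngs
from .synthesis import FeatureStack, ForestHyperparams, PredictionMaps, SynthesisModel

logger = logging.getLogger("synthreg")

__all__ = [
    "BeliefField",
    "VemState",
    "init_beliefs",
    "shifted_intensities",
    "log_likelihood_table",
    "landmark_log_factors",
    "estep_update",
    "mstep_update",
    "free_energy",
    "run",
]

LOG_FLOOR = 1e-300


def init_beliefs(shape: tuple, labels: DisplacementLabelSet) -> np.ndarray:
    """Uniform beliefs: q_x(Delta_s) = 1/S everywhere (maximum uncertainty)."""
    S = labels.n_labels
    return np.full((*shape, S), 1.0 / S)


def shifted_intensities(M: Image2D, labels: DisplacementLabelSet):
    """M(x + Delta_s) for every pixel and label.

    Returns ``(values, valid)`` of shape (H, W, S); out-of-bounds samples are
    zero-valued with ``valid`` False.
    """
    h, w = M.shape
    S = labels.n_labels
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    rows = ii[..., None] + labels.deltas[:, 1] / M.spacing
    cols = jj[..., None] + labels.deltas[:, 0] / M.spacing
    vals = map_coordinates(
        M.pixels, [rows.reshape(-1), cols.reshape(-1)], order=1, mode="constant", cval=0.0
    ).reshape(h, w, S)
    valid = (rows >= 0) & (rows <= h - 1) & (cols >= 0) & (cols <= w - 1)
    return vals, valid


def log_likelihood_table(M: Image2D, maps: PredictionMaps, labels: DisplacementLabelSet):
    """log N(M(x + Delta_s); mu_x, sigma_x^2) as an (H, W, S) table.

    For displacements that leave the image domain the factor is neutralised:
    it is replaced by the log of the pixel's mean in-bounds likelihood, so
    border pixels are driven by the prior and their neighbours rather than by
    the zero-padding value.
    """
    vals, valid = shifted_intensities(M, labels)
    var = maps.var[..., None]
    ll = -0.5 * np.log(2.0 * np.pi * var) - (vals - maps.mu[..., None]) ** 2 / (2.0 * var)
    n_valid = valid.sum(axis=-1)
    # log-mean-exp over the valid labels of each pixel
    masked = np.where(valid, ll, -np.inf)
    mx = masked.max(axis=-1)
    safe_mx = np.where(np.isfinite(mx), mx, 0.0)
    sumexp = np.exp(np.clip(masked - safe_mx[..., None], -745.0, 0.0)).sum(axis=-1)
    neutral = np.where(
        n_valid > 0, safe_mx + np.log(np.maximum(sumexp, LOG_FLOOR)) - np.log(np.maximum(n_valid, 1)), 0.0
    )
    ll = np.where(valid, ll, neutral[..., None])
    return ll, valid


def landmark_log_factors(
    landmarks: Optional[LandmarkSet],
    shape: tuple,
    spacing: float,
    labels: DisplacementLabelSet,
    sigma_k: Optional[float] = None,
) -> list:
    """Per-landmark log factors, applied at the histology landmark pixel.

    Each entry is ``(i, j, vec)`` with ``vec[s] = -||k^h - k + Delta_s||^2 /
    (2 sigma_k^2)``.  Landmarks whose histology point does not coincide with a
    grid pixel are snapped to the nearest pixel (the model assumes on-grid
    placement).
    """
    out = []
    if landmarks is None or len(landmarks) == 0:
        return out
    sk = landmarks.sigma_k if sigma_k is None else sigma_k
    h, w = shape
    for k_mri, k_hist in zip(landmarks.mri, landmarks.hist):
        j = int(round(k_hist[0] / spacing))
        i = int(round(k_hist[1] / spacing))
        if not (0 <= i < h and 0 <= j < w):
            continue
        resid = (k_hist - k_mri)[None, :] + labels.deltas
        out.append((i, j, -(resid ** 2).sum(axis=1) / (2.0 * sk ** 2)))
    return out


def _neighbour_sums(arr: np.ndarray) -> np.ndarray:
    """Sum of the 4-neighbour values at each pixel (missing neighbours omitted)."""
    out = np.zeros_like(arr)
    out[1:] += arr[:-1]
    out[:-1] += arr[1:]
    out[:, 1:] += arr[:, :-1]
    out[:, :-1] += arr[:, 1:]
    return out


def _neighbour_counts(shape: tuple) -> np.ndarray:
    return _neighbour_sums(np.ones(shape))


def _softmax(logp: np.ndarray) -> np.ndarray:
    mx = logp.max(axis=-1, keepdims=True)
    p = np.exp(logp - mx)
    tot = p.sum(axis=-1, keepdims=True)
    dead = tot.squeeze(-1) <= 0.0
    if np.any(dead):
        # total underflow: reset to uniform (logged)
        logger.warning("belief underflow at %d pixel(s); reset to uniform", int(dead.sum()))
        p[dead] = 1.0
        tot = p.sum(axis=-1, keepdims=True)
    return p / tot


def estep_update(
    beliefs: np.ndarray,
    maps: PredictionMaps,
    M: Image2D,
    landmarks: Optional[LandmarkSet],
    labels: DisplacementLabelSet,
    beta1: float,
    beta2: float,
    sigma_k: float = 0.5,
    max_inner: int = 50,
    tol: float = 1e-4,
) -> np.ndarray:
    """Fixed-point sweeps of the mean-field update for one image pair.

    Pixels are updated in red-black (checkerboard) order; the loop stops when
    the largest per-pixel L1 change of q falls below ``tol`` or after
    ``max_inner`` sweeps.  With ``beta2 = 0`` and no landmarks a single sweep
    reaches the closed-form per-pixel posterior.
    """
    q = np.array(beliefs, dtype=np.float64)
    h, w = M.shape
    S = labels.n_labels
    ll, _ = log_likelihood_table(M, maps, labels)
    sq = labels.squared_norms()
    static = ll - beta1 * sq[None, None, :]
    for i, j, vec in landmark_log_factors(landmarks, (h, w), M.spacing, labels, sigma_k):
        static[i, j] += vec

    if beta2 == 0.0:
        return _softmax(static)

    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    parity = (ii + jj) % 2
    cnt = _neighbour_counts((h, w))
    deltas = labels.deltas
    sels = [parity == 0, parity == 1]
    static_half = [static[s] for s in sels]
    cnt_half = [cnt[s, None] for s in sels]
    for sweep in range(max_inner):
        change = 0.0
        for par in (0, 1):
            m1 = q @ deltas          # (H, W, 2)  E[Delta']
            m2 = q @ sq              # (H, W)     E[||Delta'||^2]
            s1 = np.stack([_neighbour_sums(m1[..., 0]), _neighbour_sums(m1[..., 1])], axis=-1)
            s2 = _neighbour_sums(m2)
            sel = sels[par]
            pair = -beta2 * (
                cnt_half[par] * sq[None, :]
                - 2.0 * (s1[sel] @ deltas.T)
                + s2[sel, None]
            )
            pair += static_half[par]
            q_new = _softmax(pair)
            change = max(change, float(np.abs(q_new - q[sel]).sum(axis=-1).max()))
            q[sel] = q_new
        if change < tol:
            break
    return q


def free_energy(
    q: np.ndarray,
    maps: PredictionMaps,
    M: Image2D,
    landmarks: Optional[LandmarkSet],
    labels: DisplacementLabelSet,
    beta1: float,
    beta2: float,
    sigma_k: float = 0.5,
) -> float:
    """Evidence-lower-bound style diagnostic (up to constants).

    Entropy of q plus the expected log-likelihood, unary, landmark and
    pairwise prior terms under the factorised q.  Non-decreasing across
    E-step sweeps at fixed forest parameters (the pairwise term uses each
    unordered neighbour pair once).
    """
    ll, _ = log_likelihood_table(M, maps, labels)
    sq = labels.squared_norms()
    logterm = ll - beta1 * sq[None, None, :]
    for i, j, vec in landmark_log_factors(landmarks, M.shape, M.spacing, labels, sigma_k):
        logterm[i, j] += vec
    qs = np.maximum(q, LOG_FLOOR)
    entropy = -(qs * np.log(qs)).sum()
    expected = (q * logterm).sum()
    m1 = q @ labels.deltas
    m2 = q @ sq
    pair = 0.0
    for axis in (0, 1):
        a = [slice(None)] * 2
        b = [slice(None)] * 2
        a[axis], b[axis] = slice(1, None), slice(None, -1)
        a, b = tuple(a), tuple(b)
        pair += (m2[a] + m2[b] - 2.0 * (m1[a] * m1[b]).sum(-1)).sum()
    return float(entropy + expected - beta2 * pair)


def mstep_update(
    features: Sequence[FeatureStack],
    mri: Sequence[Image2D],
    beliefs: Sequence[np.ndarray],
    labels: DisplacementLabelSet,
    hyper: ForestHyperparams,
    rng: np.random.Generator,
    config: Optional[RunConfig] = None,
    candidate_mask: Optional[Sequence[np.ndarray]] = None,
):
    """Retrain the forest under the current beliefs; return (model, maps)."""
    kw = {}
    if config is not None:
        kw = dict(
            image_bag_fraction=config.image_bag_fraction,
            pixel_bag_fraction=config.pixel_bag_fraction,
            pooled_pixel_budget=config.pooled_pixel_budget,
        )
    model = synthesis.fit(
        features, mri, beliefs, labels, hyper, rng, candidate_mask=candidate_mask, **kw
    )
    maps = [synthesis.predict(model, f) for f in features]
    return model, maps


@dataclass
class VemState:
    """Final state of the VEM loop."""

    beliefs: List[np.ndarray]
    model: SynthesisModel
    maps: List[PredictionMaps]
    labels: DisplacementLabelSet
    iteration: int
    history: List[dict] = field(default_factory=list)
    converged: bool = False


def run(
    mri: Sequence[Image2D],
    hist: Sequence[Image2D],
    landmarks: Optional[Sequence[Optional[LandmarkSet]]] = None,
    config: Optional[RunConfig] = None,
    labels: Optional[DisplacementLabelSet] = None,
    rng: Optional[np.random.Generator] = None,
    features: Optional[Sequence[FeatureStack]] = None,
) -> VemState:
    """Run the full VEM loop on coarsely pre-aligned image pairs.

    Beliefs start uniform; the forest is initialised by a stochastic fit
    under those uniform beliefs, and E/M steps alternate until the relative
    L2 change of the predictive mean maps drops below ``config.outer_tol``
    or ``config.max_outer`` iterations have run (in which case the best state
    is returned with ``converged=False``).
    """
    from .deformation import make_label_set

    config = config or RunConfig()
    if labels is None:
        labels = make_label_set(config.label_radius, config.label_step)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_pairs = len(mri)
    if landmarks is None:
        landmarks = [None] * n_pairs
    if features is None:
        features = [synthesis.extract_features(h) for h in hist]
    hyper = ForestHyperparams(
        a=config.a,
        b=config.b,
        n_trees=config.n_trees,
        min_leaf=config.min_leaf,
        n_split_features=config.n_split_features,
    )
    masks = [h.mask for h in hist]
    beliefs = [init_beliefs(m.shape, labels) for m in mri]
    # initialise theta by a stochastic forest fit under the uniform beliefs
    model = synthesis.fit(
        features,
        mri,
        beliefs,
        labels,
        hyper,
        rng,
        image_bag_fraction=config.image_bag_fraction,
        pixel_bag_fraction=config.pixel_bag_fraction,
        pooled_pixel_budget=config.pooled_pixel_budget,
        candidate_mask=masks,
    )
    history: List[dict] = []
    converged = False
    prev_maps = None
    maps = []
    it = 0
    if config.max_outer < 1:
        maps = [synthesis.predict(model, f) for f in features]
        return VemState(beliefs, model, maps, labels, 0, history, False)
    for it in range(1, config.max_outer + 1):
        # E-step: maps from the current forest, then fixed-point sweeps of q
        maps = [synthesis.predict(model, f) for f in features]
        for n in range(n_pairs):
            beliefs[n] = estep_update(
                beliefs[n],
                maps[n],
                mri[n],
                landmarks[n],
                labels,
                config.beta1,
                config.beta2,
                sigma_k=config.sigma_k,
                max_inner=config.max_inner,
                tol=config.inner_tol,
            )
        if prev_maps is not None:
            rel_mu = max(
                float(
                    np.linalg.norm(maps[n].mu - prev_maps[n].mu)
                    / max(np.linalg.norm(prev_maps[n].mu), 1e-12)
                )
                for n in range(n_pairs)
            )
            rel_var = max(
                float(
                    np.linalg.norm(maps[n].var - prev_maps[n].var)
                    / max(np.linalg.norm(prev_maps[n].var), 1e-12)
                )
                for n in range(n_pairs)
            )
        else:
            rel_mu = rel_var = np.inf
        history.append({"iteration": it, "rel_change_mu": rel_mu, "rel_change_var": rel_var})
        logger.info("VEM iter %d: rel d(mu)=%.4g rel d(var)=%.4g", it, rel_mu, rel_var)
        prev_maps = maps
        if rel_mu < config.outer_tol:
            converged = True
            break
        # M-step: retrain under the updated beliefs
        model = synthesis.fit(
            features,
            mri,
            beliefs,
            labels,
            hyper,
            rng,
            image_bag_fraction=config.image_bag_fraction,
            pixel_bag_fraction=config.pixel_bag_fraction,
            pooled_pixel_budget=config.pooled_pixel_budget,
            candidate_mask=masks,
        )
    if not converged:
        logger.warning("VEM did not converge within %d outer iterations", config.max_outer)
    return VemState(beliefs, model, maps, labels, it, history, converged)
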