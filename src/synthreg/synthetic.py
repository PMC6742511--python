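"""Self-contained synthetic test data: multi-contrast phantom pairs,
ground-truth diffeomorphic deformations, Harris-corner landmark pairs and
histology-style artefacts.

The phantom stands in for preprocessed multi-contrast brain slices: a smooth
random tissue label map inside an elliptical "brain" mask, with per-class
intensities that differ (and may be non-monotonically related) between the
two modalities, a smooth multiplicative bias field and additive noise.
Modality A plays the role of the histological section (the fixed image whose
features drive the synthesis) and the deformed modality B plays the MRI.

Deformations are generated exactly as in the evaluation protocol this module
supports: a stationary velocity field (i.i.d. bivariate Gaussian noise,
Gaussian-smoothed, boundary-windowed) integrated by scaling and squaring,
composed with a random similarity transform.  Because the deformed B is
produced by resampling with a map psi, the field the registration must
recover is the displacement of psi^{-1}; the pair stores both fields (see
``SyntheticPair``).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .deformation import (
    DisplacementLabelSet,
    VelocityField,
    compose_displacements,
    integrate_velocity,
    sample_similarity_params,
    sample_velocity,
    similarity_displacement,
    warp_array,
)
from .io import DeformationField, Image2D, LandmarkSet, rescale_intensities

__all__ = [
    "PhantomSpec",
    "ArtefactSpec",
    "SyntheticPair",
    "make_phantom",
    "make_pair",
    "make_landmarks",
    "add_artefacts",
]


@dataclass
class PhantomSpec:
    """Geometry and appearance of the two-modality phantom.

    The default class intensity tables are deliberately non-monotonically
    related between modalities (bright A-classes are not bright B-classes),
    so that the pair is genuinely inter-modality: no affine intensity map
    links A and B.
    """

    shape: tuple = (128, 128)
    spacing: float = 1.0
    n_tissue_classes: int = 3
    intensities_a: tuple = (70.0, 140.0, 220.0)
    intensities_b: tuple = (200.0, 60.0, 140.0)
    background_a: float = 0.0
    background_b: float = 0.0
    noise_std: float = 2.0
    # independent smooth multiplicative bias per modality: staining
    # inhomogeneity on the histology-like modality A is typically much
    # stronger than scanner bias on the MRI-like modality B, and the two
    # have no reason to coincide spatially.  A global intensity-mapping
    # metric cannot model the resulting spatially varying contrast; the
    # synthesis model absorbs it through its location features.
    bias_amplitude: float = 0.35
    bias_amplitude_b: float = 0.1
    texture_sigma_px: float = 6.0
    # point-spread blur applied after rendering (px); emulates the partial
    # volume of scanner acquisition plus resampling, which leaves tissue
    # interfaces 2-3 px wide rather than razor-sharp
    psf_sigma_px: float = 0.8
    # shared anatomical texture: one smooth structural field modulates both
    # modalities with class-specific gains (sign and magnitude differ between
    # modalities, so the A-B intensity relation stays non-affine); emulates
    # the within-tissue structure that real multi-contrast slices share
    structure_gain_a: tuple = (8.0, 6.0, 8.0)
    structure_gain_b: tuple = (-7.0, 8.0, -6.0)
    structure_sigma_px: float = 4.0

    def __post_init__(self) -> None:
        if len(self.intensities_a) != self.n_tissue_classes:
            raise ValueError("need one modality-A intensity per tissue class")
        if len(self.intensities_b) != self.n_tissue_classes:
            raise ValueError("need one modality-B intensity per tissue class")
        if len(set(self.intensities_a)) != self.n_tissue_classes or len(
            set(self.intensities_b)
        ) != self.n_tissue_classes:
            raise ValueError("class intensities must be distinct within each modality")
        if self.noise_std < 0:
            raise ValueError("noise std must be >= 0")


@dataclass
class ArtefactSpec:
    """Histology-style artefacts: dark crack line segments and elliptical holes."""

    n_cracks: int = 2
    crack_width_px: int = 2
    n_holes: int = 1
    hole_radius_px: float = 5.0
    intensity: float = 10.0


@dataclass
class SyntheticPair:
    """A phantom pair with known deformation and landmarks.

    ``warp_field``  — the exact field used to resample modality B
                      (B_deformed(x) = B(x + warp_field(x))).
    ``truth_field`` — displacement of the inverse map: the field a perfect
                      registration of the deformed B onto A-space recovers
                      (so B_deformed(x + truth_field(x)) = B(x)).
    """

    fixed: Image2D
    moving: Image2D
    warp_field: DeformationField
    truth_field: DeformationField
    landmarks: Optional[LandmarkSet]
    seed_record: dict = dataclass_field(default_factory=dict)


def _brain_mask(shape: tuple, semi_axes=(0.42, 0.45)) -> np.ndarray:
    h, w = shape
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    return ((jj - cx) / (semi_axes[0] * w)) ** 2 + ((ii - cy) / (semi_axes[1] * h)) ** 2 <= 1.0


def _tissue_labels(spec: PhantomSpec, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth-noise blobs thresholded into n classes by quantiles (0 = background)."""
    noise = gaussian_filter(rng.normal(size=spec.shape), spec.texture_sigma_px)
    labels = np.zeros(spec.shape, dtype=np.int64)
    vals = noise[mask]
    qs = np.quantile(vals, np.linspace(0, 1, spec.n_tissue_classes + 1)[1:-1])
    labels[mask] = 1 + np.searchsorted(qs, noise[mask])
    return labels


def _render(labels, mask, intensities, background, bias, noise_std, rng,
            structure=None, gains=None, psf_sigma_px=0.0):
    img = np.full(labels.shape, float(background))
    for c, val in enumerate(intensities, start=1):
        img[labels == c] = val
    if structure is not None and gains is not None:
        for c, gain in enumerate(gains, start=1):
            sel = labels == c
            img[sel] += gain * structure[sel]
    img *= bias
    img = np.where(mask, img, background)
    if psf_sigma_px > 0:
        img = gaussian_filter(img, psf_sigma_px)
    if noise_std > 0:
        img = img + rng.normal(0.0, noise_std, size=img.shape)
    img = rescale_intensities(img)
    return np.round(img)  # 8-bit quantisation


def make_phantom(spec: PhantomSpec, seed) -> tuple:
    """Generate the two phantom modalities (A, B) on a shared label map.

    Both images are rescaled to [0, 255] and quantised to 8-bit precision.
    Deterministic given (spec, seed).
    """
    rng = np.random.default_rng(seed)
    mask = _brain_mask(spec.shape)
    labels = _tissue_labels(spec, mask, rng)
    def draw_bias(amp):
        if amp <= 0:
            return np.ones(spec.shape)
        raw = gaussian_filter(rng.normal(size=spec.shape), max(spec.shape) / 5.0)
        rg = max(np.abs(raw).max(), 1e-12)
        return 1.0 + amp * raw / rg

    bias_a = draw_bias(spec.bias_amplitude)
    bias_b = draw_bias(spec.bias_amplitude_b)
    structure = None
    if spec.structure_gain_a is not None and spec.structure_sigma_px > 0:
        structure = gaussian_filter(rng.normal(size=spec.shape), spec.structure_sigma_px)
        structure /= max(structure.std(), 1e-12)
    img_a = _render(labels, mask, spec.intensities_a, spec.background_a, bias_a, spec.noise_std,
                    rng, structure, spec.structure_gain_a, spec.psf_sigma_px)
    img_b = _render(labels, mask, spec.intensities_b, spec.background_b, bias_b, spec.noise_std,
                    rng, structure, spec.structure_gain_b, spec.psf_sigma_px)
    a = Image2D(img_a, spacing=spec.spacing, mask=mask)
    b = Image2D(img_b, spacing=spec.spacing, mask=mask)
    return a, b


def make_pair(
    spec: PhantomSpec,
    sigma_v: float,
    seed,
    n_landmarks: int = 0,
    sigma_k: float = 0.5,
    smooth_sigma_mm: float = 5.0,
    rot_std_deg: float = 2.0,
    trans_std_px: float = 1.0,
    logscale_std: float = 0.1,
) -> SyntheticPair:
    """Generate a deformed phantom pair with exact ground truth.

    The deformation applied to modality B is psi = similarity o exp(v), with
    v a random smooth velocity field at noise level ``sigma_v`` (mm) and the
    similarity drawn from zero-mean Gaussians (defaults: 2 deg rotation,
    1 px translation, 0.1 log-scale).  ``truth_field`` is the exact inverse
    displacement, built from exp(-v) and the analytic similarity inverse.
    """
    rng = np.random.default_rng(seed)
    phantom_seed, vel_seed, sim_seed, lm_seed = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in np.random.SeedSequence(seed).spawn(4)
    ]
    fixed, b0 = make_phantom(spec, phantom_seed)
    vel = sample_velocity(
        spec.shape, spec.spacing, sigma_v, np.random.default_rng(vel_seed),
        smooth_sigma_mm=smooth_sigma_mm,
    )
    u_fwd = integrate_velocity(vel)
    neg = VelocityField(-vel.v, vel.spacing, vel.sigma_v, vel.smoothing_sigma)
    u_bwd = integrate_velocity(neg)
    rot, slog, trans = sample_similarity_params(
        np.random.default_rng(sim_seed), rot_std_deg, trans_std_px, logscale_std
    )
    # psi = sim o exp(v):  resampling map applied to modality B
    sim_fwd = similarity_displacement(spec.shape, spec.spacing, rot, slog, trans)
    warp_u = compose_displacements(sim_fwd, u_fwd.u, spec.spacing)
    # psi^{-1} = exp(-v) o sim^{-1}:  ground truth for the registration
    sim_inv = similarity_displacement(spec.shape, spec.spacing, rot, slog, trans, inverse=True)
    truth_u = compose_displacements(u_bwd.u, sim_inv, spec.spacing)
    moving_px, invalid = warp_array(b0.pixels, warp_u, spec.spacing)
    moving = Image2D(moving_px, spacing=spec.spacing, mask=~invalid)
    warp_field = DeformationField(warp_u, spacing=spec.spacing, is_ground_truth=True)
    truth_field = DeformationField(truth_u, spacing=spec.spacing, is_ground_truth=True)
    landmarks = None
    if n_landmarks > 0:
        landmarks = make_landmarks(
            fixed, truth_field, n_landmarks, sigma_k, np.random.default_rng(lm_seed)
        )
    return SyntheticPair(
        fixed,
        moving,
        warp_field,
        truth_field,
        landmarks,
        seed_record={
            "seed": seed,
            "phantom_seed": phantom_seed,
            "sigma_v": sigma_v,
            "similarity": {"rot_deg": rot, "scale_log": slog, "trans_px": tuple(trans)},
        },
    )


def make_landmarks(
    fixed: Image2D,
    truth_field: DeformationField,
    n_landmarks: int,
    sigma_k: float,
    rng: np.random.Generator,
    harris_k: float = 0.05,
    harris_sigma_px: float = 1.0,
) -> LandmarkSet:
    """Spatially spread landmark pairs from Harris corners of the fixed image.

    Iteratively: take the Harris-response argmax (row-major tie-break) as the
    histology-side landmark, map it through the ground-truth field and
    perturb with Gaussian noise of std ``sigma_k`` to get the MRI-side
    landmark, then multiply the response by the complementary Gaussian
    1 - exp(-0.5 ||x - x_max||^2 / sigma^2) with per-axis sigma equal to a
    tenth of the image dimensions, pushing later landmarks away.
    """
    from skimage.feature import corner_harris

    if n_landmarks == 0:
        return LandmarkSet(np.zeros((0, 2)), np.zeros((0, 2)), sigma_k=max(sigma_k, 1e-6))
    resp = corner_harris(fixed.pixels / 255.0, k=harris_k, sigma=harris_sigma_px)
    if fixed.mask is not None:
        resp = np.where(fixed.mask, resp, -np.inf)
    h, w = fixed.shape
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    sig_y, sig_x = h / 10.0, w / 10.0
    hist_pts, mri_pts = [], []
    for _ in range(n_landmarks):
        if not np.isfinite(resp).any() or resp.max() <= 0:
            break
        imax, jmax = np.unravel_index(np.argmax(resp), resp.shape)
        k_hist = np.array([jmax * fixed.spacing, imax * fixed.spacing])
        disp = truth_field.u[imax, jmax]
        noise = rng.normal(0.0, sigma_k, size=2) if sigma_k > 0 else np.zeros(2)
        mri_pts.append(k_hist + disp + noise)
        hist_pts.append(k_hist)
        suppress = 1.0 - np.exp(
            -0.5 * (((ii - imax) / sig_y) ** 2 + ((jj - jmax) / sig_x) ** 2)
        )
        resp = resp * suppress
    if len(hist_pts) < n_landmarks:
        import logging

        logging.getLogger("synthreg").warning(
            "only %d of %d requested landmarks found", len(hist_pts), n_landmarks
        )
    return LandmarkSet(np.array(mri_pts), np.array(hist_pts), sigma_k=max(sigma_k, 1e-6))


def add_artefacts(image: Image2D, spec: ArtefactSpec, rng: np.random.Generator) -> tuple:
    """Corrupt an image with dark cracks and holes; returns (image, mask).

    The mask flags exactly the corrupted pixels.  The artefacts emulate the
    cracks/holes of mounted histological sections and exercise the
    variance-based downweighting of the synthesis.
    """
    from skimage.draw import ellipse, line
    from skimage.morphology import disk, dilation

    px = image.pixels.copy()
    h, w = image.shape
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_cracks):
        r0, r1 = rng.integers(h // 6, 5 * h // 6, size=2)
        c0, c1 = rng.integers(w // 6, 5 * w // 6, size=2)
        rr, cc = line(int(r0), int(c0), int(r1), int(c1))
        stroke = np.zeros((h, w), dtype=bool)
        stroke[rr, cc] = True
        if spec.crack_width_px > 1:
            stroke = dilation(stroke, disk(spec.crack_width_px // 2))
        mask |= stroke
    for _ in range(spec.n_holes):
        rc = rng.integers(h // 4, 3 * h // 4)
        cc_ = rng.integers(w // 4, 3 * w // 4)
        rr, cc = ellipse(int(rc), int(cc_), spec.hole_radius_px, spec.hole_radius_px, shape=(h, w))
        mask[rr, cc] = True
    px[mask] = spec.intensity
    return Image2D(px, spacing=image.spacing, mask=image.mask), mask
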