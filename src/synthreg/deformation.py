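"""Displacement label sets, the MRF deformation prior, field application and
diffeomorphic field generation by scaling and squaring.

The deformation model is discrete: at every pixel the displacement takes a
value from a finite label set {Delta_s}, a square grid of 2D vectors in mm.
The prior over fields is a Markov random field with unary potentials
penalising squared displacement magnitude (weight beta1) and pairwise
potentials penalising the squared difference between 4-neighbours (weight
beta2); each unordered neighbour pair is counted once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .io import DeformationField, Image2D

__all__ = [
    "DisplacementLabelSet",
    "VelocityField",
    "make_label_set",
    "warp_image",
    "warp_array",
    "mrf_log_prior",
    "sample_velocity",
    "integrate_velocity",
    "compose_displacements",
    "similarity_displacement",
    "sample_similarity_params",
    "compose_with_similarity",
    "jacobian_determinant",
]


@dataclass
class DisplacementLabelSet:
    """The finite set {Delta_s} of candidate 2D displacements (mm).

    ``deltas`` has shape (S, 2) with channel order (dx, dy); the grid covers
    the square [-radius, radius]^2 in increments of ``step`` and always
    contains the zero vector.
    """

    deltas: np.ndarray
    radius: float
    step: float

    @property
    def n_labels(self) -> int:
        return self.deltas.shape[0]

    @property
    def zero_index(self) -> int:
        return int(np.argmin(np.einsum("sd,sd->s", self.deltas, self.deltas)))

    def squared_norms(self) -> np.ndarray:
        return np.einsum("sd,sd->s", self.deltas, self.deltas)

    def pairwise_sq_dist(self) -> np.ndarray:
        """(S, S) matrix of ||Delta_s - Delta_s'||^2 in mm^2."""
        d = self.deltas[:, None, :] - self.deltas[None, :, :]
        return (d ** 2).sum(-1)


def make_label_set(radius_mm: float, step_mm: float) -> DisplacementLabelSet:
    """Build the square displacement grid [-radius, radius]^2 at ``step`` mm.

    ``radius`` must be a positive integer multiple of ``step``; the number of
    labels is S = (2 * radius / step + 1)^2.
    """
    if not (step_mm > 0 and radius_mm >= step_mm):
        raise ValueError("need radius >= step > 0")
    n = radius_mm / step_mm
    if abs(n - round(n)) > 1e-9:
        raise ValueError("radius must be an integer multiple of step")
    n = int(round(n))
    axis = np.arange(-n, n + 1) * step_mm
    dy, dx = np.meshgrid(axis, axis, indexing="ij")
    deltas = np.stack([dx.ravel(), dy.ravel()], axis=-1)
    return DisplacementLabelSet(deltas, float(radius_mm), float(step_mm))


def warp_array(pixels: np.ndarray, u: np.ndarray, spacing: float, order: int = 1):
    """Sample ``pixels`` at x + u(x); returns (warped, invalid_mask).

    Out-of-bounds samples are set to 0 and flagged in ``invalid_mask``.
    """
    h, w = pixels.shape
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    cols = jj + u[..., 0] / spacing
    rows = ii + u[..., 1] / spacing
    warped = map_coordinates(pixels, [rows, cols], order=order, mode="constant", cval=0.0)
    invalid = (rows < 0) | (rows > h - 1) | (cols < 0) | (cols > w - 1)
    return warped, invalid


def warp_image(image: Image2D, field: DeformationField) -> Image2D:
    """Warp an image by a displacement field: output(x) = input(x + U(x)).

    Bilinear interpolation; pixels whose sample point falls outside the
    domain are zeroed and excluded via the output mask.
    """
    if image.shape != field.shape:
        raise ValueError("image and field shapes must match")
    warped, invalid = warp_array(image.pixels, field.u, image.spacing)
    valid = ~invalid
    if image.mask is not None:
        valid = valid & image.mask
    return Image2D(warped, spacing=image.spacing, mask=valid)


def _neighbour_diff_energy(u: np.ndarray) -> float:
    # sum over unordered 4-neighbour pairs of ||u(x) - u(x')||^2
    dv = np.diff(u, axis=0)
    dh = np.diff(u, axis=1)
    return float((dv ** 2).sum() + (dh ** 2).sum())


def mrf_log_prior(field: DeformationField, beta1: float, beta2: float) -> float:
    """Log of the MRF prior up to its (never evaluated) normalising constant.

    Returns ``-beta1 * sum ||U||^2 - beta2 * sum_edges ||U(x) - U(x')||^2``
    over 4-neighbour edges, each edge counted once.  Maximal (= 0) at U = 0.
    """
    if beta1 < 0 or beta2 < 0:
        raise ValueError("beta1 and beta2 must be >= 0")
    u = field.u
    unary = float((u ** 2).sum())
    return -beta1 * unary - beta2 * _neighbour_diff_energy(u)


@dataclass
class VelocityField:
    """Stationary velocity field (mm) used to generate diffeomorphisms."""

    v: np.ndarray
    spacing: float
    sigma_v: float
    smoothing_sigma: float


def _boundary_window(shape: tuple, spacing: float, rate: float = 0.1) -> np.ndarray:
    """w(x) = 1 - exp(-rate * D(x)), D = distance to image boundary in mm.

    Zero on boundary pixels, -> 1 in the interior; keeps generated
    deformations from pushing content over the image edge.  The default
    rate of 0.1 / mm saturates the window (w > 0.95) about 30 mm inside
    the boundary, so desk-scale images get full-strength deformations in
    their interior while the edges stay pinned.
    """
    h, w = shape
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    d = np.minimum.reduce([ii, jj, h - 1 - ii, w - 1 - jj]) * spacing
    return 1.0 - np.exp(-rate * d)


def sample_velocity(
    shape: tuple,
    spacing: float,
    sigma_v: float,
    rng: np.random.Generator,
    smooth_sigma_mm: float = 5.0,
    window: bool = True,
    window_rate: float = 0.1,
) -> VelocityField:
    """Draw a random smooth velocity field.

    Per pixel, i.i.d. bivariate Gaussian noise with std ``sigma_v`` (mm, no
    x-y correlation), smoothed with a Gaussian filter of ``smooth_sigma_mm``
    and multiplied by a window that vanishes at the image boundary.
    """
    if sigma_v < 0:
        raise ValueError("sigma_v must be >= 0")
    v = rng.normal(0.0, sigma_v, size=(*shape, 2)) if sigma_v > 0 else np.zeros((*shape, 2))
    if sigma_v > 0 and smooth_sigma_mm > 0:
        sig_px = smooth_sigma_mm / spacing
        for c in range(2):
            v[..., c] = gaussian_filter(v[..., c], sig_px)
    if window:
        v *= _boundary_window(shape, spacing, window_rate)[..., None]
    return VelocityField(v, spacing, sigma_v, smooth_sigma_mm)


def compose_displacements(outer: np.ndarray, inner: np.ndarray, spacing: float) -> np.ndarray:
    """Displacement of the composed map (x -> x + inner(x) -> + outer(...)).

    Returns w with x + w(x) = (x + inner(x)) + outer(x + inner(x)); the outer
    field is resampled bilinearly (edge-replicated) at the displaced points.
    """
    h, w_ = outer.shape[:2]
    ii, jj = np.meshgrid(np.arange(h), np.arange(w_), indexing="ij")
    rows = ii + inner[..., 1] / spacing
    cols = jj + inner[..., 0] / spacing
    out = np.empty_like(outer)
    for c in range(2):
        out[..., c] = inner[..., c] + map_coordinates(
            outer[..., c], [rows, cols], order=1, mode="nearest"
        )
    return out


def integrate_velocity(vel: VelocityField, n_squarings: int | None = None) -> DeformationField:
    """Integrate a stationary velocity field over unit time (scaling and
    squaring), yielding a diffeomorphic displacement field.

    The number of squarings defaults to ceil(log2(max ||v|| / (0.5 * spacing)))
    with a floor of 4, so the initial scaled displacement is below half a
    pixel.  Each squaring composes the field with itself by bilinear
    resampling.
    """
    v = vel.v
    if n_squarings is None:
        max_disp = float(np.linalg.norm(v, axis=-1).max())
        if max_disp == 0.0:
            n_squarings = 4
        else:
            n_squarings = max(4, int(np.ceil(np.log2(max_disp / (0.5 * vel.spacing)))))
    if n_squarings < 1:
        raise ValueError("n_squarings must be >= 1")
    u = v / (2 ** n_squarings)
    for _ in range(n_squarings):
        u = compose_displacements(u, u, vel.spacing)
    return DeformationField(u, spacing=vel.spacing)


def sample_similarity_params(
    rng: np.random.Generator,
    rot_std_deg: float = 2.0,
    trans_std_px: float = 1.0,
    logscale_std: float = 0.1,
) -> tuple:
    """Draw (rot_deg, scale_log, (tx_px, ty_px)) from zero-mean Gaussians."""
    return (
        float(rng.normal(0.0, rot_std_deg)),
        float(rng.normal(0.0, logscale_std)),
        tuple(rng.normal(0.0, trans_std_px, size=2)),
    )


def similarity_displacement(
    shape: tuple,
    spacing: float,
    rot_deg: float,
    scale_log: float,
    trans_px: tuple,
    inverse: bool = False,
) -> np.ndarray:
    """Dense displacement of a similarity transform about the image centre.

    The forward map is A(x) = c + s R (x - c) + t with s = exp(scale_log),
    R a CCW rotation by ``rot_deg`` and t = trans_px * spacing (mm).
    """
    h, w = shape
    cx, cy = (w - 1) * spacing / 2.0, (h - 1) * spacing / 2.0
    th = np.deg2rad(rot_deg)
    s = np.exp(scale_log)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    t = np.asarray(trans_px, dtype=np.float64) * spacing
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pts = np.stack([jj * spacing - cx, ii * spacing - cy], axis=-1)
    if inverse:
        # A^-1(x) = c + (1/s) R^T (x - c - t)
        mapped = (pts - t) @ (R / s)  # == (1/s) R^T p, row-vector convention
    else:
        mapped = s * (pts @ R.T) + t
    return mapped - pts


def compose_with_similarity(
    field: DeformationField,
    rot_deg: float = 0.0,
    scale_log: float = 0.0,
    trans_px: tuple = (0.0, 0.0),
) -> DeformationField:
    """Displacement of (similarity o nonlinear): x -> A(x + U(x)).

    With the identity similarity this returns U unchanged; with U = 0 and a
    pure translation t it returns the constant field t.
    """
    sim = similarity_displacement(field.shape, field.spacing, rot_deg, scale_log, trans_px)
    composed = compose_displacements(sim, field.u, field.spacing)
    return DeformationField(composed, spacing=field.spacing)


def jacobian_determinant(field: DeformationField) -> np.ndarray:
    """Finite-difference Jacobian determinant of x -> x + U(x), per pixel."""
    u = field.u / field.spacing  # displacement in pixels
    dux_dy, dux_dx = np.gradient(u[..., 0])
    duy_dy, duy_dx = np.gradient(u[..., 1])
    return (1.0 + dux_dx) * (1.0 + duy_dy) - dux_dy * duy_dx
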