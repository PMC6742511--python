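"""Data containers and file I/O for images, landmarks, deformation fields and run
configuration.

Conventions used throughout the package
---------------------------------------
* Pixel grids are indexed ``pixels[i, j]`` with ``i`` the row (y) and ``j`` the
  column (x) index, 0-based.
* Physical coordinates are in mm: a pixel centre sits at
  ``(x, y) = (j * spacing, i * spacing)``; the origin is the centre of pixel
  ``(0, 0)``.  Spacing is isotropic.
* Displacement vectors and fields are stored channel-last as ``(dx, dy)`` in mm.
* Landmarks are stored in mm, as ``(x, y)`` pairs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("synthreg")

__all__ = [
    "Image2D",
    "LandmarkSet",
    "DeformationField",
    "RunConfig",
    "read_image",
    "write_image",
    "read_landmarks",
    "write_landmarks",
    "read_field",
    "write_field",
    "read_config",
    "write_config",
    "rescale_intensities",
    "child_rngs",
]


def rescale_intensities(pixels: np.ndarray) -> np.ndarray:
    """Linearly rescale intensities to [0, 255].

    A constant image maps to all zeros (the degenerate range is resolved by
    convention rather than dividing by zero).
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi == lo:
        return np.zeros_like(pixels)
    return np.clip((pixels - lo) * (255.0 / (hi - lo)), 0.0, 255.0)


@dataclass
class Image2D:
    """A 2D grayscale image with isotropic pixel spacing in mm.

    Parameters
    ----------
    pixels : ndarray, shape (H, W)
        Intensities (float, arbitrary units; readers rescale to [0, 255]).
    spacing : float
        Isotropic pixel size in mm, > 0.
    mask : ndarray of bool, optional
        Foreground mask, same shape as ``pixels``.
    """

    pixels: np.ndarray
    spacing: float = 1.0
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D raster, got ndim={self.pixels.ndim}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")
        if not self.spacing > 0:
            raise ValueError("spacing must be > 0")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape:
                raise ValueError("mask shape must match pixels")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def extent_mm(self) -> tuple:
        """(width_mm, height_mm) spanned by pixel centres."""
        h, w = self.pixels.shape
        return ((w - 1) * self.spacing, (h - 1) * self.spacing)


@dataclass
class LandmarkSet:
    """Paired landmarks: ``mri[l]`` on the MRI slice, ``hist[l]`` on the
    histological section, both as (x, y) in mm.

    ``sigma_k`` is the standard deviation (mm) of the isotropic Gaussian
    placement-error model shared by all pairs.
    """

    mri: np.ndarray
    hist: np.ndarray
    sigma_k: float = 0.5

    def __post_init__(self) -> None:
        self.mri = np.atleast_2d(np.asarray(self.mri, dtype=np.float64)).reshape(-1, 2)
        self.hist = np.atleast_2d(np.asarray(self.hist, dtype=np.float64)).reshape(-1, 2)
        if self.mri.shape != self.hist.shape:
            raise ValueError("mri and hist landmark arrays must have matching shapes")
        if not self.sigma_k > 0:
            raise ValueError("sigma_k must be > 0")

    def __len__(self) -> int:
        return self.mri.shape[0]

    def separations(self) -> np.ndarray:
        """Euclidean distance (mm) between the two members of each pair."""
        if len(self) == 0:
            return np.zeros(0)
        return np.linalg.norm(self.hist - self.mri, axis=1)

    def drop_outside(self, shape: tuple, spacing: float) -> "LandmarkSet":
        """Drop pairs with either point outside the pixel-centre domain (warn)."""
        if len(self) == 0:
            return self
        h, w = shape
        xmax, ymax = (w - 1) * spacing, (h - 1) * spacing

        def inside(p):
            return (p[:, 0] >= 0) & (p[:, 0] <= xmax) & (p[:, 1] >= 0) & (p[:, 1] <= ymax)

        keep = inside(self.mri) & inside(self.hist)
        if not np.all(keep):
            logger.warning("dropping %d out-of-domain landmark pair(s)", int((~keep).sum()))
        return LandmarkSet(self.mri[keep], self.hist[keep], self.sigma_k)


@dataclass
class DeformationField:
    """Dense 2D displacement field (mm), defined on histology-space pixels.

    ``u[i, j] = (dx, dy)`` displaces the pixel centred at
    ``(j * spacing, i * spacing)``.
    """

    u: np.ndarray
    spacing: float = 1.0
    is_ground_truth: bool = False

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.u.ndim != 3 or self.u.shape[-1] != 2:
            raise ValueError("deformation field must have shape (H, W, 2)")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("deformation field must be finite")
        if not self.spacing > 0:
            raise ValueError("spacing must be > 0")

    @property
    def shape(self) -> tuple:
        return self.u.shape[:2]

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.u, axis=-1)

    def sample(self, points_mm: np.ndarray) -> np.ndarray:
        """Bilinearly interpolate the field at (x, y) points in mm."""
        from scipy.ndimage import map_coordinates

        points_mm = np.atleast_2d(np.asarray(points_mm, dtype=np.float64))
        cols = points_mm[:, 0] / self.spacing
        rows = points_mm[:, 1] / self.spacing
        out = np.empty((points_mm.shape[0], 2))
        for c in range(2):
            out[:, c] = map_coordinates(self.u[..., c], [rows, cols], order=1, mode="nearest")
        return out


# Reference defaults.  beta1 = beta2 = 0.02 (beta1 equivalent to a 5 mm
# prior std); sigma_k = 0.5 mm (standard deviation); Inverse-Gamma a = 2,
# b = 5^2 * a = 50; forest: 100 trees, min 5 samples per leaf, 5 features per
# split (= floor(sqrt(32))); MI: 64 bins; B-spline regularisation weights
# beta_b = 0.001, beta_l = 0.01, beta_j = 0.
@dataclass
class RunConfig:
    """All model and algorithm parameters with their default settings."""

    beta1: float = 0.02
    beta2: float = 0.02
    sigma_k: float = 0.5
    a: float = 2.0
    b: float = 50.0
    n_trees: int = 100
    min_leaf: int = 5
    n_split_features: int = 5
    mi_bins: int = 64
    beta_bending: float = 0.001
    beta_linear: float = 0.01
    beta_jacobian: float = 0.0
    # displacement label grid
    label_radius: float = 10.0
    label_step: float = 0.5
    # VEM loop control
    outer_tol: float = 1e-2
    max_outer: int = 10
    inner_tol: float = 1e-4
    max_inner: int = 50
    # B-spline control-point spacing (mm): proposed vs MI baseline
    cp_spacing: float = 6.0
    cp_spacing_mi: float = 18.0
    # forest bagging
    image_bag_fraction: float = 0.66
    pixel_bag_fraction: float = 0.66
    pooled_pixel_budget: int = 25000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("beta1", "beta2", "beta_bending", "beta_linear", "beta_jacobian"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.label_radius > 0 and self.label_step > 0):
            raise ValueError("label radius and step must be > 0")
        if not self.sigma_k > 0:
            raise ValueError("sigma_k must be > 0")

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def child_rngs(seed, n: int) -> list:
    """Spawn ``n`` independent Generators from one seed.

    Every stochastic operation in the package receives an explicit Generator;
    this is the single funnel through which runs are made reproducible.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_image(path, spacing_mm: float = 1.0) -> Image2D:
    """Read a 2D grayscale raster (PNG/TIFF or single-slice NIfTI).

    Intensities are rescaled to [0, 255] on ingest.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        import nibabel as nib

        arr = np.asanyarray(nib.load(str(path)).dataobj).squeeze()
    elif path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(tifffile.imread(str(path))).squeeze()
    else:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(str(path))).squeeze()
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D grayscale raster, got shape {arr.shape}")
    return Image2D(rescale_intensities(arr), spacing=spacing_mm)


def write_image(path, image: Image2D) -> None:
    """Write an image as 8-bit PNG, float TIFF, or NIfTI depending on suffix."""
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(image.pixels.astype(np.float32), np.eye(4)), str(path))
    elif path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), image.pixels.astype(np.float32))
    else:
        import imageio.v3 as iio

        iio.imwrite(str(path), np.clip(np.round(image.pixels), 0, 255).astype(np.uint8))


_LANDMARK_COLUMNS = ["x_mri", "y_mri", "x_hist", "y_hist"]


def read_landmarks(path, sigma_k: float = 0.5) -> LandmarkSet:
    """Read a landmark table (CSV with header x_mri,y_mri,x_hist,y_hist; mm)."""
    df = pd.read_csv(path)
    missing = [c for c in _LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing landmark column(s) {missing}")
    return LandmarkSet(
        df[["x_mri", "y_mri"]].to_numpy(dtype=np.float64),
        df[["x_hist", "y_hist"]].to_numpy(dtype=np.float64),
        sigma_k=sigma_k,
    )


def write_landmarks(path, landmarks: LandmarkSet) -> None:
    df = pd.DataFrame(
        np.hstack([landmarks.mri, landmarks.hist]) if len(landmarks) else np.zeros((0, 4)),
        columns=_LANDMARK_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_field(path, spacing_mm: Optional[float] = None) -> DeformationField:
    """Read a two-channel (dx, dy) displacement field in mm."""
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj).squeeze()
        if spacing_mm is None:
            spacing_mm = float(img.header.get_zooms()[0])
    else:
        import tifffile

        arr = np.asarray(tifffile.imread(str(path)))
        if spacing_mm is None:
            spacing_mm = 1.0
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3 and arr.shape[0] == 2 and arr.shape[-1] != 2:
        arr = np.moveaxis(arr, 0, -1)
    if arr.ndim != 3 or arr.shape[-1] != 2:
        raise ValueError(f"{path}: expected a two-channel field, got shape {arr.shape}")
    return DeformationField(arr, spacing=spacing_mm)


def write_field(path, field_: DeformationField) -> None:
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        aff = np.diag([field_.spacing, field_.spacing, 1.0, 1.0])
        nib.save(nib.Nifti1Image(field_.u.astype(np.float64), aff), str(path))
    else:
        import tifffile

        tifffile.imwrite(str(path), field_.u.astype(np.float64))


def write_config(path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def read_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**data)
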