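"""Model/Results interface to the joint synthesis-registration framework.

``JointSynthRegModel`` wraps the full probabilistic model: given a coarsely
pre-aligned MRI/histology pair (plus optional landmarks), ``fit`` runs the
variational EM loop, the discrete graph-cut registration and the continuous
B-spline refinement, and returns a ``JointSynthRegResults`` carrying the
estimated deformation, the synthesised contrast with its per-pixel
uncertainty, belief summaries and convergence diagnostics.
``MutualInfoRegistration`` is the matching baseline model.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import registration, vem
from .deformation import warp_image
from .io import DeformationField, Image2D, LandmarkSet, RunConfig
from .synthesis import PredictionMaps

__all__ = [
    "JointSynthRegModel",
    "JointSynthRegResults",
    "MutualInfoRegistration",
    "MutualInfoResults",
]


class JointSynthRegModel:
    """Joint image-synthesis and deformable-registration model for one pair.

    Parameters
    ----------
    mri : Image2D
        The image to be warped (plays the MRI role).
    histology : Image2D
        The fixed image whose features drive the contrast synthesis.
    landmarks : LandmarkSet, optional
        Manually placed corresponding points (mm).
    config : RunConfig, optional
        Model and algorithm parameters; defaults to the reference settings.

    Examples
    --------
    >>> model = JointSynthRegModel(mri, histology, landmarks)
    >>> res = model.fit(seed=0)
    >>> print(res.summary())
    """

    def __init__(
        self,
        mri: Image2D,
        histology: Image2D,
        landmarks: Optional[LandmarkSet] = None,
        config: Optional[RunConfig] = None,
    ):
        if mri.shape != histology.shape:
            raise ValueError("the pair must be defined on a shared domain")
        self.mri = mri
        self.histology = histology
        self.landmarks = (
            landmarks.drop_outside(histology.shape, histology.spacing)
            if landmarks is not None
            else None
        )
        self.config = config or RunConfig()

    @classmethod
    def from_arrays(
        cls, mri: np.ndarray, histology: np.ndarray, spacing: float = 1.0, **kw
    ) -> "JointSynthRegModel":
        return cls(Image2D(mri, spacing), Image2D(histology, spacing), **kw)

    @classmethod
    def from_files(cls, mri_path, histology_path, spacing: float = 1.0, landmarks_path=None, **kw):
        from .io import read_image, read_landmarks

        lm = read_landmarks(landmarks_path) if landmarks_path else None
        return cls(
            read_image(mri_path, spacing), read_image(histology_path, spacing), landmarks=lm, **kw
        )

    def fit(
        self,
        seed=None,
        refine: bool = True,
        graphcut_cycles: int = 2,
    ) -> "JointSynthRegResults":
        """Run VEM, the graph-cut registration and (optionally) B-spline
        refinement; returns the results object."""
        cfg = self.config
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        state = vem.run([self.mri], [self.histology], [self.landmarks], config=cfg, rng=rng)
        maps = state.maps[0]
        energy = registration.build_energy(self.mri, maps, self.landmarks, state.labels, cfg)
        init = np.argmax(state.beliefs[0], axis=-1)
        gc_field, _, gc_energy = registration.minimize_graphcut(
            energy, init=init, max_cycles=graphcut_cycles, spacing=self.mri.spacing
        )
        bspline_info = None
        final = gc_field
        if refine:
            final, bspline_info = registration.refine_bspline(
                self.mri, maps, self.landmarks, gc_field, cfg, cp_spacing=cfg.cp_spacing
            )
        return JointSynthRegResults(self, state, maps, gc_field, gc_energy, final, bspline_info)


class JointSynthRegResults:
    """Estimates, uncertainties and diagnostics of a fitted joint model."""

    def __init__(self, model, vem_state, maps, graphcut_field, graphcut_energy, field, bspline_info):
        self.model = model
        self.vem_state = vem_state
        self.prediction = maps
        self.graphcut_field = graphcut_field
        self.graphcut_energy = graphcut_energy
        self.deformation = field
        self.bspline_info = bspline_info

    # -- uncertainty summaries -------------------------------------------
    @property
    def prediction_mean(self) -> np.ndarray:
        """Synthesised MRI contrast (per-pixel predictive mean)."""
        return self.prediction.mu

    @property
    def prediction_variance(self) -> np.ndarray:
        """Per-pixel predictive variance (high in artefacts/ambiguous areas)."""
        return self.prediction.var

    def expected_displacement(self) -> DeformationField:
        return registration.expected_displacement(
            self.vem_state.beliefs[0], self.vem_state.labels, self.model.mri.spacing
        )

    def belief_entropy(self) -> np.ndarray:
        return registration.entropy_map(self.vem_state.beliefs[0])

    def warped_mri(self) -> Image2D:
        """The MRI resampled into histology space by the final field."""
        return warp_image(self.model.mri, self.deformation)

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        s = self.vem_state
        mag = self.deformation.magnitude()
        lines = [
            "Joint synthesis-registration results",
            "=" * 38,
            f"image domain          : {self.model.mri.shape} px @ {self.model.mri.spacing:g} mm",
            f"displacement labels   : {s.labels.n_labels} "
            f"(radius {s.labels.radius:g} mm, step {s.labels.step:g} mm)",
            f"landmarks             : {0 if self.model.landmarks is None else len(self.model.landmarks)}",
            f"VEM outer iterations  : {s.iteration} (converged: {s.converged})",
            f"final map change      : {s.history[-1]['rel_change_mu']:.4g}" if s.history else "",
            f"graph-cut energy      : {self.graphcut_energy:.6g}",
            f"mean |U| (mm)         : {float(mag.mean()):.3f}",
            f"max |U| (mm)          : {float(mag.max()):.3f}",
            f"mean belief entropy   : {float(self.belief_entropy().mean()):.3f} nats",
            f"mean predictive sigma : {float(np.sqrt(self.prediction.var).mean()):.3f}",
        ]
        if self.bspline_info is not None:
            lines.append(
                f"B-spline refinement   : obj {self.bspline_info['objective']:.6g} "
                f"in {self.bspline_info['n_iter']} iterations"
            )
        return "\n".join(line for line in lines if line)

    def plot_uncertainty(self, axes=None):
        """Panel plot: synthesised mean, predictive variance, belief entropy,
        expected-displacement magnitude."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 4, figsize=(16, 4))
        panels = [
            (self.prediction_mean, "synthesised mean"),
            (self.prediction_variance, "predictive variance"),
            (self.belief_entropy(), "belief entropy"),
            (self.expected_displacement().magnitude(), "E[displacement] (mm)"),
        ]
        for ax, (img, title) in zip(np.ravel(axes), panels):
            im = ax.imshow(img)
            ax.set_title(title)
            ax.axis("off")
            plt.colorbar(im, ax=ax, fraction=0.046)
        return axes


class MutualInfoRegistration:
    """Mutual-information B-spline registration baseline (same landmarks,
    same regularisers, 64-bin hard joint histogram)."""

    def __init__(
        self,
        mri: Image2D,
        histology: Image2D,
        landmarks: Optional[LandmarkSet] = None,
        config: Optional[RunConfig] = None,
    ):
        if mri.shape != histology.shape:
            raise ValueError("the pair must be defined on a shared domain")
        self.mri = mri
        self.histology = histology
        self.landmarks = landmarks
        self.config = config or RunConfig()

    def fit(self, cp_spacing: Optional[float] = None, maxfev: Optional[int] = None):
        field, info = registration.register_mi(
            self.mri,
            self.histology,
            self.landmarks,
            self.config,
            cp_spacing=cp_spacing or self.config.cp_spacing_mi,
            maxfev=maxfev,
        )
        return MutualInfoResults(self, field, info)


class MutualInfoResults:
    def __init__(self, model, field, info):
        self.model = model
        self.deformation = field
        self.info = info

    def warped_mri(self) -> Image2D:
        return warp_image(self.model.mri, self.deformation)

    def summary(self) -> str:
        mag = self.deformation.magnitude()
        return "\n".join(
            [
                "Mutual-information registration results",
                "=" * 40,
                f"image domain   : {self.model.mri.shape} px @ {self.model.mri.spacing:g} mm",
                f"final objective: {self.info['objective']:.6g}",
                f"evaluations    : {self.info['n_fev']}",
                f"mean |U| (mm)  : {float(mag.mean()):.3f}",
                f"max |U| (mm)   : {float(mag.max()):.3f}",
            ]
        )
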