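"""End-to-end registration pipelines on a synthetic or user-supplied pair.

Both pipelines start with a coarse 2D linear (similarity) mutual-information
alignment — the joint model assumes its inputs are coarsely linearly
pre-aligned, and the synthetic generator deliberately leaves a residual
similarity misalignment in its pairs.  The nonlinear stage then runs on the
linearly aligned image and the estimated fields are composed, so the
returned displacement maps the original moving image into fixed space.

``register_pair_proposed``: linear pre-alignment, then variational EM for
the synthesis, discrete graph-cut registration and continuous B-spline
refinement.  ``register_pair_mi``: linear pre-alignment, then the
mutual-information B-spline baseline.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import registration, vem
from .deformation import compose_displacements, warp_array
from .io import DeformationField, Image2D, LandmarkSet, RunConfig
from .synthetic import SyntheticPair

__all__ = ["register_pair_proposed", "register_pair_mi", "apply_linear_prealignment"]


def apply_linear_prealignment(pair: SyntheticPair, config: RunConfig):
    """MI similarity pre-alignment of the moving image; returns
    ``(moving_aligned, linear_field, shifted_landmarks)``.

    Landmark MRI-side points are mapped through the inverse of the linear
    map so they refer to the aligned moving image.
    """
    params, lin = registration.prealign_similarity(pair.moving, pair.fixed, config)
    warped, invalid = warp_array(pair.moving.pixels, lin.u, pair.moving.spacing)
    moving_aligned = Image2D(warped, pair.moving.spacing, mask=~invalid)
    landmarks = pair.landmarks
    if landmarks is not None and len(landmarks) > 0:
        from .deformation import similarity_displacement

        h, w = pair.moving.shape
        inv = similarity_displacement(
            (h, w), pair.moving.spacing, params[0], params[1], params[2:], inverse=True
        )
        lin_inv = DeformationField(inv, pair.moving.spacing)
        landmarks = LandmarkSet(
            landmarks.mri + lin_inv.sample(landmarks.mri),
            landmarks.hist,
            sigma_k=landmarks.sigma_k,
        )
    return moving_aligned, lin, landmarks


def _compose_with_linear(nonlinear: DeformationField, linear: DeformationField):
    """Total displacement of x -> linear(x + nonlinear(x))."""
    return DeformationField(
        compose_displacements(linear.u, nonlinear.u, linear.spacing), linear.spacing
    )


def register_pair_proposed(
    pair: SyntheticPair,
    config: Optional[RunConfig] = None,
    seed=None,
    landmarks: Optional[LandmarkSet] = None,
    use_pair_landmarks: bool = True,
    refine: bool = True,
    graphcut_cycles: int = 2,
    prealign: bool = True,
) -> tuple:
    """Linear pre-alignment -> VEM -> graph cut -> B-spline refinement."""
    config = config or RunConfig()
    if seed is None:
        seed = config.seed
    if landmarks is None and use_pair_landmarks:
        landmarks = pair.landmarks
    H = pair.fixed
    if prealign:
        work = pair if landmarks is pair.landmarks else SyntheticPair(
            pair.fixed, pair.moving, pair.warp_field, pair.truth_field, landmarks
        )
        M, lin_field, landmarks = apply_linear_prealignment(work, config)
    else:
        M, lin_field = pair.moving, None
    rng = np.random.default_rng(seed)
    state = vem.run([M], [H], [landmarks], config=config, rng=rng)
    maps = state.maps[0]
    energy = registration.build_energy(M, maps, landmarks, state.labels, config)
    init = np.argmax(state.beliefs[0], axis=-1)
    field, labels_idx, e_final = registration.minimize_graphcut(
        energy, init=init, max_cycles=graphcut_cycles, spacing=M.spacing
    )
    details = {
        "vem": state,
        "linear_field": lin_field,
        "graphcut_field": field,
        "graphcut_energy": e_final,
        "labels_idx": labels_idx,
    }
    if refine:
        field, info = registration.refine_bspline(
            M, maps, landmarks, field, config, cp_spacing=config.cp_spacing
        )
        details["bspline"] = info
    if lin_field is not None:
        field = _compose_with_linear(field, lin_field)
    return field, details


def register_pair_mi(
    pair: SyntheticPair,
    config: Optional[RunConfig] = None,
    landmarks: Optional[LandmarkSet] = None,
    use_pair_landmarks: bool = True,
    cp_spacing: Optional[float] = None,
    maxfev: Optional[int] = None,
    prealign: bool = True,
) -> tuple:
    """Linear pre-alignment -> mutual-information B-spline baseline."""
    config = config or RunConfig()
    if landmarks is None and use_pair_landmarks:
        landmarks = pair.landmarks
    H = pair.fixed
    if prealign:
        work = pair if landmarks is pair.landmarks else SyntheticPair(
            pair.fixed, pair.moving, pair.warp_field, pair.truth_field, landmarks
        )
        M, lin_field, landmarks = apply_linear_prealignment(work, config)
    else:
        M, lin_field = pair.moving, None
    field, info = registration.register_mi(
        M, H, landmarks, config,
        cp_spacing=cp_spacing or config.cp_spacing_mi, maxfev=maxfev,
    )
    if lin_field is not None:
        field = _compose_with_linear(field, lin_field)
    return field, info
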