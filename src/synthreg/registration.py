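"""Final deformation estimation.

Three routes are provided once the synthesis has been fitted:

* ``minimize_graphcut`` — alpha-expansion minimisation of the discrete MRF
  energy (weighted SSD between the warped MRI and the synthesised prediction,
  with the synthesis variance as inverse weight, plus the landmark quadratic
  and the unary/pairwise regularisers).
* ``refine_bspline`` — continuous refinement with a cubic B-spline transform,
  optimising the alpha-scaled weighted SSD + landmark term + bending /
  linear-elastic / (optional) Jacobian regularisers by L-BFGS with analytic
  gradients.
* ``register_mi`` — the mutual-information baseline over the same B-spline
  model (hard-binned joint histogram; derivative-free optimisation, since
  hard binning makes MI piecewise constant in the coefficients).

The binary subproblems of alpha-expansion are solved by max-flow
(scipy.sparse.csgraph.maximum_flow) on integer-scaled capacities;
non-submodular pairwise terms (squared Euclidean label distance is not a
metric) are truncated, and a move is accepted only if it strictly lowers the
exact (float) energy, so the reported energy is always attained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import minimize
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .deformation import DisplacementLabelSet
from .io import DeformationField, Image2D, LandmarkSet, RunConfig
from .synthesis import PredictionMaps
from .vem import landmark_log_factors, shifted_intensities

logger = logging.getLogger("synthreg")

__all__ = [
    "DiscreteEnergy",
    "BSplineTransform",
    "build_energy",
    "total_energy",
    "minimize_graphcut",
    "refine_bspline",
    "register_mi",
    "mutual_information",
    "expected_displacement",
    "entropy_map",
    "weighted_ssd_data_term",
]


# ---------------------------------------------------------------------------
# Discrete energy and alpha-expansion
# ---------------------------------------------------------------------------


@dataclass
class DiscreteEnergy:
    """Pixel-labelled MRF energy over a displacement label set.

    ``unary[i, j, s]`` is the cost of assigning label s at pixel (i, j);
    the pairwise cost of a 4-neighbour edge with labels (s, s') is
    ``beta2 * ||Delta_s - Delta_s'||^2`` (each unordered edge once).
    """

    unary: np.ndarray
    labels: DisplacementLabelSet
    beta2: float

    @property
    def shape(self) -> tuple:
        return self.unary.shape[:2]


def build_energy(
    M: Image2D,
    maps: PredictionMaps,
    landmarks: Optional[LandmarkSet],
    labels: DisplacementLabelSet,
    config: Optional[RunConfig] = None,
) -> DiscreteEnergy:
    """Term-by-term construction of the discrete registration cost.

    unary = [M(x+Delta_s) - mu_x]^2 / (2 sigma_x^2) + beta1 ||Delta_s||^2
            + ||k^h - k + Delta_s||^2 / (2 sigma_k^2) at landmark pixels.

    Out-of-bounds image samples get the pixel's mean in-bounds image cost
    (neutral), so border pixels are decided by the regularisers.
    """
    config = config or RunConfig()
    vals, valid = shifted_intensities(M, labels)
    image_cost = (vals - maps.mu[..., None]) ** 2 / (2.0 * maps.var[..., None])
    n_valid = valid.sum(axis=-1)
    mean_cost = np.where(
        n_valid > 0,
        np.where(valid, image_cost, 0.0).sum(axis=-1) / np.maximum(n_valid, 1),
        0.0,
    )
    image_cost = np.where(valid, image_cost, mean_cost[..., None])
    unary = image_cost + config.beta1 * labels.squared_norms()[None, None, :]
    for i, j, vec in landmark_log_factors(
        landmarks, M.shape, M.spacing, labels, config.sigma_k
    ):
        unary[i, j] -= vec  # vec is a log factor; cost = -log
    return DiscreteEnergy(unary, labels, config.beta2)


def total_energy(energy: DiscreteEnergy, label_field: np.ndarray) -> float:
    """Exact energy of a label assignment (unary + pairwise)."""
    h, w = energy.shape
    idx = label_field.reshape(h, w)
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    e = float(energy.unary[ii, jj, idx].sum())
    if energy.beta2 > 0:
        V = energy.labels.pairwise_sq_dist()
        e += energy.beta2 * float(V[idx[1:], idx[:-1]].sum() + V[idx[:, 1:], idx[:, :-1]].sum())
    return e


def _solve_binary_cut(t_source, t_sink, edges_pq, cap_pq, n_nodes):
    """Min-cut of the binary expansion subproblem.

    ``t_source[p]`` is the cost of x_p = 1 (cut when p is on the sink side),
    ``t_sink[p]`` of x_p = 0; ``cap_pq`` the coefficient on (1 - x_p) x_q.
    Returns the boolean move vector x (True = take the new label).
    """
    SCALE_LIMIT = 1_000_000_000.0
    finite_max = max(
        float(t_source.max(initial=0.0)),
        float(t_sink.max(initial=0.0)),
        float(cap_pq.max(initial=0.0)) if cap_pq.size else 0.0,
        1e-12,
    )
    scale = min(1e7, SCALE_LIMIT / finite_max)
    src, snk = n_nodes, n_nodes + 1
    rows = np.concatenate([np.full(n_nodes, src), np.arange(n_nodes), edges_pq[:, 0]])
    cols = np.concatenate([np.arange(n_nodes), np.full(n_nodes, snk), edges_pq[:, 1]])
    caps = np.concatenate([t_source, t_sink, cap_pq])
    caps_int = np.round(caps * scale).astype(np.int64)
    keep = caps_int > 0
    graph = csr_matrix(
        (caps_int[keep].astype(np.int32), (rows[keep], cols[keep])),
        shape=(n_nodes + 2, n_nodes + 2),
    )
    res = maximum_flow(graph, src, snk)
    # residual capacities; flow pushed along (u, v) opens the reverse arc
    # (v, u), which appears as a positive entry of graph - flow
    residual = graph - res.flow
    reach = breadth_first_order(residual > 0, src, directed=True, return_predecessors=False)
    x = np.ones(n_nodes, dtype=bool)
    reach = reach[(reach >= 0) & (reach < n_nodes)]
    x[reach] = False  # reachable from source => keep current label
    return x


def _swap_cycle(f, unary, V, beta2, edges, n, best, energy):
    """One alpha-beta swap cycle (exact submodular subproblems).

    Swap moves complement expansions on strongly coupled energies; the cost
    grows with S^2, so they are only used for small label sets.
    """
    S = V.shape[0]
    improved = False
    # pairwise cost to non-participating neighbours folded into the unary
    for a in range(S):
        for b in range(a + 1, S):
            part = (f == a) | (f == b)
            if not part.any():
                continue
            idx_map = -np.ones(n, dtype=np.int64)
            pidx = np.flatnonzero(part)
            idx_map[pidx] = np.arange(pidx.size)
            d_a = unary[pidx, a].copy()
            d_b = unary[pidx, b].copy()
            ep = edges[part[edges[:, 0]] | part[edges[:, 1]]]
            both = part[ep[:, 0]] & part[ep[:, 1]]
            for col in (0, 1):
                half = ep[~both & part[ep[:, col]]]
                if half.size:
                    fo = f[half[:, 1 - col]]
                    np.add.at(d_a, idx_map[half[:, col]], beta2 * V[a, fo])
                    np.add.at(d_b, idx_map[half[:, col]], beta2 * V[b, fo])
            eb = ep[both]
            sub_edges = np.stack([idx_map[eb[:, 0]], idx_map[eb[:, 1]]], axis=1)
            # x=0 -> a, x=1 -> b; with v = beta2 V(a,b):
            # E(0,1) = E(1,0) = v, E(0,0) = E(1,1) = 0, which decomposes as
            # v x_p - v x_q + 2v (1-x_p) x_q  (always submodular)
            vab = beta2 * V[a, b]
            t_source = d_b.copy()
            t_sink = d_a.copy()
            if eb.size:
                np.add.at(t_source, sub_edges[:, 0], vab)
                np.add.at(t_sink, sub_edges[:, 1], vab)
            x = _solve_binary_cut(
                t_source, t_sink, sub_edges, np.full(eb.shape[0], 2.0 * vab), pidx.size
            )
            cand = f.copy()
            cand[pidx] = np.where(x, b, a)
            e_cand = total_energy(energy, cand)
            if e_cand < best - 1e-12:
                f = cand
                best = e_cand
                improved = True
    return f, best, improved


def minimize_graphcut(
    energy: DiscreteEnergy,
    init: Optional[np.ndarray] = None,
    max_cycles: int = 10,
    spacing: float = 1.0,
    swap_moves: Optional[bool] = None,
) -> tuple:
    """Alpha-expansion over all labels until no move lowers the energy.

    Returns ``(field, label_indices, final_energy)``; the displacement field
    maps the winning label of each pixel to mm.  Labels are visited in fixed
    order; a candidate move is accepted only on strict decrease of the exact
    energy (guarding against the truncation of non-submodular terms).  For
    small label sets (or ``swap_moves=True``) stalled expansion cycles are
    followed by exact alpha-beta swap cycles.
    """
    h, w = energy.shape
    S = energy.labels.n_labels
    n = h * w
    unary = energy.unary.reshape(n, S)
    if init is None:
        f = np.full(n, energy.labels.zero_index, dtype=np.int64)
    else:
        f = np.asarray(init, dtype=np.int64).reshape(n).copy()
    V = energy.labels.pairwise_sq_dist() * energy.beta2
    # 4-neighbour edge list (each unordered edge once)
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    flat = (ii * w + jj)
    edges = np.concatenate(
        [
            np.stack([flat[:-1].ravel(), flat[1:].ravel()], axis=1),
            np.stack([flat[:, :-1].ravel(), flat[:, 1:].ravel()], axis=1),
        ]
    )
    best = total_energy(energy, f)
    if swap_moves is None:
        swap_moves = S <= 81 and energy.beta2 > 0
    order = np.arange(S)
    for _ in range(max_cycles):
        improved = False
        for alpha in order:
            d_keep = unary[np.arange(n), f]
            d_move = unary[:, alpha]
            if energy.beta2 > 0:
                fa, fb = f[edges[:, 0]], f[edges[:, 1]]
                A0 = V[fa, fb]
                B0 = V[fa, alpha]
                C0 = V[alpha, fb]
                candidates = []
                # squared label distance is a semi-metric, so the binary
                # subproblem can be non-submodular (B + C < A).  Two
                # truncated surrogates are tried: an optimistic one that
                # lowers the keep-keep cost A (can overshoot; accepted only
                # on strict true-energy decrease) and a conservative one
                # that raises the mixed costs B and C (upper-bounds the move
                # energy, so its cut never raises the true energy).
                excess = np.maximum(A0 - (B0 + C0), 0.0)
                if np.any(excess > 0):
                    variants = (
                        (np.minimum(A0, B0 + C0), B0, C0),
                        (A0, B0 + 0.5 * excess, C0 + 0.5 * excess),
                    )
                else:
                    variants = ((A0, B0, C0),)
                for A, B, C in variants:
                    # E = A + (C-A) x_p + (D-C) x_q
                    #       + (B+C-A-D)(1-x_p) x_q,  with D = 0
                    coef_p = C - A
                    coef_q = -C
                    pair_cap = B + C - A
                    t_source = d_move.copy()
                    t_sink = d_keep.copy()
                    np.add.at(t_source, edges[:, 0], np.maximum(coef_p, 0.0))
                    np.add.at(t_sink, edges[:, 0], np.maximum(-coef_p, 0.0))
                    np.add.at(t_source, edges[:, 1], np.maximum(coef_q, 0.0))
                    np.add.at(t_sink, edges[:, 1], np.maximum(-coef_q, 0.0))
                    x = _solve_binary_cut(t_source, t_sink, edges, pair_cap, n)
                    cand = np.where(x, alpha, f)
                    e_cand = total_energy(energy, cand)
                    candidates.append((e_cand, cand))
                    if e_cand < best - 1e-12:
                        break
                e_cand, cand = min(candidates, key=lambda t: t[0])
            else:
                x = d_move < d_keep
                cand = np.where(x, alpha, f)
                e_cand = total_energy(energy, cand)
            if e_cand < best - 1e-12:
                f = cand
                best = e_cand
                improved = True
        if not improved and swap_moves and energy.beta2 > 0:
            f, best, improved = _swap_cycle(
                f, unary, energy.labels.pairwise_sq_dist(), energy.beta2, edges, n, best, energy
            )
        if not improved:
            break
    field = DeformationField(energy.labels.deltas[f].reshape(h, w, 2), spacing=spacing)
    return field, f.reshape(h, w), best


# ---------------------------------------------------------------------------
# Cubic B-spline transform and continuous refinement
# ---------------------------------------------------------------------------


def _bspline_weights(t: np.ndarray) -> np.ndarray:
    """Cubic B-spline basis values for fractional offsets t in [0, 1).

    Returns the 4 weights (for control points floor-1 .. floor+2).
    """
    t2, t3 = t * t, t ** 3
    return np.stack(
        [
            (1 - t) ** 3 / 6.0,
            (3 * t3 - 6 * t2 + 4) / 6.0,
            (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0,
            t3 / 6.0,
        ],
        axis=-1,
    )


@dataclass
class BSplineTransform:
    """Free-form deformation on a cubic B-spline control grid.

    The displacement at x is a weighted sum of control coefficients:
    u(x) = sum_k c_k B((x - x_k)/spacing).  ``basis`` holds the dense-grid
    evaluation matrix (|Omega| x n_ctrl), built once per image geometry.
    """

    shape: tuple
    spacing: float
    cp_spacing: float
    basis: csr_matrix
    grid_shape: tuple

    @classmethod
    def create(cls, shape: tuple, spacing: float, cp_spacing: float) -> "BSplineTransform":
        if cp_spacing <= 0:
            raise ValueError("control-point spacing must be > 0")
        h, w = shape
        ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        pts = np.stack([jj.ravel() * spacing, ii.ravel() * spacing], axis=-1)
        basis, grid_shape = cls._basis_for_points(pts, shape, spacing, cp_spacing)
        return cls(shape, spacing, cp_spacing, basis, grid_shape)

    @staticmethod
    def _grid_shape(shape, spacing, cp_spacing):
        h, w = shape
        nx = int(np.floor((w - 1) * spacing / cp_spacing)) + 4
        ny = int(np.floor((h - 1) * spacing / cp_spacing)) + 4
        return ny, nx

    @classmethod
    def _basis_for_points(cls, pts_mm, shape, spacing, cp_spacing):
        ny, nx = cls._grid_shape(shape, spacing, cp_spacing)
        # control point k sits at (k - 1) * cp_spacing, so index 1 is at 0
        gx = pts_mm[:, 0] / cp_spacing
        gy = pts_mm[:, 1] / cp_spacing
        ix = np.floor(gx).astype(int)
        iy = np.floor(gy).astype(int)
        wx = _bspline_weights(gx - ix)  # (n, 4)
        wy = _bspline_weights(gy - iy)
        n = pts_mm.shape[0]
        rows = np.repeat(np.arange(n), 16)
        cols = np.empty((n, 16), dtype=int)
        vals = np.empty((n, 16))
        for a in range(4):  # y offsets
            for b in range(4):  # x offsets
                cy = np.clip(iy + a, 0, ny - 1)
                cx = np.clip(ix + b, 0, nx - 1)
                cols[:, a * 4 + b] = cy * nx + cx
                vals[:, a * 4 + b] = wy[:, a] * wx[:, b]
        basis = csr_matrix(
            (vals.ravel(), (rows, cols.ravel())), shape=(n, ny * nx)
        )
        return basis, (ny, nx)

    @property
    def n_ctrl(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def displacement(self, coeffs: np.ndarray) -> np.ndarray:
        """Dense displacement field (H, W, 2) in mm from coefficients (n_ctrl, 2)."""
        u = self.basis @ coeffs
        return u.reshape(*self.shape, 2)

    def fit_coefficients(self, field: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
        """Least-squares projection of a dense field onto the spline space."""
        from scipy.sparse.linalg import lsqr

        out = np.zeros((self.n_ctrl, 2))
        for c in range(2):
            out[:, c] = lsqr(self.basis, field[..., c].ravel(), damp=ridge)[0]
        return out


def _fd_second_derivs(u: np.ndarray, spacing: float):
    """(u_xx, u_xy, u_yy) by centred differences, zero-padded domain."""
    uxx = np.zeros_like(u)
    uyy = np.zeros_like(u)
    uxy = np.zeros_like(u)
    uxx[:, 1:-1] = (u[:, 2:] - 2 * u[:, 1:-1] + u[:, :-2]) / spacing ** 2
    uyy[1:-1, :] = (u[2:, :] - 2 * u[1:-1, :] + u[:-2, :]) / spacing ** 2
    uxy[1:-1, 1:-1] = (u[2:, 2:] - u[2:, :-2] - u[:-2, 2:] + u[:-2, :-2]) / (4 * spacing ** 2)
    return uxx, uxy, uyy


def _fd_second_adjoint(gxx, gxy, gyy, spacing):
    """Adjoint of _fd_second_derivs (for gradient backpropagation)."""
    out = np.zeros_like(gxx)
    t = gxx[:, 1:-1] / spacing ** 2
    out[:, 2:] += t
    out[:, 1:-1] -= 2 * t
    out[:, :-2] += t
    t = gyy[1:-1, :] / spacing ** 2
    out[2:, :] += t
    out[1:-1, :] -= 2 * t
    out[:-2, :] += t
    t = gxy[1:-1, 1:-1] / (4 * spacing ** 2)
    out[2:, 2:] += t
    out[2:, :-2] -= t
    out[:-2, 2:] -= t
    out[:-2, :-2] += t
    return out


def _fd_first_derivs(u: np.ndarray, spacing: float):
    """(u_x, u_y) by centred differences with one-sided edges (np.gradient)."""
    uy, ux = np.gradient(u, spacing)
    return ux, uy


def _fd_first_adjoint_x(g, spacing):
    out = np.zeros_like(g)
    # interior: centred differences
    out[:, 2:] += g[:, 1:-1] / (2 * spacing)
    out[:, :-2] -= g[:, 1:-1] / (2 * spacing)
    # edges: one-sided
    out[:, 0] -= g[:, 0] / spacing
    out[:, 1] += g[:, 0] / spacing
    out[:, -1] += g[:, -1] / spacing
    out[:, -2] -= g[:, -1] / spacing
    return out


def _fd_first_adjoint_y(g, spacing):
    return _fd_first_adjoint_x(g.T, spacing).T


def bending_energy(u: np.ndarray, spacing: float, with_grad: bool = True):
    """Mean squared second derivatives of the displacement (per-pixel
    average, matching the normalised-penalty convention of control-point
    registration packages); zero for any globally affine transform.
    """
    n = u.shape[0] * u.shape[1]
    e = 0.0
    grad = np.zeros_like(u) if with_grad else None
    for c in range(2):
        uxx, uxy, uyy = _fd_second_derivs(u[..., c], spacing)
        e += float((uxx ** 2 + 2 * uxy ** 2 + uyy ** 2).sum()) / n
        if with_grad:
            grad[..., c] = 2 * _fd_second_adjoint(uxx, 2 * uxy, uyy, spacing) / n
    return e, grad


def linear_elastic_energy(u: np.ndarray, spacing: float, with_grad: bool = True):
    """Squared Frobenius norm of the symmetric displacement-gradient part.

    The Jacobian of the transform is J = I + grad u; subtracting rotation and
    the identity leaves sym(grad u), so E_l = sum ||sym(grad u)||_F^2
    (penalises stretch and shear, not rigid motion).
    """
    u1x, u1y = _fd_first_derivs(u[..., 0], spacing)
    u2x, u2y = _fd_first_derivs(u[..., 1], spacing)
    n = u.shape[0] * u.shape[1]
    sxy = 0.5 * (u1y + u2x)
    e = float((u1x ** 2 + u2y ** 2 + 2 * sxy ** 2).sum()) / n
    if not with_grad:
        return e, None
    grad = np.zeros_like(u)
    grad[..., 0] = (2 * _fd_first_adjoint_x(u1x, spacing) + 2 * _fd_first_adjoint_y(sxy, spacing)) / n
    grad[..., 1] = (2 * _fd_first_adjoint_y(u2y, spacing) + 2 * _fd_first_adjoint_x(sxy, spacing)) / n
    return e, grad


def jacobian_energy(u: np.ndarray, spacing: float):
    """Sum of squared log-determinants of the transform Jacobian.

    Off by default (Table-1 weight 0); determinants clipped away from zero
    for numerical safety.
    """
    u1x, u1y = _fd_first_derivs(u[..., 0], spacing)
    u2x, u2y = _fd_first_derivs(u[..., 1], spacing)
    det = (1 + u1x) * (1 + u2y) - u1y * u2x
    n = u.shape[0] * u.shape[1]
    det_c = np.clip(det, 1e-6, None)
    logd = np.log(det_c)
    e = float((logd ** 2).sum()) / n
    w = 2 * logd / det_c * (det > 1e-6) / n
    grad = np.zeros_like(u)
    grad[..., 0] = _fd_first_adjoint_x(w * (1 + u2y), spacing) + _fd_first_adjoint_y(-w * u2x, spacing)
    grad[..., 1] = _fd_first_adjoint_y(w * (1 + u1x), spacing) + _fd_first_adjoint_x(-w * u1y, spacing)
    return e, grad


def weighted_ssd_data_term(
    warped: np.ndarray,
    maps: PredictionMaps,
    valid: Optional[np.ndarray] = None,
    alpha: Optional[float] = None,
) -> float:
    """The alpha-scaled image term: alpha * sum (M(V(x)) - mu)^2 / (2 sigma^2).

    With the default alpha^-1 = 9 |Omega| / 2 the term equals 1 when every
    pixel's residual is exactly three predicted standard deviations.
    """
    n_pix = maps.mu.size
    if alpha is None:
        alpha = 2.0 / (9.0 * n_pix)
    r2 = (warped - maps.mu) ** 2 / (2.0 * maps.var)
    if valid is not None:
        r2 = np.where(valid, r2, 0.0)
    return float(alpha * r2.sum())


class _BSplineObjective:
    """Weighted-SSD B-spline objective with analytic gradient.

    Penalty weights follow the control-grid normalisation convention of
    control-point registration packages: the bending and linear-elastic
    energies are evaluated per control-grid unit, which multiplies the
    per-mm energies by (cp_spacing / spacing)^4 and (cp_spacing / spacing)^2
    respectively, so the default weights act at comparable strength across
    grid resolutions.
    """

    def __init__(self, M, maps, landmarks, transform, config):
        from scipy.interpolate import RectBivariateSpline

        self.maps = maps
        self.transform = transform
        self.config = config
        self.spacing = M.spacing
        h, w = M.shape
        self.h, self.w = h, w
        y = np.arange(h) * M.spacing
        x = np.arange(w) * M.spacing
        self.spline = RectBivariateSpline(y, x, M.pixels, kx=3, ky=3)
        ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        self.base_x = (jj * M.spacing).ravel()
        self.base_y = (ii * M.spacing).ravel()
        self.alpha = 2.0 / (9.0 * h * w)
        self.xmax, self.ymax = (w - 1) * M.spacing, (h - 1) * M.spacing
        ratio = transform.cp_spacing / M.spacing
        self.w_bending = config.beta_bending * ratio ** 4
        self.w_linear = config.beta_linear * ratio ** 2
        self.w_jacobian = config.beta_jacobian
        self.landmarks = landmarks
        if landmarks is not None and len(landmarks) > 0:
            self.lm_basis, _ = BSplineTransform._basis_for_points(
                landmarks.hist, M.shape, M.spacing, transform.cp_spacing
            )
        else:
            self.lm_basis = None

    def __call__(self, psi: np.ndarray):
        tr = self.transform
        cfg = self.config
        coeffs = psi.reshape(tr.n_ctrl, 2)
        u = tr.basis @ coeffs  # (n, 2)
        px = self.base_x + u[:, 0]
        py = self.base_y + u[:, 1]
        inside = (px >= 0) & (px <= self.xmax) & (py >= 0) & (py <= self.ymax)
        pxc = np.clip(px, 0, self.xmax)
        pyc = np.clip(py, 0, self.ymax)
        vals = self.spline.ev(pyc, pxc)
        gx = self.spline.ev(pyc, pxc, dy=1)  # d/dx (2nd axis)
        gy = self.spline.ev(pyc, pxc, dx=1)
        r = (vals - self.maps.mu.ravel()) / self.maps.var.ravel()
        r2 = (vals - self.maps.mu.ravel()) ** 2 / (2.0 * self.maps.var.ravel())
        e = self.alpha * float(np.where(inside, r2, 0.0).sum())
        gw = self.alpha * np.where(inside, r, 0.0)
        grad_u = np.stack([gw * gx, gw * gy], axis=-1)  # (n, 2)

        u_img = u.reshape(self.h, self.w, 2)
        eb, gb = bending_energy(u_img, self.spacing)
        el, gl = linear_elastic_energy(u_img, self.spacing)
        e += self.w_bending * eb + self.w_linear * el
        grad_u += (self.w_bending * gb + self.w_linear * gl).reshape(-1, 2)
        if self.w_jacobian > 0:
            ej, gj = jacobian_energy(u_img, self.spacing)
            e += self.w_jacobian * ej
            grad_u += (self.w_jacobian * gj).reshape(-1, 2)

        grad_c = tr.basis.T @ grad_u  # (n_ctrl, 2)

        if self.lm_basis is not None:
            lm_u = self.lm_basis @ coeffs
            resid = self.landmarks.hist + lm_u - self.landmarks.mri
            sk2 = cfg.sigma_k ** 2
            e += float((resid ** 2).sum()) / (2.0 * sk2)
            grad_c += self.lm_basis.T @ (resid / sk2)
        if not np.isfinite(e):
            raise FloatingPointError("non-finite B-spline objective")
        return e, grad_c.ravel()


def refine_bspline(
    M: Image2D,
    maps: PredictionMaps,
    landmarks: Optional[LandmarkSet],
    init_field: Optional[DeformationField],
    config: Optional[RunConfig] = None,
    cp_spacing: Optional[float] = None,
    max_iter: int = 200,
) -> tuple:
    """Continuous B-spline refinement of the registration.

    Minimises the alpha-scaled weighted SSD + landmark + regulariser cost by
    L-BFGS with analytic gradients, starting from the projection of
    ``init_field`` onto the spline space (or from the identity).  Returns
    ``(field, info)`` with the dense displacement and an optimisation record.
    """
    config = config or RunConfig()
    if cp_spacing is None:
        cp_spacing = config.cp_spacing
    tr = BSplineTransform.create(M.shape, M.spacing, cp_spacing)
    if init_field is not None:
        psi0 = tr.fit_coefficients(init_field.u).ravel()
    else:
        psi0 = np.zeros(tr.n_ctrl * 2)
    obj = _BSplineObjective(M, maps, landmarks, tr, config)
    res = minimize(
        obj,
        psi0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-6, "gtol": 1e-8},
    )
    u = tr.displacement(res.x.reshape(tr.n_ctrl, 2))
    info = {
        "objective": float(res.fun),
        "n_iter": int(res.nit),
        "converged": bool(res.success),
        "message": str(res.message),
    }
    logger.info("B-spline refine: obj=%.6g after %d iterations", res.fun, res.nit)
    return DeformationField(u, spacing=M.spacing), info


# ---------------------------------------------------------------------------
# Mutual-information baseline
# ---------------------------------------------------------------------------


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 64, mask=None) -> float:
    """Hard-binned joint-histogram MI (nats); 0 for degenerate (constant) input.

    Intensities are min-max scaled to the bin range per image.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        a, b = a[m], b[m]
    if a.size == 0 or a.max() == a.min() or b.max() == b.min():
        return 0.0
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * (np.log(p[nz]) - np.log((px @ py)[nz]))).sum())


def register_mi(
    M: Image2D,
    H: Image2D,
    landmarks: Optional[LandmarkSet],
    config: Optional[RunConfig] = None,
    cp_spacing: Optional[float] = None,
    maxfev: Optional[int] = None,
) -> tuple:
    """Mutual-information baseline over the same B-spline deformation model.

    Minimises  -MI(M(V(x)), H(x)) + landmark term + bending/linear
    regularisers.  The joint histogram uses hard binning, which makes the
    objective piecewise constant in the coefficients, so the optimiser is
    Powell's derivative-free method rather than a gradient scheme.
    """
    config = config or RunConfig()
    if cp_spacing is None:
        cp_spacing = config.cp_spacing_mi
    tr = BSplineTransform.create(M.shape, M.spacing, cp_spacing)
    h, w = M.shape
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    base_r = ii.ravel().astype(np.float64)
    base_c = jj.ravel().astype(np.float64)
    if landmarks is not None and len(landmarks) > 0:
        lm_basis, _ = BSplineTransform._basis_for_points(
            landmarks.hist, M.shape, M.spacing, cp_spacing
        )
    else:
        lm_basis = None
    sk2 = config.sigma_k ** 2
    ratio = cp_spacing / M.spacing
    w_bending = config.beta_bending * ratio ** 4
    w_linear = config.beta_linear * ratio ** 2
    bins = config.mi_bins
    # fixed-image bins precomputed once; the moving image is min-max scaled
    # over its full range, so warped (interpolated) values stay in range
    hp = H.pixels.ravel()
    h_rng = hp.max() - hp.min()
    bin_h = (
        np.minimum(((hp - hp.min()) / max(h_rng, 1e-12) * bins).astype(np.int64), bins - 1)
        if h_rng > 0
        else np.zeros(hp.size, dtype=np.int64)
    )
    m_lo, m_hi = M.pixels.min(), M.pixels.max()
    m_scale = bins / max(m_hi - m_lo, 1e-12)

    def objective(psi):
        coeffs = psi.reshape(tr.n_ctrl, 2)
        u = tr.basis @ coeffs
        rows = base_r + u[:, 1] / M.spacing
        cols = base_c + u[:, 0] / M.spacing
        inside = (rows >= 0) & (rows <= h - 1) & (cols >= 0) & (cols <= w - 1)
        warped = map_coordinates(M.pixels, [rows, cols], order=1, mode="constant", cval=0.0)
        if m_hi == m_lo or h_rng == 0 or not inside.any():
            mi = 0.0
        else:
            bin_m = np.minimum(((warped - m_lo) * m_scale).astype(np.int64), bins - 1)
            joint = np.bincount(
                bin_m[inside] * bins + bin_h[inside], minlength=bins * bins
            ).reshape(bins, bins)
            p = joint / joint.sum()
            px = p.sum(axis=1)
            py = p.sum(axis=0)
            nz = p > 0
            outer = px[:, None] * py[None, :]
            mi = float((p[nz] * (np.log(p[nz]) - np.log(outer[nz]))).sum())
        e = -mi
        u_img = u.reshape(h, w, 2)
        e += w_bending * bending_energy(u_img, M.spacing, with_grad=False)[0]
        e += w_linear * linear_elastic_energy(u_img, M.spacing, with_grad=False)[0]
        if lm_basis is not None:
            resid = landmarks.hist + lm_basis @ coeffs - landmarks.mri
            e += float((resid ** 2).sum()) / (2.0 * sk2)
        return e

    n_par = tr.n_ctrl * 2
    if maxfev is None:
        maxfev = 60 * n_par
    res = minimize(
        objective,
        np.zeros(n_par),
        method="Powell",
        options={"maxfev": maxfev, "maxiter": 8, "xtol": 1e-3, "ftol": 1e-6},
    )
    u = tr.displacement(res.x.reshape(tr.n_ctrl, 2))
    info = {
        "objective": float(res.fun),
        "n_fev": int(res.nfev),
        "converged": bool(res.success),
    }
    logger.info("MI registration: obj=%.6g after %d evaluations", res.fun, res.nfev)
    return DeformationField(u, spacing=M.spacing), info


def prealign_similarity(
    M: Image2D,
    H: Image2D,
    config: Optional[RunConfig] = None,
    maxfev: int = 600,
) -> tuple:
    """Coarse 2D linear (similarity) alignment of M to H by mutual information.

    The joint model assumes its input pair is coarsely linearly pre-aligned;
    this provides that step when it has not been done upstream.  A
    4-parameter similarity (rotation, log-scale, translation about the image
    centre) is optimised by Powell's method on the hard-binned MI.

    Returns ``(params, field)`` with ``params = (rot_deg, scale_log, tx_px,
    ty_px)`` and the dense displacement of the fitted map.
    """
    from .deformation import similarity_displacement, warp_array

    config = config or RunConfig()
    h, w = M.shape

    def objective(p):
        rot, slog, tx, ty = p
        disp = similarity_displacement((h, w), M.spacing, rot, slog, (tx, ty))
        warped, invalid = warp_array(M.pixels, disp, M.spacing)
        return -mutual_information(warped, H.pixels, bins=config.mi_bins, mask=~invalid)

    # bounds express "coarse residual" misalignment; they keep the search
    # away from degenerate large-motion optima of the hard-binned MI
    bounds = [(-15.0, 15.0), (-0.3, 0.3), (-10.0, 10.0), (-10.0, 10.0)]
    res = minimize(
        objective,
        np.zeros(4),
        method="Powell",
        bounds=bounds,
        options={"maxfev": maxfev, "xtol": 1e-3},
    )
    params = tuple(float(v) for v in res.x)
    field = DeformationField(
        similarity_displacement((h, w), M.spacing, params[0], params[1], params[2:]),
        spacing=M.spacing,
    )
    logger.info("linear pre-alignment: rot %.2f deg, log-scale %.3f, t (%.2f, %.2f) px",
                *params)
    return params, field


# ---------------------------------------------------------------------------
# Belief summaries
# ---------------------------------------------------------------------------


def expected_displacement(beliefs: np.ndarray, labels: DisplacementLabelSet, spacing: float = 1.0) -> DeformationField:
    """Per-pixel posterior mean displacement E_q[Delta] as a field (mm)."""
    u = beliefs @ labels.deltas
    return DeformationField(u, spacing=spacing)


def entropy_map(beliefs: np.ndarray) -> np.ndarray:
    """Per-pixel Shannon entropy of q (nats); log S at uniform pixels."""
    q = np.maximum(beliefs, 1e-300)
    return -(q * np.log(q)).sum(axis=-1)
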