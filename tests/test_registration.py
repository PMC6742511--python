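import numpy as np
import pytest

from synthreg import registration as rg
from synthreg.deformation import make_label_set
from synthreg.io import DeformationField, Image2D, LandmarkSet, RunConfig
from synthreg.synthesis import PredictionMaps


def exact_minimum_energy(unary, V, beta2):
    """Exact global minimum of the grid MRF energy by frontier dynamic
    programming over scan order (transfer-matrix; independent of the
    graph-cut code path).  Feasible for width <= 4 and small label counts.

    The frontier state holds the labels of the last ``w`` assigned pixels as
    base-S digits, digit 0 being the most recent; the vertical neighbour of
    the next pixel is the oldest digit, which is dropped on transition.
    """
    h, w, S = unary.shape
    cur = np.zeros(1)  # empty frontier
    for k in range(h * w):
        i, j = divmod(k, w)
        n_states = cur.size
        cost = cur[:, None] + unary[i, j][None, :]  # (n_states, S)
        states = np.arange(n_states)
        if j > 0:
            d_left = states % S  # most recent pixel
            cost = cost + beta2 * V[d_left][:, :]
        if i > 0:
            d_top = states // (S ** (w - 1))  # pixel w back
            cost = cost + beta2 * V[d_top][:, :]
        if k < w:
            new_state = states[:, None] * S + np.arange(S)[None, :]
            n_new = n_states * S
        else:
            new_state = (states[:, None] % (S ** (w - 1))) * S + np.arange(S)[None, :]
            n_new = n_states
        nxt = np.full(n_new, np.inf)
        np.minimum.at(nxt, new_state.ravel(), cost.ravel())
        cur = nxt
    return float(cur.min())


class TestBuildEnergy:
    def _maps(self, shape, mu=100.0, var=25.0):
        return PredictionMaps(np.full(shape, mu), np.full(shape, var))

    def test_perfect_prediction_minimised_at_zero(self):
        M = Image2D(np.full((8, 8), 100.0))
        labels = make_label_set(2, 1)
        en = rg.build_energy(M, self._maps((8, 8)), None, labels, RunConfig())
        best = np.argmin(en.unary, axis=-1)
        assert np.all(best == labels.zero_index)

    def test_variance_doubling_halves_image_term(self, rng):
        M = Image2D(rng.random((8, 8)) * 255)
        labels = make_label_set(1, 1)
        cfg = RunConfig(beta1=0.0)
        maps1 = PredictionMaps(np.full((8, 8), 50.0), np.full((8, 8), 20.0))
        maps2 = PredictionMaps(np.full((8, 8), 50.0), np.full((8, 8), 40.0))
        e1 = rg.build_energy(M, maps1, None, labels, cfg)
        e2 = rg.build_energy(M, maps2, None, labels, cfg)
        np.testing.assert_allclose(e2.unary, e1.unary / 2.0)

    def test_tight_landmark_dominates_unary(self):
        M = Image2D(np.full((10, 10), 100.0))
        labels = make_label_set(3, 1)
        lm = LandmarkSet([[7.0, 5.0]], [[5.0, 5.0]], sigma_k=1e-3)
        cfg = RunConfig(sigma_k=1e-3)
        en = rg.build_energy(M, self._maps((10, 10)), lm, labels, cfg)
        best = labels.deltas[np.argmin(en.unary[5, 5])]
        np.testing.assert_allclose(best, [2.0, 0.0])  # label nearest k - k^h


class TestGraphCut:
    def test_identical_images_return_zero_field(self):
        M = Image2D(np.full((6, 6), 80.0))
        labels = make_label_set(1, 1)
        maps = PredictionMaps(np.full((6, 6), 80.0), np.full((6, 6), 10.0))
        en = rg.build_energy(M, maps, None, labels, RunConfig())
        field, idx, e = rg.minimize_graphcut(en)
        assert np.all(field.u == 0.0)

    def test_energy_never_below_exact_optimum(self, rng):
        labels = make_label_set(1, 1)
        V = labels.pairwise_sq_dist()
        for _ in range(5):
            unary = rng.random((3, 3, 9)) * 5
            en = rg.DiscreteEnergy(unary, labels, beta2=0.05)
            _, _, e = rg.minimize_graphcut(en)
            e0 = exact_minimum_energy(unary, V, 0.05)
            assert e >= e0 - 1e-9
            assert e <= e0 * 1.05 + 1e-9

    def test_returned_energy_matches_labelling(self, rng):
        labels = make_label_set(1, 1)
        unary = rng.random((4, 4, 9)) * 3
        en = rg.DiscreteEnergy(unary, labels, beta2=0.1)
        _, idx, e = rg.minimize_graphcut(en)
        assert e == pytest.approx(rg.total_energy(en, idx))

    def test_result_improves_on_init(self, rng):
        labels = make_label_set(1, 1)
        unary = rng.random((5, 5, 9)) * 3
        en = rg.DiscreteEnergy(unary, labels, beta2=0.1)
        init = np.full((5, 5), 3)
        e_init = rg.total_energy(en, init)
        _, _, e = rg.minimize_graphcut(en, init=init)
        assert e <= e_init


class TestVarianceDownweighting:
    def test_tenfold_variance_reduces_contribution_tenfold(self, rng):
        M = Image2D(rng.random((10, 10)) * 255)
        labels = make_label_set(1, 1)
        cfg = RunConfig(beta1=0.0)
        var = np.full((10, 10), 10.0)
        region = np.zeros((10, 10), dtype=bool)
        region[2:5, 2:5] = True
        var10 = np.where(region, var * 10, var)
        mu = np.full((10, 10), 100.0)
        e1 = rg.build_energy(M, PredictionMaps(mu, var), None, labels, cfg)
        e2 = rg.build_energy(M, PredictionMaps(mu, var10), None, labels, cfg)
        np.testing.assert_allclose(e2.unary[region], e1.unary[region] / 10.0)
        np.testing.assert_allclose(e2.unary[~region], e1.unary[~region])


class TestBSpline:
    def test_three_sigma_residual_data_term_is_one(self, rng):
        sig = rng.uniform(0.5, 20.0, (31, 27))
        maps = PredictionMaps(np.zeros((31, 27)), sig ** 2)
        val = rg.weighted_ssd_data_term(3.0 * sig, maps)
        assert val == pytest.approx(1.0, abs=1e-12)

    def test_bending_energy_zero_for_affine(self):
        ii, jj = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
        u = np.stack([0.3 * jj - 0.1 * ii + 2.0, 0.05 * jj + 0.2 * ii - 1.0], axis=-1)
        e, _ = rg.bending_energy(u, 1.0)
        assert e == pytest.approx(0.0, abs=1e-18)

    def test_objective_gradient_matches_finite_differences(self, rng):
        from synthreg.synthetic import PhantomSpec, make_phantom

        a, b = make_phantom(PhantomSpec(shape=(24, 24)), 3)
        maps = PredictionMaps(b.pixels.copy(), np.full((24, 24), 30.0))
        lm = LandmarkSet([[5.0, 5.0]], [[6.0, 5.0]], sigma_k=0.5)
        tr = rg.BSplineTransform.create((24, 24), 1.0, 8.0)
        obj = rg._BSplineObjective(Image2D(b.pixels), maps, lm, tr, RunConfig())
        psi = rng.normal(0, 0.3, tr.n_ctrl * 2)
        _, g = obj(psi)
        for i in rng.choice(psi.size, 6, replace=False):
            eps = 1e-5
            p1, p2 = psi.copy(), psi.copy()
            p1[i] += eps
            p2[i] -= eps
            fd = (obj(p1)[0] - obj(p2)[0]) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=2e-3, abs=1e-7)

    def test_descent_from_identity_on_aligned_pair(self, rng):
        from synthreg.synthetic import PhantomSpec, make_phantom

        a, b = make_phantom(PhantomSpec(shape=(32, 32)), 9)
        maps = PredictionMaps(b.pixels.copy(), np.full((32, 32), 30.0))
        tr = rg.BSplineTransform.create((32, 32), 1.0, 10.0)
        obj = rg._BSplineObjective(Image2D(b.pixels), maps, None, tr, RunConfig())
        e0, _ = obj(np.zeros(tr.n_ctrl * 2))
        field, info = rg.refine_bspline(
            Image2D(b.pixels), maps, None, None, RunConfig(), cp_spacing=10.0, max_iter=30
        )
        assert info["objective"] <= e0 + 1e-12

    def test_strong_bending_weight_yields_near_affine_field(self, rng):
        from synthreg.synthetic import PhantomSpec, make_pair

        pair = make_pair(PhantomSpec(shape=(32, 32)), 10.0, 4)
        maps = PredictionMaps(pair.fixed.pixels.copy(), np.full((32, 32), 30.0))
        cfg = RunConfig(beta_bending=1e6, beta_linear=0.0)
        field, _ = rg.refine_bspline(
            pair.moving, maps, None, pair.truth_field, cfg, cp_spacing=6.0, max_iter=400
        )
        e_b, _ = rg.bending_energy(field.u, 1.0)
        e_b0, _ = rg.bending_energy(pair.truth_field.u, 1.0)
        assert e_b < 0.01 * e_b0


class TestMutualInformation:
    def test_self_information_equals_entropy(self):
        x = np.repeat(np.arange(8), 100).astype(float)
        assert rg.mutual_information(x, x, bins=8) == pytest.approx(np.log(8))

    def test_independent_noise_near_zero(self, rng):
        a = rng.random(300000) * 255
        b = rng.random(300000) * 255
        mi = rg.mutual_information(a, b, bins=64)
        assert mi == pytest.approx(0.0, abs=0.02)

    def test_constant_image_degenerate(self):
        assert rg.mutual_information(np.full(100, 5.0), np.arange(100.0)) == 0.0

    def test_translation_sweep_peaks_at_true_shift(self, rng):
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(rng.random((64, 64)), 2.0) * 255
        shift = 3
        rolled = np.roll(img, shift, axis=1)
        scores = []
        for t in range(-6, 7):
            back = np.roll(rolled, -t, axis=1)
            scores.append(rg.mutual_information(back[:, 8:-8], img[:, 8:-8], bins=32))
        assert np.argmax(scores) == shift + 6

    def test_register_mi_recovers_small_translation(self, rng):
        from synthreg.synthetic import PhantomSpec, make_phantom
        from synthreg.deformation import DeformationField as DF, warp_image

        a, b = make_phantom(PhantomSpec(shape=(48, 48)), 6)
        u = np.zeros((48, 48, 2))
        u[..., 0] = 2.0
        moved = warp_image(b, DF(u))
        cfg = RunConfig()
        field, info = rg.register_mi(moved, a, None, cfg, cp_spacing=24.0, maxfev=2000)
        # recovered displacement should be ~ -2 mm in x over the interior
        inner = field.u[16:-16, 16:-16, 0]
        assert np.abs(inner.mean() - (-2.0)) < 0.8


class TestBeliefSummaries:
    def test_uniform_beliefs_zero_expectation(self):
        labels = make_label_set(1, 1)
        q = np.full((5, 5, 9), 1.0 / 9.0)
        field = rg.expected_displacement(q, labels)
        np.testing.assert_allclose(field.u, 0.0, atol=1e-15)
        np.testing.assert_allclose(rg.entropy_map(q), np.log(9))

    def test_point_mass_recovers_label(self):
        labels = make_label_set(1, 1)
        q = np.zeros((3, 3, 9))
        q[..., 7] = 1.0
        field = rg.expected_displacement(q, labels)
        np.testing.assert_allclose(field.u, np.broadcast_to(labels.deltas[7], (3, 3, 2)))
        assert rg.entropy_map(q).max() == pytest.approx(0.0, abs=1e-12)
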