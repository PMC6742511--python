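import numpy as np
import pytest

from synthreg import vem
from synthreg.deformation import make_label_set
from synthreg.io import Image2D, LandmarkSet, RunConfig
from synthreg.synthesis import PredictionMaps
from synthreg.synthetic import PhantomSpec, make_phantom


def brute_force_posterior(M, maps, labels, beta1):
    """Independent per-pixel enumeration of the closed-form posterior
    (beta2 = 0, no landmarks), written directly from the model definition."""
    h, w = M.shape
    S = labels.n_labels
    q = np.zeros((h, w, S))
    vals, valid = vem.shifted_intensities(M, labels)
    for i in range(h):
        for j in range(w):
            mu, var = maps.mu[i, j], maps.var[i, j]
            lik = np.empty(S)
            for s in range(S):
                lik[s] = np.exp(-((vals[i, j, s] - mu) ** 2) / (2 * var)) / np.sqrt(
                    2 * np.pi * var
                )
            if (~valid[i, j]).any() and valid[i, j].any():
                lik[~valid[i, j]] = lik[valid[i, j]].mean()
            unnorm = lik * np.exp(-beta1 * (labels.deltas ** 2).sum(1))
            q[i, j] = unnorm / unnorm.sum()
    return q


class TestInitBeliefs:
    def test_uniform(self):
        labels = make_label_set(1, 1)
        q = vem.init_beliefs((4, 5), labels)
        np.testing.assert_allclose(q, 1.0 / 9.0)
        np.testing.assert_allclose(q.sum(axis=-1), 1.0)
        ent = -(q * np.log(q)).sum(axis=-1)
        np.testing.assert_allclose(ent, np.log(9))


class TestEStep:
    def test_flat_likelihood_stays_uniform(self):
        M = Image2D(np.full((8, 8), 50.0))
        maps = PredictionMaps(np.full((8, 8), 50.0), np.full((8, 8), 4.0))
        labels = make_label_set(1, 1)
        q0 = vem.init_beliefs((8, 8), labels)
        q = vem.estep_update(q0, maps, M, None, labels, beta1=0.0, beta2=0.0)
        np.testing.assert_allclose(q, 1.0 / 9.0, atol=1e-12)

    def test_closed_form_matches_brute_force(self, rng):
        M = Image2D(rng.random((10, 10)) * 255)
        maps = PredictionMaps(rng.random((10, 10)) * 255, rng.uniform(5, 50, (10, 10)))
        labels = make_label_set(2, 1)
        q0 = vem.init_beliefs((10, 10), labels)
        q = vem.estep_update(q0, maps, M, None, labels, beta1=0.02, beta2=0.0)
        expect = brute_force_posterior(M, maps, labels, beta1=0.02)
        np.testing.assert_allclose(q, expect, atol=1e-12)

    def test_dominant_landmark_selects_nearest_label(self):
        # flat likelihood, tiny sigma_k: the landmark term decides
        M = Image2D(np.full((12, 12), 100.0))
        maps = PredictionMaps(np.full((12, 12), 100.0), np.full((12, 12), 25.0))
        labels = make_label_set(3, 1)
        k_hist = np.array([[6.0, 6.0]])
        # k - k^h = (2, 0): residual ||k^h - k + Delta|| is minimal at (2, 0)
        k_mri = k_hist + np.array([[2.0, 0.0]])
        lm = LandmarkSet(k_mri, k_hist, sigma_k=0.05)
        q0 = vem.init_beliefs((12, 12), labels)
        q = vem.estep_update(q0, maps, M, lm, labels, beta1=0.0, beta2=0.0, sigma_k=0.05)
        best = labels.deltas[np.argmax(q[6, 6])]
        np.testing.assert_allclose(best, [2.0, 0.0])

    def test_beliefs_remain_normalised_with_coupling(self, rng):
        M = Image2D(rng.random((10, 10)) * 255)
        maps = PredictionMaps(rng.random((10, 10)) * 255, rng.uniform(5, 50, (10, 10)))
        labels = make_label_set(2, 1)
        q0 = vem.init_beliefs((10, 10), labels)
        q = vem.estep_update(q0, maps, M, None, labels, beta1=0.02, beta2=0.1, max_inner=6)
        assert np.all(q >= 0)
        np.testing.assert_allclose(q.sum(axis=-1), 1.0, atol=1e-12)

    def test_landmark_sharpens_neighbourhood_entropy(self):
        # flat likelihood isolates the mechanism: without the landmark q stays
        # uniform; with it, the pairwise coupling spreads the confidence to
        # the 4-neighbourhood
        M = Image2D(np.full((14, 14), 100.0))
        maps = PredictionMaps(np.full((14, 14), 100.0), np.full((14, 14), 25.0))
        labels = make_label_set(2, 1)
        q0 = vem.init_beliefs((14, 14), labels)
        # offset landmark: the confident displacement (2, 0) at the landmark
        # pixel propagates through the neighbour moments
        lm = LandmarkSet([[9.0, 7.0]], [[7.0, 7.0]], sigma_k=0.3)
        q_no = vem.estep_update(q0, maps, M, None, labels, 0.0, 0.1, max_inner=20)
        q_lm = vem.estep_update(q0, maps, M, lm, labels, 0.0, 0.1, sigma_k=0.3, max_inner=20)

        def ent(q, i, j):
            p = np.maximum(q[i, j], 1e-300)
            return -(p * np.log(p)).sum()

        assert ent(q_lm, 7, 7) < ent(q_no, 7, 7)
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            assert ent(q_lm, 7 + di, 7 + dj) < ent(q_no, 7 + di, 7 + dj)

    def test_free_energy_nondecreasing_over_sweeps(self, rng):
        M = Image2D(rng.random((10, 10)) * 255)
        maps = PredictionMaps(rng.random((10, 10)) * 255, rng.uniform(20, 80, (10, 10)))
        labels = make_label_set(2, 1)
        q = vem.init_beliefs((10, 10), labels)
        prev = vem.free_energy(q, maps, M, None, labels, 0.02, 0.05)
        for _ in range(5):
            q = vem.estep_update(q, maps, M, None, labels, 0.02, 0.05, max_inner=1, tol=0.0)
            cur = vem.free_energy(q, maps, M, None, labels, 0.02, 0.05)
            assert cur >= prev - 1e-9
            prev = cur


class TestMStepAndRun:
    def test_pointmass_truth_beats_uniform_beliefs(self, rng):
        from synthreg.synthesis import ForestHyperparams, extract_features, predict

        a, b = make_phantom(PhantomSpec(shape=(40, 40), noise_std=0.0, bias_amplitude=0.0), 3)
        labels = make_label_set(2, 1)
        feats = extract_features(a)
        hyper = ForestHyperparams(n_trees=8)
        q_true = np.zeros((40, 40, labels.n_labels))
        q_true[..., labels.zero_index] = 1.0
        q_unif = vem.init_beliefs((40, 40), labels)
        m_true, maps_true = vem.mstep_update(
            [feats], [b], [q_true], labels, hyper, np.random.default_rng(0)
        )
        m_unif, maps_unif = vem.mstep_update(
            [feats], [b], [q_unif], labels, hyper, np.random.default_rng(0)
        )
        sel = a.mask
        rmse_true = np.sqrt(np.mean((maps_true[0].mu - b.pixels)[sel] ** 2))
        rmse_unif = np.sqrt(np.mean((maps_unif[0].mu - b.pixels)[sel] ** 2))
        assert rmse_true < rmse_unif

    def test_mstep_deterministic_under_seed(self, rng):
        from synthreg.synthesis import ForestHyperparams, extract_features

        a, b = make_phantom(PhantomSpec(shape=(24, 24)), 5)
        labels = make_label_set(1, 1)
        feats = extract_features(a)
        hyper = ForestHyperparams(n_trees=3)
        _, maps1 = vem.mstep_update([feats], [b], [vem.init_beliefs((24, 24), labels)],
                                    labels, hyper, np.random.default_rng(42))
        _, maps2 = vem.mstep_update([feats], [b], [vem.init_beliefs((24, 24), labels)],
                                    labels, hyper, np.random.default_rng(42))
        np.testing.assert_array_equal(maps1[0].mu, maps2[0].mu)
        np.testing.assert_array_equal(maps1[0].var, maps2[0].var)

    def test_multi_pair_pools_pixels(self, rng):
        from synthreg.synthesis import ForestHyperparams, extract_features, fit

        pairs = [make_phantom(PhantomSpec(shape=(24, 24)), s) for s in (1, 2)]
        labels = make_label_set(1, 1)
        feats = [extract_features(a) for a, _ in pairs]
        mris = [b for _, b in pairs]
        qs = [vem.init_beliefs((24, 24), labels) for _ in pairs]
        model = fit(feats, mris, qs, labels, ForestHyperparams(n_trees=3),
                    np.random.default_rng(0), pooled_pixel_budget=400)
        # with 2 pairs and 66% bagging each tree uses at least one pair; over
        # 3 trees both pairs' pixel pools are drawn from without error
        assert model.n_trees == 3

    def test_self_registration_recovers_zero_displacement(self):
        # identical modality, zero true deformation
        a, _ = make_phantom(PhantomSpec(shape=(48, 48)), 11)
        cfg = RunConfig(label_radius=2.0, label_step=1.0, n_trees=8, max_outer=3,
                        max_inner=6)
        state = vem.run([a], [a], config=cfg, rng=np.random.default_rng(0))
        from synthreg.registration import expected_displacement

        ed = expected_displacement(state.beliefs[0], state.labels)
        mags = ed.magnitude()[a.mask]
        assert mags.mean() < cfg.label_step

    def test_history_recorded_each_iteration(self):
        a, b = make_phantom(PhantomSpec(shape=(32, 32)), 2)
        cfg = RunConfig(label_radius=1.0, label_step=1.0, n_trees=4, max_outer=2,
                        max_inner=4)
        state = vem.run([b], [a], config=cfg, rng=np.random.default_rng(0))
        assert len(state.history) == state.iteration
        assert all("rel_change_mu" in h for h in state.history)
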