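"""EM core: likelihood, posterior moments, updates, rescaling, matching."""

import numpy as np
import pytest

import perfifa as pf
from perfifa.ifa import _estep, m_step
from perfifa.mog import MoGSourceParams, build_q_states

from conftest import grid_oracle, random_small_model, sample_from_model


def _unit_model(mixing, noise, weights, means, variances):
    return pf.IFAModel(
        mixing=np.asarray(mixing, float),
        noise_diag=np.asarray(noise, float),
        mog=MoGSourceParams(
            [np.asarray(w, float) for w in weights],
            [np.asarray(m, float) for m in means],
            [np.asarray(v, float) for v in variances],
        ),
    )


class TestNegativeLogLikelihood:
    def test_scalar_gaussian_closed_form(self):
        """T=1, N=1 single standard Gaussian source, H=1, Lambda=1, y=0:
        the marginal is N(0, 2), so the loss is 0.5*log(4*pi)."""
        model = _unit_model([[1.0]], [1.0], [[1.0]], [[0.0]], [[1.0]])
        nll = pf.negative_log_likelihood(np.array([[0.0]]), model)
        assert nll == pytest.approx(0.5 * np.log(4 * np.pi), abs=1e-12)

    def test_matches_grid_quadrature(self, rng):
        """Exact marginalisation agrees with dense-grid quadrature over x."""
        model = random_small_model(rng, t=3, n=2)
        y = rng.normal(0, 2, size=(3, 10))
        oracle_nll, oracle_ex = grid_oracle(y, model)
        nll = pf.negative_log_likelihood(y, model)
        assert nll == pytest.approx(oracle_nll, abs=1e-4)
        mom = pf.e_step(y, model)
        np.testing.assert_allclose(mom.post_mean, oracle_ex, atol=1e-4)

    def test_single_source_posterior_matches_bayes_quadrature(self, rng):
        """N=1, two-component MoG: component responsibilities match a direct
        1-D Bayes-rule computation by quadrature."""
        model = random_small_model(rng, t=2, n=1, n_gauss=2)
        y = rng.normal(0, 2, size=(2, 5))
        mom = pf.e_step(y, model)
        gs = np.linspace(-12, 12, 4001)
        dx = gs[1] - gs[0]
        w, m, v = model.mog.weights[0], model.mog.means[0], model.mog.variances[0]
        for p in range(y.shape[1]):
            lik = np.ones_like(gs)
            for t in range(2):
                lam = model.noise_diag[t]
                lik = lik * np.exp(
                    -0.5 * (y[t, p] - model.mixing[t, 0] * gs) ** 2 / lam
                ) / np.sqrt(2 * np.pi * lam)
            post_q = []
            for a in range(2):
                comp = w[a] * np.exp(-0.5 * (gs - m[a]) ** 2 / v[a]) / np.sqrt(
                    2 * np.pi * v[a]
                )
                post_q.append((comp * lik).sum() * dx)
            post_q = np.array(post_q) / np.sum(post_q)
            np.testing.assert_allclose(mom.comp_resp[0][:, p], post_q, atol=1e-6)


class TestEStep:
    def test_noiseless_limit_inverts_mixing(self, rng):
        """With vanishing noise, a square invertible H and a single joint
        state, the posterior mean approaches H^-1 y."""
        h = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        model = _unit_model(
            h, [1e-10, 1e-10], [[1.0], [1.0]], [[0.0], [0.0]], [[1.0], [1.0]]
        )
        y = rng.normal(size=(2, 6))
        mom = pf.e_step(y, model)
        np.testing.assert_allclose(mom.post_mean, np.linalg.solve(h, y), rtol=1e-4)

    def test_responsibilities_normalised(self, rng):
        model = random_small_model(rng, t=3, n=2)
        y = rng.normal(0, 3, size=(3, 20))
        mom = pf.e_step(y, model)
        np.testing.assert_allclose(mom.state_resp.sum(axis=0), 1.0, atol=1e-12)
        for j in range(2):
            np.testing.assert_allclose(mom.comp_resp[j].sum(axis=0), 1.0, atol=1e-12)


class TestMStep:
    def test_fixed_point_self_consistency(self):
        """Data generated by the model, many pixels: one EM update stays
        close to the generating parameters."""
        rng = np.random.default_rng(3)
        model = random_small_model(rng, t=4, n=2)
        model = pf.rescale(model)
        y = sample_from_model(model, 100_000, rng)
        qt = build_q_states(model.mog)
        stats = _estep(y, model.mixing, model.noise_diag, qt)
        mixing, noise, mog = m_step(stats, model.mog.n_components)
        col = np.linalg.norm(model.mixing, axis=0)
        assert np.max(np.abs(mixing - model.mixing) / col) < 1e-2
        assert np.max(np.abs(noise - model.noise_diag)) < 1e-2
        for j in range(2):
            assert np.max(np.abs(np.sort(mog.means[j]) - np.sort(model.mog.means[j]))) < 5e-2

    def test_weights_normalised_and_noise_positive(self, rng):
        """Across many random small instances the updated MoG weights sum to
        one and the noise diagonal stays positive."""
        for i in range(100):
            r = np.random.default_rng(i)
            model = random_small_model(r, t=3, n=2)
            y = sample_from_model(model, 50, r)
            qt = build_q_states(model.mog)
            stats = _estep(y, model.mixing, model.noise_diag, qt)
            _, noise, mog = m_step(stats, model.mog.n_components)
            assert np.all(noise > 0)
            for j in range(2):
                assert mog.weights[j].sum() == pytest.approx(1.0, abs=1e-9)


class TestRescale:
    def test_unit_variance_is_identity(self):
        model = _unit_model(
            [[1.0], [0.5]], [1.0, 1.0], [[1.0]], [[0.0]], [[1.0]]
        )
        out = pf.rescale(model)
        np.testing.assert_allclose(out.mixing, model.mixing)
        np.testing.assert_allclose(out.mog.variances[0], [1.0])

    def test_sigma_two_doubles_column(self):
        """A zero-mean source with variance 4 halves its scale and doubles
        the mixing column."""
        model = _unit_model([[1.0], [2.0]], [1.0, 1.0], [[1.0]], [[0.0]], [[4.0]])
        out = pf.rescale(model)
        np.testing.assert_allclose(out.mixing[:, 0], [2.0, 4.0])
        assert out.mog.marginal_variance(0) == pytest.approx(1.0)

    def test_likelihood_invariant(self):
        """Rescaling is a pure reparametrisation: the data likelihood is
        unchanged on random instances."""
        for i in range(10):
            rng = np.random.default_rng(100 + i)
            model = random_small_model(rng, t=3, n=2)
            y = rng.normal(0, 2, size=(3, 15))
            before = pf.negative_log_likelihood(y, model)
            after = pf.negative_log_likelihood(y, pf.rescale(model))
            assert after == pytest.approx(before, abs=1e-8)

    def test_degenerate_source_rejected(self):
        # a collapsed source (zero component variance) is rejected either at
        # construction or by the rescale guard, whichever sees it first
        with pytest.raises(ValueError, match="degenerate|variance"):
            model = _unit_model([[1.0]], [1.0], [[1.0]], [[0.0]], [[1e-12]])
            model.mog.variances[0][0] = 0.0
            pf.rescale(model)


class TestFit:
    def test_monotone_loss_and_determinism(self, rng):
        """The loss trace never increases, and the same seed reproduces the
        same model bit for bit."""
        truth = random_small_model(rng, t=4, n=2)
        y = sample_from_model(pf.rescale(truth), 2000, rng)
        m1 = pf.fit_ifa(y, 2, 2, seed=11, n_restarts=2, max_iter=80)
        m2 = pf.fit_ifa(y, 2, 2, seed=11, n_restarts=2, max_iter=80)
        trace = np.array(m1.loss_trace)
        assert np.all(np.diff(trace) <= 1e-8)
        np.testing.assert_array_equal(m1.mixing, m2.mixing)
        np.testing.assert_array_equal(m1.noise_diag, m2.noise_diag)

    def test_underdetermined_warns(self, rng):
        y = rng.normal(size=(2, 40))
        with pytest.warns(RuntimeWarning, match="underdetermined|converge"):
            pf.fit_ifa(y, 3, 1, seed=0, n_restarts=1, max_iter=5)

    def test_nonconvergence_flag_not_exception(self, rng):
        y = rng.normal(size=(3, 60))
        with pytest.warns(RuntimeWarning):
            model = pf.fit_ifa(y, 2, 2, seed=0, n_restarts=1, max_iter=2)
        assert model.converged is False
        assert len(model.loss_trace) >= 2


class TestLMSReconstruction:
    def test_matches_explicit_state_sum(self, rng):
        """The reconstruction equals the explicit sum over joint states of
        p(q|y) (A_q y + b_q) with A_q, b_q formed from the model."""
        model = random_small_model(rng, t=3, n=2)
        y = rng.normal(0, 2, size=(3, 12))
        fimgs = pf.reconstruct_sources_lms(y, model, grid_shape=(1, 12))
        qt = build_q_states(model.mog)
        mom = pf.e_step(y, model)
        lam_inv = np.diag(1.0 / model.noise_diag)
        h = model.mixing
        explicit = np.zeros((2, 12))
        for s in range(qt.n_states):
            vq_inv = np.diag(1.0 / qt.variances[s])
            prec = h.T @ lam_inv @ h + vq_inv
            a_q = np.linalg.solve(prec, h.T @ lam_inv)
            b_q = np.linalg.solve(prec, vq_inv @ qt.means[s])
            explicit += mom.state_resp[s] * (a_q @ y + b_q[:, None])
        np.testing.assert_allclose(fimgs.images, explicit, atol=1e-10)

    def test_noiseless_single_state_limit(self, rng):
        h = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        model = _unit_model(
            h, [1e-10, 1e-10], [[1.0], [1.0]], [[0.0], [0.0]], [[1.0], [1.0]]
        )
        y = rng.normal(size=(2, 5))
        fimgs = pf.reconstruct_sources_lms(y, model, grid_shape=(1, 5))
        np.testing.assert_allclose(fimgs.images, np.linalg.solve(h, y), rtol=1e-4)


class TestMatching:
    def test_self_match_is_identity(self, rng):
        comps = rng.normal(size=(3, 50))
        res = pf.match_components(comps, comps)
        np.testing.assert_array_equal(res.permutation, np.arange(3))
        np.testing.assert_allclose(res.correlations, 1.0)
        j = pf.mixing_crosstalk(comps.T, comps.T, res)
        np.testing.assert_allclose(j, np.eye(3), atol=1e-10)

    def test_recovers_permutation_sign_and_scale(self, rng):
        truth = rng.normal(size=(4, 60))
        perm = np.array([2, 0, 3, 1])
        scales = np.array([1.5, -0.3, 2.0, -4.0])
        est = truth[perm] * scales[:, None]
        res = pf.match_components(est, truth)
        # est row matched to truth row k must be the one built from it
        for k in range(4):
            assert perm[res.permutation[k]] == k
        np.testing.assert_allclose(res.correlations, 1.0)

    def test_zero_variance_component_warns(self, rng):
        est = np.vstack([np.zeros(20), rng.normal(size=20)])
        truth = rng.normal(size=(2, 20))
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            res = pf.match_components(est, truth)
        assert np.min(res.correlations) == 0.0

    def test_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="counts"):
            pf.match_components(rng.normal(size=(2, 10)), rng.normal(size=(3, 10)))
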