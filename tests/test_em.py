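"""EM machinery: E-step moments, M-step ascent, initialization, fitting."""

import warnings

import numpy as np
import pytest

import zifa
from zifa.em import (
    ConvergenceWarning,
    e_step_exact,
    expected_complete_loglik,
    initialize,
    m_step,
    make_blocks,
)


class TestEStep:
    def test_no_zeros_reduces_to_fa_posterior(self):
        """Without zeros the z-posterior is the textbook FA posterior."""
        rng = np.random.default_rng(1)
        D, K, N = 6, 2, 15
        p = zifa.ModelParams(
            A=rng.uniform(-0.5, 0.5, (D, K)),
            mu=np.full(D, 3.0),
            sigma2=rng.uniform(0.2, 0.6, D),
            lam=5.0,
        )
        Y = np.abs(rng.normal(3.0, 1.0, (N, D))) + 0.5  # strictly positive
        post = e_step_exact(p, Y)
        Lam = np.eye(K) + p.A.T @ np.diag(1 / p.sigma2) @ p.A
        Ez_fa = np.linalg.solve(Lam, p.A.T @ np.diag(1 / p.sigma2) @ (Y - p.mu).T).T
        assert np.allclose(post.Ez, Ez_fa, atol=1e-10)
        cov = np.linalg.inv(Lam)
        assert np.allclose(post.Ezz[0] - np.outer(post.Ez[0], post.Ez[0]), cov, atol=1e-10)

    def test_moments_match_importance_sampling(self, small_params):
        """Exact E-step agrees with a brute-force weighted-sample oracle."""
        from scipy.stats import norm

        p = small_params
        st_ = zifa.sample(p, 10, seed=3)
        assert 0 < (st_.Y == 0).sum() < st_.Y.size
        post = e_step_exact(p, st_.Y)
        rng = np.random.default_rng(0)
        S = 300_000
        z = rng.standard_normal((S, 1))
        x = z @ p.A.T + p.mu + rng.standard_normal((S, 3)) * np.sqrt(p.sigma2)
        mean_x = z @ p.A.T + p.mu
        for i in range(10):
            w = np.ones(S)
            for j in range(3):
                if st_.Y[i, j] == 0:
                    w *= np.exp(-p.lam * x[:, j] ** 2)
                else:
                    w *= norm.pdf(st_.Y[i, j], mean_x[:, j], np.sqrt(p.sigma2[j]))
            w /= w.sum()
            ess = 1.0 / np.sum(w**2)
            se_z = np.sqrt(np.sum(w * (z[:, 0] - np.sum(w * z[:, 0])) ** 2) / ess)
            assert post.Ez[i, 0] == pytest.approx(np.sum(w * z[:, 0]), abs=4 * se_z + 1e-4)
            for j in range(3):
                if st_.Y[i, j] == 0:
                    ex = np.sum(w * x[:, j])
                    se_x = np.sqrt(np.sum(w * (x[:, j] - ex) ** 2) / ess)
                    assert post.Ex[i, j] == pytest.approx(ex, abs=4 * se_x + 1e-4)
                    assert post.Ex2[i, j] == pytest.approx(
                        np.sum(w * x[:, j] ** 2), abs=8 * se_x + 1e-3
                    )

    def test_all_zero_cell_leans_on_the_prior(self, small_params):
        """Zero entries are soft (variance-inflated) pseudo-observations:
        an all-zero cell keeps a wider z-posterior than a fully observed
        cell, and its mean is shrunk relative to treating the zeros as
        hard observations of x = 0."""
        import dataclasses

        Y = np.array([[0.0, 0.0, 0.0], [3.2, 2.9, 2.4]])
        post = e_step_exact(small_params, Y)
        var = post.Ezz[:, 0, 0] - post.Ez[:, 0] ** 2
        assert var[0] > var[1]
        # hard-observation reference: lam -> inf removes the inflation
        hard = e_step_exact(dataclasses.replace(small_params, lam=1e8), Y)
        assert abs(post.Ez[0, 0]) < abs(hard.Ez[0, 0])

    def test_second_moments_dominate_squared_means(self, base_sim):
        post = e_step_exact(base_sim.true_params, base_sim.Y)
        assert np.all(post.Ex0sq >= post.Ex0**2 - 1e-12)
        # Ezz - Ez Ez^T is a covariance: PSD for every cell
        covs = post.Ezz - np.einsum("nk,nl->nkl", post.Ez, post.Ez)
        assert np.linalg.eigvalsh(covs).min() > -1e-10


class TestMStep:
    def test_increases_expected_complete_loglik(self):
        """M-step ascends its own objective on random instances."""
        for seed in range(5):
            sim = zifa.simulate_factor_data(N=60, D=12, K=3, seed=seed)
            p0 = initialize(sim.Y, 3, seed=seed)
            post = e_step_exact(p0, sim.Y)
            p1 = m_step(post, sim.Y, p0)
            assert expected_complete_loglik(p1, post, sim.Y) >= (
                expected_complete_loglik(p0, post, sim.Y) - 1e-8
            )

    def test_tied_variance_is_constant(self, base_sim):
        p0 = initialize(base_sim.Y, 10, seed=0)
        post = e_step_exact(p0, base_sim.Y)
        p1 = m_step(post, base_sim.Y, p0, tied_variance=True)
        assert np.ptp(p1.sigma2) == 0.0

    def test_no_zero_data_gives_classical_fa_update(self):
        """With no zeros the A, mu, sigma2 update is the FA M-step."""
        rng = np.random.default_rng(2)
        D, K, N = 5, 2, 40
        Y = np.abs(rng.normal(3, 1, (N, D))) + 0.5
        p0 = zifa.ModelParams(
            A=rng.uniform(-0.5, 0.5, (D, K)), mu=Y.mean(0), sigma2=np.full(D, 0.4), lam=1.0
        )
        post = e_step_exact(p0, Y)
        p1 = m_step(post, Y, p0)
        # classical FA normal equations from the same moments
        s1, S2 = post.Ez.sum(0), post.Ezz.sum(0)
        G = np.block([[S2, s1[:, None]], [s1[None, :], np.array([[N]])]])
        for j in range(D):
            rhs = np.concatenate([(Y[:, j : j + 1] * post.Ez).sum(0), [Y[:, j].sum()]])
            beta = np.linalg.solve(G, rhs)
            assert np.allclose(p1.A[j], beta[:K], atol=1e-10)
            assert p1.mu[j] == pytest.approx(beta[K], abs=1e-10)


class TestInitialize:
    def test_lam_within_factor_three_at_base_setting(self):
        hits = 0
        for seed in range(10):
            sim = zifa.simulate_factor_data(seed=seed)
            lam0 = initialize(sim.Y, 10, seed=seed).lam
            hits += 0.1 / 3 < lam0 < 0.1 * 3
        assert hits > 5

    def test_zero_free_falls_back_to_small_default(self):
        rng = np.random.default_rng(0)
        Y = np.abs(rng.normal(3, 1, (50, 8))) + 0.5
        assert initialize(Y, 2, seed=0).lam == zifa.em.LAM_DEFAULT_INIT

    def test_deterministic_under_seed(self, base_sim):
        a = initialize(base_sim.Y, 5, seed=3)
        b = initialize(base_sim.Y, 5, seed=3)
        assert np.array_equal(a.A, b.A) and a.lam == b.lam

    def test_all_zero_gene_rejected(self):
        Y = np.abs(np.random.default_rng(0).normal(3, 1, (20, 4)))
        Y[:, 2] = 0.0
        with pytest.raises(ValueError, match="filter"):
            initialize(Y, 2, seed=0)


class TestMakeBlocks:
    @pytest.mark.parametrize(
        "D,size,expected_sizes",
        [(500, 50, [50] * 10), (40, 40, [40]), (53, 50, [50, 3])],
    )
    def test_chunking(self, D, size, expected_sizes):
        part = make_blocks(D, size, seed=0)
        assert [len(b) for b in part.blocks] == expected_sizes
        assert sorted(np.concatenate(part.blocks)) == list(range(D))

    def test_deterministic_and_permuted(self):
        a = make_blocks(100, 30, seed=5)
        b = make_blocks(100, 30, seed=5)
        assert all(np.array_equal(x, y) for x, y in zip(a.blocks, b.blocks))
        assert not np.array_equal(a.blocks[0], np.arange(30))  # actually shuffled

    def test_bad_block_size(self):
        with pytest.raises(ValueError):
            make_blocks(10, 0, seed=0)


class TestFit:
    def test_monotone_loglik_trace(self, base_sim):
        state = zifa.fit_exact(base_sim.Y, 10, seed=0)
        diffs = np.diff(state.loglik_trace)
        assert np.all(diffs >= -1e-8)
        assert state.converged

    def test_block_size_d_degenerates_to_exact(self):
        """A single block is the exact algorithm (gene order aside)."""
        sim = zifa.simulate_factor_data(N=60, D=20, K=3, seed=4)
        p0 = initialize(sim.Y, 3, seed=4)
        pe = zifa.e_step_exact(p0, sim.Y)
        pb = zifa.e_step_block(p0, sim.Y, make_blocks(20, 20, seed=4))
        assert np.allclose(pe.Ez, pb.Ez, atol=1e-12)
        assert np.allclose(pe.Ex, pb.Ex, atol=1e-12)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            ex = zifa.fit_exact(sim.Y, 3, seed=4, max_iter=8)
            bl = zifa.fit_block(sim.Y, 3, block_size=20, seed=4, max_iter=8)
        # summation order inside the permuted block differs, so allow
        # float-accumulation drift over the iterations
        assert np.allclose(ex.loglik_trace, bl.loglik_trace, rtol=1e-6)

    def test_nonconvergence_warns_and_flags(self, base_sim):
        with pytest.warns(ConvergenceWarning):
            state = zifa.fit_exact(base_sim.Y, 10, seed=0, max_iter=3)
        assert not state.converged

    def test_block_runtime_scales_linearly_in_genes(self):
        """Per-iteration cost grows ~linearly with D at fixed block size."""
        import time

        times = {}
        for D in (100, 200, 400):
            sim = zifa.simulate_factor_data(N=60, D=D, K=5, seed=0)
            p0 = initialize(sim.Y, 5, seed=0)
            part = make_blocks(D, 50, seed=0)
            t0 = time.perf_counter()
            for _ in range(5):
                post = zifa.e_step_block(p0, sim.Y, part)
                m_step(post, sim.Y, p0)
            times[D] = time.perf_counter() - t0
        # quadratic growth would give a 16x ratio from 100 to 400; allow
        # generous slack around the linear 4x for constant overheads
        assert times[400] / times[100] < 8.0

    def test_fit_deterministic_under_seed(self):
        sim = zifa.simulate_factor_data(N=50, D=15, K=2, seed=6)
        a = zifa.fit_exact(sim.Y, 2, seed=6)
        b = zifa.fit_exact(sim.Y, 2, seed=6)
        assert np.array_equal(a.params.A, b.params.A)
        assert a.loglik_trace == b.loglik_trace
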