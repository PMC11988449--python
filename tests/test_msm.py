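"""MSM stack: discretisation, counting, reversible MLE, timescales, tICA,
VAMP-2 and free-energy projection — each checked against an independent
oracle (brute-force enumeration, constrained optimiser, analytic chains)."""

import numpy as np
import pytest
from scipy import optimize

from crypticsite import msm


# ---------------------------------------------------------------- k-means
class TestKmeans:
    def test_k_equals_frames(self):
        x = np.arange(6, dtype=float).reshape(-1, 1) * 10
        d = msm.kmeans_discretize(x, k=6, seed=0)
        assert len(np.unique(d.labels[0])) == 6

    def test_k_one(self):
        x = np.random.default_rng(0).normal(size=(20, 3))
        d = msm.kmeans_discretize(x, k=1, seed=0)
        assert np.all(d.labels[0] == 0)

    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.normal(loc=0.0, scale=1.0, size=(100, 2))
        b = rng.normal(loc=20.0, scale=1.0, size=(100, 2))
        d = msm.kmeans_discretize(np.vstack([a, b]), k=2, seed=0)
        la, lb = d.labels[0][:100], d.labels[0][100:]
        assert len(np.unique(la)) == 1 and len(np.unique(lb)) == 1
        assert la[0] != lb[0]

    def test_k_exceeds_frames_error(self):
        with pytest.raises(ValueError):
            msm.kmeans_discretize(np.zeros((3, 1)), k=4)


# --------------------------------------------------------------- counting
class TestCountTransitions:
    def test_enumerated_pairs_lag1(self):
        c = msm.count_transitions([np.array([0, 0, 1, 1])], lag=1)
        assert np.array_equal(c, [[1, 1], [0, 1]])

    def test_lag3_single_pair(self):
        c = msm.count_transitions([np.array([0, 0, 1, 1])], lag=3)
        assert np.array_equal(c, [[0, 1], [0, 0]])

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, size=200)
        for lag in (1, 2, 5):
            c = msm.count_transitions([labels], lag=lag)
            brute = np.zeros((4, 4))
            for t in range(len(labels) - lag):
                brute[labels[t], labels[t + lag]] += 1
            assert np.array_equal(c, brute)

    def test_no_counting_across_trajectories(self):
        c = msm.count_transitions([np.array([0, 0]), np.array([1, 1])], lag=1)
        assert c[0, 1] == 0 and c[1, 0] == 0

    def test_short_trajectory_warns_and_skips(self):
        with pytest.warns(UserWarning, match="skipped"):
            c = msm.count_transitions([np.array([0]), np.array([0, 1])], lag=1,
                                      n_states=2)
        assert c.sum() == 1


# ------------------------------------------------------------------- SCC
class TestLargestConnectedSet:
    def test_block_diagonal(self):
        c = np.zeros((5, 5))
        c[0, 1] = c[1, 0] = 1          # 2-block
        c[2, 3] = c[3, 4] = c[4, 2] = 1  # 3-cycle
        assert msm.largest_connected_set(c).tolist() == [2, 3, 4]

    def test_fully_connected(self):
        c = np.ones((4, 4))
        assert msm.largest_connected_set(c).tolist() == [0, 1, 2, 3]

    def test_matches_networkx_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(3)
        c = (rng.random((12, 12)) < 0.12).astype(float)
        g = nx.from_numpy_array(c, create_using=nx.DiGraph)
        best = max(nx.strongly_connected_components(g), key=lambda s: (len(s), -min(s)))
        ours = set(msm.largest_connected_set(c).tolist())
        assert len(ours) == len(best)


# ------------------------------------------------------- reversible MLE
def _reversible_mle_oracle(c):
    """Constrained optimiser: maximise sum C_ij ln T_ij over symmetric
    nonneg flux x (upper-triangle parametrised), T_ij = x_ij / x_i."""
    n = c.shape[0]
    iu = np.triu_indices(n)

    def unpack(v):
        x = np.zeros((n, n))
        x[iu] = np.exp(v)           # positivity via log parametrisation
        x = x + x.T - np.diag(np.diag(x))
        return x

    def negll(v):
        x = unpack(v)
        t = x / x.sum(axis=1, keepdims=True)
        m = c > 0
        return -np.sum(c[m] * np.log(t[m]))

    v0 = np.log((c + c.T)[iu] / (c + c.T).sum() + 1e-8)
    res = optimize.minimize(negll, v0, method="Nelder-Mead",
                            options={"maxiter": 20000, "fatol": 1e-12, "xatol": 1e-10})
    return -res.fun


class TestReversibleTpm:
    def test_two_state_equals_row_normalised_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            c = rng.integers(1, 40, size=(2, 2)).astype(float)
            m = msm.estimate_reversible_tpm(c)
            assert np.allclose(m.transition_matrix,
                               c / c.sum(axis=1, keepdims=True), atol=1e-9)

    def test_symmetric_counts_uniform_pi(self):
        c = np.array([[4.0, 2.0, 2.0], [2.0, 4.0, 2.0], [2.0, 2.0, 4.0]])
        m = msm.estimate_reversible_tpm(c)
        assert np.allclose(m.stationary, 1 / 3, atol=1e-9)
        assert np.allclose(m.transition_matrix, m.transition_matrix.T, atol=1e-9)

    def test_detailed_balance_random_4state(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            c = rng.integers(1, 30, size=(4, 4)).astype(float)
            m = msm.estimate_reversible_tpm(c)
            flux = m.stationary[:, None] * m.transition_matrix
            assert np.abs(flux - flux.T).max() < 1e-8
            assert np.allclose(m.transition_matrix.sum(axis=1), 1.0, atol=1e-10)

    def test_likelihood_beats_naive_reversible_projection(self):
        rng = np.random.default_rng(11)
        c = rng.integers(1, 25, size=(4, 4)).astype(float)
        m = msm.estimate_reversible_tpm(c)
        ours = msm.reversible_log_likelihood(c, m.transition_matrix)
        naive_x = (c + c.T) / 2.0
        naive_t = naive_x / naive_x.sum(axis=1, keepdims=True)
        assert ours >= msm.reversible_log_likelihood(c, naive_t) - 1e-10

    def test_matches_constrained_optimizer_oracle(self):
        rng = np.random.default_rng(13)
        c = rng.integers(1, 20, size=(4, 4)).astype(float)
        m = msm.estimate_reversible_tpm(c)
        ours = msm.reversible_log_likelihood(c, m.transition_matrix)
        oracle = _reversible_mle_oracle(c)
        assert ours >= oracle - 1e-4     # fixed point attains the optimum


class TestStationary:
    def test_two_state_balance(self):
        pi = msm.stationary_distribution(np.array([[0.9, 0.1], [0.2, 0.8]]))
        assert np.allclose(pi, [2 / 3, 1 / 3], atol=1e-12)

    def test_doubly_stochastic_uniform(self):
        t = np.array([[0.5, 0.3, 0.2], [0.3, 0.5, 0.2], [0.2, 0.2, 0.6]])
        assert np.allclose(msm.stationary_distribution(t), 1 / 3, atol=1e-12)

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(17)
        c = rng.integers(1, 20, size=(5, 5)).astype(float)
        t = msm.estimate_reversible_tpm(c).transition_matrix
        pi = msm.stationary_distribution(t)
        p = np.full(5, 0.2)
        for _ in range(20000):
            p = p @ t
        assert np.abs(pi - p).max() < 1e-10

    def test_reducible_error(self):
        t = np.eye(2)
        with pytest.raises(ValueError, match="reducible"):
            msm.stationary_distribution(t)


def _sample_chain(t, n, seed, start=0):
    rng = np.random.default_rng(seed)
    cdf = np.cumsum(t, axis=1)
    out = np.empty(n, int)
    s = start
    u = rng.random(n)
    for i in range(n):
        s = int(np.searchsorted(cdf[s], u[i]))
        out[i] = s
    return out


class TestImpliedTimescales:
    def test_direct_formula_two_state(self):
        # 2-state chain with lambda2 = 0.7 at lag 5 -> t2 = -5/ln 0.7
        t = np.array([[0.85, 0.15], [0.15, 0.85]])   # lambda2 = 0.7
        labels = _sample_chain(t, 100_000, seed=3)
        # estimate at lag 5 frames from data generated at lag-1 dynamics:
        # lambda2(5 steps) = 0.7**5, so t2 = -5/ln(0.7**5) = -1/ln 0.7
        df = msm.implied_timescales([labels], lags=[5], n_states=2)
        expected = -1.0 / np.log(0.7)
        got = df.loc[df["process"] == 2, "timescale"].iloc[0]
        assert got == pytest.approx(expected, rel=0.10)

    def test_eigenvalue_near_one_flagged(self):
        c = np.array([[1000.0, 1.0], [1.0, 1000.0]])
        m = msm.estimate_reversible_tpm(c)
        lam = msm.eigenvalues_reversible(m)[1]
        assert lam > 0.99

    def test_markov_chain_timescales_lag_independent(self):
        # exact 3-state reversible chain: t_k(tau) constant in tau
        t = np.array([[0.90, 0.08, 0.02],
                      [0.08, 0.84, 0.08],
                      [0.02, 0.08, 0.90]])
        labels = _sample_chain(t, 200_000, seed=5)
        df = msm.implied_timescales([labels], lags=[1, 2, 4, 8], n_states=3,
                                    n_timescales=1)
        ts = df.loc[df["process"] == 2, "timescale"].to_numpy()
        analytic = -1.0 / np.log(np.sort(np.linalg.eigvals(t).real)[-2])
        assert np.all(np.abs(ts - analytic) / analytic < 0.15)


def _ar1(n, rho, seed, d_noise=0):
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    e = rng.standard_normal(n)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + e[t]
    cols = [x]
    for k in range(d_noise):
        cols.append(rng.standard_normal(n))
    return np.stack(cols, axis=1)


class TestTica:
    def test_white_noise_eigenvalues_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((50_000, 3))
        model = msm.tica_fit(x, lag=1)
        assert np.abs(model.eigenvalues).max() < 0.05

    def test_ar1_leading_eigenvalue(self):
        n, rho = 200_000, 0.9
        x = _ar1(n, rho, seed=1)
        model = msm.tica_fit(x, lag=1)
        # autocorrelation estimator SE ~ sqrt((1-rho^2)/n_eff)
        se = np.sqrt((1 - rho**2) / (n * (1 - rho) / (1 + rho)))
        assert np.abs(model.eigenvalues[0] - rho) < 3 * se

    def test_slow_mode_alignment(self):
        n = 100_000
        rng = np.random.default_rng(2)
        slow = _ar1(n, 0.95, seed=3)[:, 0]
        fast = _ar1(n, 0.5, seed=4)[:, 0]
        x = np.stack([slow, fast], axis=1)
        model = msm.tica_fit(x, lag=1)
        v = model.eigenvectors[:, 0]
        cos = np.abs(v[0]) / np.linalg.norm(v)
        assert cos > 0.99

    def test_eigenvalues_bounded(self):
        x = _ar1(20_000, 0.8, seed=5, d_noise=2)
        model = msm.tica_fit(x, lag=2)
        assert np.all(np.abs(model.eigenvalues) <= 1.0 + 1e-6)

    def test_too_short_error(self):
        with pytest.raises(ValueError):
            msm.tica_fit(np.zeros((3, 2)), lag=5)


class TestVamp2:
    def test_constant_only(self):
        m = msm.TicaModel(lag=1, mean=np.zeros(2), eigenvalues=np.array([0.9, 0.5]),
                          eigenvectors=np.eye(2))
        assert msm.vamp2_score(m, 0) == 1.0

    def test_direct_sum(self):
        m = msm.TicaModel(lag=1, mean=np.zeros(2), eigenvalues=np.array([0.9, 0.5]),
                          eigenvectors=np.eye(2))
        assert msm.vamp2_score(m, 2) == pytest.approx(1 + 0.81 + 0.25)

    def test_nondecreasing_in_n(self):
        x = _ar1(30_000, 0.9, seed=6, d_noise=3)
        model = msm.tica_fit(x, lag=1)
        scores = [msm.vamp2_score(model, k) for k in range(5)]
        assert np.all(np.diff(scores) >= -1e-12)

    def test_white_noise_score_near_one(self):
        x = np.random.default_rng(7).standard_normal((50_000, 2))
        model = msm.tica_fit(x, lag=1)
        assert msm.vamp2_score(model, 2) == pytest.approx(1.0, abs=0.01)


class TestFes:
    def _model_identity(self):
        return msm.TicaModel(lag=1, mean=np.zeros(2),
                             eigenvalues=np.array([1.0, 1.0]),
                             eigenvectors=np.eye(2), n_components=2)

    def test_uniform_density_flat(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, size=(200_000, 2))
        fes = msm.project_fes(x, self._model_identity(), kT=1.0, bins=4)
        assert np.nanmax(np.where(np.isfinite(fes.f), fes.f, np.nan)) < 0.1

    def test_two_bin_ratio_e2(self):
        # densities in ratio e^2 -> free-energy gap of exactly 2 kT
        n1, n2 = 100_000, int(100_000 / np.e**2)
        a = np.full((n1, 2), 0.25)
        b = np.full((n2, 2), 0.75)
        x = np.vstack([a, b])
        fes = msm.project_fes(x, self._model_identity(), kT=1.0, bins=2)
        vals = np.sort(fes.f[np.isfinite(fes.f)])
        assert vals[0] == pytest.approx(0.0)
        # integer truncation of n2 perturbs the ratio by ~1e-5
        assert vals[1] == pytest.approx(2.0, abs=1e-3)

    def test_three_well_basins(self):
        # FAST-style coverage of the three-well landscape shows 3 basins
        from crypticsite.sampling import FastConfig, ToyEngine, run_fast

        engine = ToyEngine()
        arch = run_fast(engine, np.zeros(2),
                        FastConfig(n_generations=10, sims_per_generation=10,
                                   sim_length=400, stride=5, seed=2))
        model = msm.tica_fit(arch.features, lag=2)
        fes = msm.project_fes(arch.features, model, kT=1.0, bins=30)
        assert msm.count_basins(fes, max_f=3.0) >= 3

    def test_degenerate_surface_warns(self):
        x = np.zeros((100, 2))
        with pytest.warns(UserWarning, match="degenerate"):
            msm.project_fes(x, self._model_identity(), bins=3)


class TestRecovery:
    def test_five_state_chain_pi_and_timescale(self):
        # trajectories from a known reversible 5-state chain: pi recovered
        # with L1 error < 0.02 and the slowest timescale within 10%
        rng = np.random.default_rng(23)
        w = rng.random((5, 5)) * 0.08
        w = (w + w.T) / 2
        t = w.copy()
        np.fill_diagonal(t, 0)
        np.fill_diagonal(t, 1 - t.sum(axis=1))
        pi_true = np.full(5, 0.2)       # symmetric t -> uniform pi
        labels = _sample_chain(t, 100_000, seed=29)
        c = msm.count_transitions([labels], lag=1, n_states=5)
        m = msm.estimate_reversible_tpm(c)
        assert np.abs(m.stationary - pi_true).sum() < 0.02
        lam = np.sort(np.linalg.eigvals(t).real)[-2]
        analytic = -1.0 / np.log(lam)
        est = msm.implied_timescales([labels], lags=[1], n_states=5,
                                     n_timescales=1)["timescale"].iloc[0]
        assert est == pytest.approx(analytic, rel=0.10)
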