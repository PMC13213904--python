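import numpy as np
import pytest
from scipy.optimize import minimize

from metastate import markov, msm, synthetic


def brute_force_reversible_mle(C):
    """Independent oracle: direct likelihood maximization over symmetric x."""
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    iu = np.triu_indices(n)

    def unpack(v):
        x = np.zeros((n, n))
        x[iu] = np.exp(v)
        return x + x.T - np.diag(np.diag(x))

    def negll(v):
        x = unpack(v)
        return -(C * (np.log(x) - np.log(x.sum(axis=1))[:, None])).sum()

    res = minimize(negll, np.zeros(len(iu[0])), method="L-BFGS-B",
                   options={"maxiter": 50_000, "ftol": 1e-16, "gtol": 1e-12})
    x = unpack(res.x)
    return x / x.sum(axis=1, keepdims=True)


def simulate_dtraj(T, n_steps, seed, start=0):
    rng = np.random.default_rng(seed)
    cum = np.cumsum(T, axis=1)
    u = rng.random(n_steps)
    d = np.empty(n_steps, dtype=int)
    d[0] = start
    for t in range(1, n_steps):
        d[t] = np.searchsorted(cum[d[t - 1]], u[t])
    return d


class TestClusterKmeans:
    def test_k_equals_distinct_points_zero_inertia(self):
        pts = np.repeat(np.arange(5, dtype=float)[:, None], 2, axis=1)
        data = np.repeat(pts, 10, axis=0)
        disc = msm.cluster_kmeans(data, k=5, seed=0)
        assert disc.inertia == pytest.approx(0.0, abs=1e-20)

    def test_two_blob_centers(self):
        rng = np.random.default_rng(1)
        a = rng.normal([0, 0], 0.5, size=(2000, 2))
        b = rng.normal([10, 10], 0.5, size=(2000, 2))
        disc = msm.cluster_kmeans(np.vstack([a, b]), k=2, seed=0)
        centers = disc.centers[np.argsort(disc.centers[:, 0])]
        se = 0.5 / np.sqrt(2000)
        assert np.all(np.abs(centers[0] - [0, 0]) < 3 * se)
        assert np.all(np.abs(centers[1] - [10, 10]) < 3 * se)

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((5000, 3))
        d1 = msm.cluster_kmeans(data, k=10, seed=5)
        d2 = msm.cluster_kmeans(data, k=10, seed=5)
        assert np.array_equal(d1.dtrajs[0], d2.dtrajs[0])

    def test_k_exceeds_distinct_points_raises(self):
        data = np.zeros((100, 2))
        with pytest.raises(ValueError):
            msm.cluster_kmeans(data, k=5, seed=0)


class TestCountTransitions:
    def test_hand_counted_lag_one(self):
        cm = msm.count_transitions([np.array([0, 1, 0, 1, 0])], 1)
        assert cm.C[0, 1] == 2 and cm.C[1, 0] == 2
        assert cm.C[0, 0] == 0 and cm.C[1, 1] == 0

    def test_hand_counted_lag_two(self):
        cm = msm.count_transitions([np.array([0, 1, 0, 1, 0])], 2)
        assert cm.C[0, 0] == 2 and cm.C[1, 1] == 1

    def test_strided_mode(self):
        cm = msm.count_transitions([np.array([0, 1, 0, 1, 0])], 2, mode="strided")
        # pairs (0,2) and (2,4) only
        assert cm.C.sum() == 2 and cm.C[0, 0] == 2

    def test_dead_end_state_trimmed(self):
        d = np.array([0, 1, 0, 1, 2])   # state 2 visited once, never left
        cm = msm.count_transitions([d], 1, trim=True)
        assert 2 not in cm.active_set
        assert set(cm.active_set) == {0, 1}

    def test_bad_lag_raises(self):
        with pytest.raises(ValueError):
            msm.count_transitions([np.array([0, 1])], 5)


class TestReversibleMLE:
    def test_symmetric_counts_closed_form(self):
        C = np.array([[10, 4, 2], [4, 8, 6], [2, 6, 12]], dtype=float)
        cm = msm.CountMatrix(C=C, lag_frames=1, frame_interval_ns=1.0,
                             mode="sliding", active_set=np.arange(3))
        model = msm.estimate_reversible(cm)
        expected = C / C.sum(axis=1, keepdims=True)
        assert np.allclose(model.T, expected, atol=1e-10)

    def test_against_brute_force_oracle(self):
        C = np.array([[8, 2], [1, 9]], dtype=float)
        T, _ = msm.reversible_mle(C)
        assert np.allclose(T, brute_force_reversible_mle(C), atol=1e-8)

    @pytest.mark.parametrize("seed", range(4))
    def test_detailed_balance_residual(self, seed):
        rng = np.random.default_rng(seed)
        C = rng.integers(1, 100, size=(5, 5)).astype(float)
        T, pi = msm.reversible_mle(C)
        assert markov.detailed_balance_residual(T, pi) < 1e-8
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(pi @ T, pi, atol=1e-10)


class TestImpliedTimescales:
    def test_formula(self):
        lam = np.exp(-1.0)
        T = np.array([[1 - (1 - lam) / 2, (1 - lam) / 2],
                      [(1 - lam) / 2, 1 - (1 - lam) / 2]])
        m = msm.MarkovModel(T=T, pi=np.array([0.5, 0.5]), lag_ns=10.0)
        assert m.timescales_ns(1)[0] == pytest.approx(10.0, rel=1e-12)

    def test_flat_in_lag_for_exact_chain(self):
        T = np.array([[0.95, 0.05], [0.10, 0.90]])
        d = simulate_dtraj(T, 200_000, seed=0)
        its = np.array([msm.estimate_reversible(msm.count_transitions([d], lag))
                        .timescales_ns(1)[0] for lag in (1, 2, 5, 10)])
        assert np.all(np.abs(its - its[0]) / its[0] < 0.1)

    def test_negative_eigenvalue_flagged(self):
        T = np.array([[0.1, 0.9], [0.9, 0.1]])   # lambda2 = -0.8
        m = msm.MarkovModel(T=T, pi=np.array([0.5, 0.5]), lag_ns=1.0)
        assert np.isnan(m.timescales_ns(1)[0])
        df = msm.implied_timescales([m], n=1)
        assert np.isnan(df.loc[0, "t1_ns"])


@pytest.fixture(scope="module")
def counts():
    T = np.array([[0.9, 0.1], [0.2, 0.8]])
    d = simulate_dtraj(T, 50_000, seed=3)
    return msm.count_transitions([d], 1)


class TestPosteriorSampling:

    def test_every_sample_detailed_balanced(self, counts):
        ens = msm.sample_posterior(counts, n_samples=20, seed=0)
        for m in ens.models:
            assert markov.detailed_balance_residual(m.T, m.pi) < 1e-8
            assert np.allclose(m.T.sum(axis=1), 1.0, atol=1e-12)

    def test_posterior_mean_near_mle_at_large_counts(self, counts):
        mle = msm.estimate_reversible(counts)
        ens = msm.sample_posterior(counts, n_samples=100, seed=1)
        Ts = np.array([m.T for m in ens.models])
        sd = Ts.std(axis=0)
        assert np.all(np.abs(Ts.mean(axis=0) - mle.T) < 3 * sd + 1e-12)

    def test_seed_reproducibility(self, counts):
        a = msm.sample_posterior(counts, n_samples=5, seed=42)
        b = msm.sample_posterior(counts, n_samples=5, seed=42)
        for ma, mb in zip(a.models, b.models):
            assert np.array_equal(ma.T, mb.T)


class TestCoarseGrain:
    def test_two_block_memberships(self):
        T = np.full((4, 4), 0.005)
        for i, j in ((0, 1), (1, 0), (2, 3), (3, 2)):
            T[i, j] = 0.495
        np.fill_diagonal(T, 0)
        np.fill_diagonal(T, 1 - T.sum(axis=1))
        d = simulate_dtraj(T, 100_000, seed=1)
        cm = msm.count_transitions([d], 1)
        micro = msm.estimate_reversible(cm)
        mac = msm.coarse_grain([d], micro, n_macro=2, lag_frames=1)
        crisp = mac.micro_to_macro()
        # states {0,1} and {2,3} must land in different macrostates
        assert crisp[0] == crisp[1] and crisp[2] == crisp[3]
        assert crisp[0] != crisp[2]
        assert np.all(np.max(mac.memberships, axis=1) > 0.95)

    def test_identity_coarse_graining(self, generator_run):
        micro = generator_run["micro"]
        mac = msm.coarse_grain(generator_run["disc"].dtrajs, micro,
                               n_macro=micro.n_states)
        assert np.allclose(mac.T_macro, micro.T)
        assert np.allclose(mac.memberships, np.eye(micro.n_states))

    def test_generator_population_recovery(self, generator_run, macro_truth_map):
        run = generator_run
        pi_est = run["macro"].pi_macro
        chain = run["chain"]
        # macro-level posterior CI from the assigned macro trajectories
        macro_d = msm.assign_macro_dtrajs(run["macro"], run["disc"].dtrajs)
        cm = msm.count_transitions(macro_d, run["lag_frames"],
                                   frame_interval_ns=chain.step_ns)
        ens = msm.sample_posterior(cm, n_samples=100, seed=0)
        pis = ens.collect(lambda m: m.pi)
        for truth_state in range(6):
            est_state = macro_truth_map[truth_state]
            lo, hi = np.percentile(pis[:, est_state], [0.5, 99.5])
            width = max(hi - lo, 0.02)
            assert lo - width <= chain.pi[truth_state] <= hi + width, \
                f"state {truth_state}: pi={chain.pi[truth_state]} CI=({lo},{hi})"
        del pi_est

    def test_membership_rows_sum_to_one(self, generator_run):
        chi = generator_run["macro"].memberships
        assert np.allclose(chi.sum(axis=1), 1.0, atol=1e-8)
        assert np.all((chi >= 0) & (chi <= 1 + 1e-12))


class TestCKTest:
    def test_exact_macro_chain_passes(self, generator_run):
        res = msm.ck_test(generator_run["macro"], generator_run["disc"].dtrajs,
                          generator_run["lag_frames"], multiples=(2, 3, 4, 5))
        ok = res.table[res.table["status"] != "indeterminate"]
        assert res.passed, res.table[ok["status"] == "fail"]

    def test_k_one_identity(self, generator_run):
        res = msm.ck_test(generator_run["macro"], generator_run["disc"].dtrajs,
                          generator_run["lag_frames"], multiples=(1,))
        t = res.table
        # at k=1 prediction and re-estimation use the same count statistics
        assert np.allclose(t["predicted"], t["estimated"], atol=0.05)

    def test_underresolved_model_fails(self):
        # deliberately lump two basins with very different exit rates: the
        # merged state's residence decay is strongly non-exponential, so the
        # one-step macro matrix cannot predict residence at larger multiples
        T = np.array([
            [0.970, 0.030, 0.000],
            [0.015, 0.980, 0.005],
            [0.000, 0.002, 0.998]])
        T = T / T.sum(axis=1, keepdims=True)
        d = simulate_dtraj(T, 500_000, seed=7)
        cm = msm.count_transitions([d], 1)
        micro = msm.estimate_reversible(cm)
        chi = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        Tm = msm._coarse_grain_T(micro.T, micro.pi, chi)
        emission = (chi * micro.pi[:, None]).T
        emission /= emission.sum(axis=1, keepdims=True)
        mac = msm.MacrostateModel(
            n_macro=2, T_macro=Tm, pi_macro=markov.stationary_distribution(Tm),
            memberships=chi, emission=emission, lag_ns=1.0,
            active_set=cm.active_set)
        res = msm.ck_test(mac, [d], lag_frames=1, multiples=(20, 50, 100, 200))
        assert not res.passed


class TestMFPT:
    def test_two_state_geometric_dwell(self):
        T = np.array([[0.9, 0.1], [0.5, 0.5]])
        m = msm.MarkovModel(T=T, pi=markov.stationary_distribution(T), lag_ns=10.0)
        assert m.mfpt_ns([0], [1]) == pytest.approx(100.0, rel=1e-10)

    def test_mfpt_a_to_a_is_zero(self):
        T = np.array([[0.9, 0.1], [0.5, 0.5]])
        m = msm.MarkovModel(T=T, pi=markov.stationary_distribution(T), lag_ns=10.0)
        assert m.mfpt_ns([0], [0]) == 0.0

    def test_against_monte_carlo_oracle(self):
        T = np.array([[0.90, 0.08, 0.02],
                      [0.05, 0.90, 0.05],
                      [0.03, 0.07, 0.90]])
        m = msm.MarkovModel(T=T, pi=markov.stationary_distribution(T), lag_ns=1.0)
        analytic = m.mfpt_ns([0], [2])
        rng = np.random.default_rng(0)
        n_walkers = 100_000
        state = np.zeros(n_walkers, dtype=int)
        steps = np.zeros(n_walkers)
        alive = np.ones(n_walkers, dtype=bool)
        cum = np.cumsum(T, axis=1)
        t = 0
        while alive.any() and t < 10_000:
            t += 1
            u = rng.random(alive.sum())
            idx = np.flatnonzero(alive)
            nxt = np.array([np.searchsorted(cum[s], uu)
                            for s, uu in zip(state[idx], u)])
            state[idx] = nxt
            absorbed = nxt == 2
            steps[idx[absorbed]] = t
            alive[idx[absorbed]] = False
        assert analytic == pytest.approx(steps.mean(), rel=0.02)

    def test_unreachable_returns_inf(self):
        T = np.array([[1.0, 0.0], [0.5, 0.5]])
        m = msm.MarkovModel(T=T, pi=np.array([1.0, 0.0]), lag_ns=1.0)
        assert m.mfpt_ns([1], [0]) < np.inf     # reachable direction
        assert np.isinf(m.mfpt_ns([0], [1]))    # absorbing state 0


class TestKineticSummaries:
    def test_lifetime_formula(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        mac = msm.MacrostateModel(n_macro=2, T_macro=T, pi_macro=np.array([0.5, 0.5]),
                                  memberships=np.eye(2), emission=np.eye(2),
                                  lag_ns=10.0, active_set=np.arange(2))
        assert mac.lifetimes_ns()[0] == pytest.approx(100.0)

    def test_gmm_single_gaussian(self):
        rng = np.random.default_rng(0)
        hits = 0
        for rep in range(10):
            samples = rng.normal(5.0, 0.3, size=300)
            g = msm.gmm_summary(samples, seed=rep)
            se = 0.3 / np.sqrt(300)
            assert abs(g.mean - 5.0) < 4 * se
            hits += g.n_components == 1
        assert hits >= 9

    def test_generator_lifetime_recovery(self, generator_run, macro_truth_map):
        run = generator_run
        chain = run["chain"]
        macro_d = msm.assign_macro_dtrajs(run["macro"], run["disc"].dtrajs)
        cm = msm.count_transitions(macro_d, run["lag_frames"],
                                   frame_interval_ns=chain.step_ns)
        ens = msm.sample_posterior(cm, n_samples=100, seed=3)
        summary = msm.summarize_kinetics(ens, run["macro"])
        # the geometric lifetime at lag tau targets tau / (1 - (T^tau)_ii);
        # compute that analytic value from the generator as the oracle. The
        # honest uncertainty scale is set by the number of independent dwell
        # episodes, not by the (autocorrelated) sliding-count volume.
        tau = run["lag_frames"] * chain.step_ns
        T_lag = np.linalg.matrix_power(chain.T, run["lag_frames"])
        life_at_lag = tau / (1.0 - np.diag(T_lag))
        all_truth = np.concatenate(run["hidden"])
        for truth_state in range(6):
            est_state = macro_truth_map[truth_state]
            row = summary.lifetimes.loc[summary.lifetimes["state"] == est_state].iloc[0]
            n_frames = int(np.sum(all_truth == truth_state))
            dwell_steps = 1.0 / (1.0 - chain.T[truth_state, truth_state])
            n_episodes = max(n_frames / dwell_steps, 1.0)
            band = 4.0 * life_at_lag[truth_state] / np.sqrt(n_episodes)
            err = abs(row["posterior_mean"] - life_at_lag[truth_state])
            assert err <= band, \
                f"state {truth_state}: |{row['posterior_mean']:.1f} - " \
                f"{life_at_lag[truth_state]:.1f}| > {band:.1f}"
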