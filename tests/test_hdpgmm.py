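"""Collapsed HDP machinery against quadrature, closed-form and stub oracles."""

import math

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import invgamma, kstest, norm

from fhrhdp import hdpgmm as hd


# ---------------------------------------------------------------------------
# Independent quadrature oracle (1-D Normal-Inverse-Gamma base measure)

def predictive_by_quadrature(x, prior, data=()):
    """f(x | data) via direct 2-D grid integration over (mean, variance).

    Integrates prior x likelihood on a dense grid; completely independent of
    the closed-form Student-t path under test.
    """
    from scipy.integrate import simpson

    mu0, k0, nu0, psi0 = (prior.mu0[0], prior.kappa0, prior.nu0,
                          prior.psi0[0, 0])
    # log-variance grid (mass below 5e-4 is ~exp(-750), safely negligible)
    # and a mean grid scaled to the conditional prior sd sqrt(s2/k0), so the
    # integrand stays resolved at every variance
    t = np.linspace(math.log(5e-4), math.log(1e7), 3001)
    s2 = np.exp(t)
    z = np.linspace(-14.0, 14.0, 3001)
    S2, Z = np.meshgrid(s2, z, indexing="ij")
    MU = mu0 + np.sqrt(S2 / k0) * Z
    dens = invgamma.pdf(S2, a=nu0 / 2.0, scale=psi0 / 2.0) * norm.pdf(Z)
    lik = np.ones_like(dens)
    for d in data:
        lik = lik * norm.pdf(d, loc=MU, scale=np.sqrt(S2))

    def integrate(f):
        return simpson(simpson(f, x=z, axis=1) * s2, x=t)

    num = integrate(dens * lik * norm.pdf(x, loc=MU, scale=np.sqrt(S2)))
    den = integrate(dens * lik)
    return num / den


def stats_from(data, q=1):
    st = hd.GaussianComponentStats(q)
    for d in np.atleast_2d(np.asarray(data, dtype=float).reshape(-1, q)):
        st.add(d)
    return st


class TestPredictiveDensities:
    def test_empty_stats_equals_prior_predictive(self, scalar_prior):
        x = np.array([0.3])
        empty = hd.GaussianComponentStats(1)
        assert hd.log_posterior_predictive(x, empty, scalar_prior) == \
            hd.log_prior_predictive(x, scalar_prior)

    @pytest.mark.parametrize("x", [-0.7, 0.5, 1.9])
    def test_prior_predictive_matches_quadrature(self, scalar_prior, x):
        dens = math.exp(hd.log_prior_predictive(np.array([x]), scalar_prior))
        assert dens == pytest.approx(predictive_by_quadrature(x, scalar_prior),
                                     abs=1e-6)

    @pytest.mark.parametrize("x", [-0.5, 0.4, 1.2])
    def test_posterior_predictive_matches_quadrature(self, scalar_prior, x):
        data = [0.2, 1.1, -0.4]
        dens = math.exp(hd.log_posterior_predictive(
            np.array([x]), stats_from(data), scalar_prior))
        assert dens == pytest.approx(
            predictive_by_quadrature(x, scalar_prior, data), abs=1e-6)

    def test_exclude_gives_leave_one_out(self, scalar_prior):
        data = [0.2, 1.1, -0.4]
        loo = hd.log_posterior_predictive(
            np.array([0.4]), stats_from(data), scalar_prior,
            exclude=np.array([1.1]))
        direct = hd.log_posterior_predictive(
            np.array([0.4]), stats_from([0.2, -0.4]), scalar_prior)
        assert loo == pytest.approx(direct, abs=1e-10)

    def test_prior_predictive_is_symmetric_and_normalized(self, scalar_prior):
        delta = 0.8
        lo = hd.log_prior_predictive(np.array([0.5 - delta]), scalar_prior)
        hi = hd.log_prior_predictive(np.array([0.5 + delta]), scalar_prior)
        assert lo == pytest.approx(hi, abs=1e-12)
        grid = np.linspace(-60, 61, 20001)
        dens = np.exp([hd.log_prior_predictive(np.array([g]), scalar_prior)
                       for g in grid])
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-4)

    def test_predictive_converges_to_generating_gaussian(self, scalar_prior,
                                                         rng):
        mu_star, sd_star = 2.0, 0.5
        st = stats_from(mu_star + sd_star * rng.standard_normal(10_000))
        grid = np.linspace(mu_star - 5 * sd_star, mu_star + 5 * sd_star, 1500)
        logp = np.array([hd.log_posterior_predictive(np.array([g]), st,
                                                     scalar_prior)
                         for g in grid])
        logq = norm.logpdf(grid, mu_star, sd_star)
        q = np.exp(logq)
        kl = np.trapezoid(q * (logq - logp), grid)
        assert kl < 1e-3

    def test_block_predictive_is_chain_of_conditionals(self, scalar_prior):
        X = np.array([[0.3], [0.9]])
        chain = (hd.log_prior_predictive(X[0], scalar_prior)
                 + hd.log_posterior_predictive(X[1], stats_from([0.3]),
                                               scalar_prior))
        assert hd.log_block_predictive(X, None, scalar_prior) == \
            pytest.approx(chain, abs=1e-12)
        # and the joint matches 2-D quadrature of the joint integral
        dens_joint = predictive_by_quadrature(0.9, scalar_prior, data=[0.3]) \
            * predictive_by_quadrature(0.3, scalar_prior)
        assert math.exp(hd.log_block_predictive(X, None, scalar_prior)) == \
            pytest.approx(dens_joint, abs=1e-6)

    def test_dimension_mismatch_raises(self, scalar_prior):
        with pytest.raises(ValueError, match="dimension"):
            hd.log_prior_predictive(np.array([0.1, 0.2]), scalar_prior)


class TestStatsBookkeeping:
    def test_remove_then_add_restores(self, rng):
        st = stats_from(rng.standard_normal((20, 2)), q=2)
        before = (st.n, st.sum.copy(), st.sumsq.copy())
        x = np.array([0.7, -1.2])
        st.add(x)
        st.remove(x)
        assert st.n == before[0]
        assert np.allclose(st.sum, before[1], atol=1e-12)
        assert np.allclose(st.sumsq, before[2], atol=1e-12)

    def test_remove_from_empty_raises(self):
        with pytest.raises(ValueError):
            hd.GaussianComponentStats(1).remove(np.array([1.0]))


class TestSeatingArithmetic:
    def test_table_prior_odds(self):
        # one table of 4 customers, alpha = 1, likelihoods stubbed equal
        probs = hd.seating_probabilities([4], [0.0], 1.0, 0.0)
        assert probs == pytest.approx([0.8, 0.2])

    def test_dish_prior_odds(self):
        # one dish on 3 tables, gamma = 1, likelihoods stubbed equal
        probs = hd.dish_probabilities([3], [0.0], 1.0, 0.0)
        assert probs == pytest.approx([0.75, 0.25])

    def test_empirical_frequency_matches(self, rng):
        probs = hd.seating_probabilities([4], [0.0], 1.0, 0.0)
        draws = np.array([hd.categorical_from_logweights(np.log(probs), rng)
                          for _ in range(100_000)])
        freq = np.mean(draws == 0)
        sigma = math.sqrt(0.8 * 0.2 / 100_000)
        assert abs(freq - 0.8) < 3 * sigma

    def test_empty_franchise_seats_new_table_new_dish(self, scalar_prior, rng):
        state = hd.FranchiseState(scalar_prior)
        state.add_restaurant("j0")
        state.seat_customer("j0", np.array([0.1]), hd.Concentrations(), rng)
        assert state.K == 1
        assert len(state.restaurants["j0"].tables) == 1
        state.check_invariants()


class TestFranchiseState:
    @pytest.fixture
    def small_state(self, scalar_prior, rng):
        state = hd.FranchiseState(scalar_prior)
        conc = hd.Concentrations()
        data = {"j0": rng.standard_normal((6, 1)),
                "j1": rng.standard_normal((5, 1)) + 4.0}
        for j, X in data.items():
            state.add_restaurant(j)
            for x in X:
                state.seat_customer(j, x, conc, rng)
        return state, conc

    def test_detach_attach_symmetry(self, scalar_prior, rng):
        # build a table with several customers explicitly, then remove and
        # re-add one: every count and sufficient statistic must be restored
        state = hd.FranchiseState(scalar_prior)
        conc = hd.Concentrations()
        state.add_restaurant("j0")
        first = state.seat_customer("j0", np.array([0.2]), conc, rng)
        rest = state.restaurants["j0"]
        table_id = rest.assignment[first]
        cids = [first]
        for v in (0.5, -0.1, 0.3):
            cid = state._next_cid
            state._next_cid += 1
            rest.customers[cid] = np.array([v])
            rest.order.append(cid)
            state._attach("j0", cid, np.array([v]), table_id)
            cids.append(cid)
        dish = rest.tables[table_id].dish
        n_before = state.dishes[dish].stats.n
        sum_before = state.dishes[dish].stats.sum.copy()
        sumsq_before = state.dishes[dish].stats.sumsq.copy()
        cid = cids[1]
        x = state.detach("j0", cid)
        state._attach("j0", cid, x, table_id)
        assert rest.assignment[cid] == table_id
        assert state.dishes[dish].stats.n == n_before
        assert np.allclose(state.dishes[dish].stats.sum, sum_before,
                           atol=1e-12)
        assert np.allclose(state.dishes[dish].stats.sumsq, sumsq_before,
                           atol=1e-12)
        state.check_invariants()

    def test_invariants_hold_through_sweeps(self, small_state, rng):
        state, conc = small_state
        for _ in range(10):
            conc = hd.gibbs_sweep(state, conc, rng)
            state.check_invariants()

    def test_well_separated_table_keeps_its_dish(self, scalar_prior, rng):
        # two dishes 10 sigma apart; a table holding dish-A data must re-pick A
        state = hd.FranchiseState(scalar_prior)
        conc = hd.Concentrations(alpha=1.0, gamma=1.0, frozen=True)
        state.add_restaurant("j0")
        for x in np.concatenate([rng.standard_normal(15) * 0.3,
                                 rng.standard_normal(15) * 0.3 + 10.0]):
            state.seat_customer("j0", np.array([x]), conc, rng)
        for _ in range(20):
            conc = hd.gibbs_sweep(state, conc, rng)
        # every table whose customers all sit in the low cluster must keep
        # re-picking a low-mean dish, never the 10-sigma-distant one
        rest = state.restaurants["j0"]
        picks = []
        for table_id, table in list(rest.tables.items()):
            xs = [rest.customers[c][0] for c in table.customers]
            if max(xs) < 5.0 and len(xs) >= 3:
                hits = 0
                for _ in range(50):
                    state.resample_dish("j0", table_id, conc, rng)
                    st = state.dishes[rest.tables[table_id].dish].stats
                    hits += (st.sum[0] / st.n) < 5.0
                picks.append(hits / 50)
        assert picks and min(picks) > 0.99


class TestConcentrationSamplers:
    def test_prior_only_draws_match_gamma_moments(self, rng):
        g = [hd.sample_gamma_concentration(1.0, 0, 0, (1.0, 1.0), rng)
             for _ in range(10_000)]
        assert abs(np.mean(g) - 1.0) < 3.0 * 1.0 / 100.0
        a = [hd.sample_alpha_concentration(1.0, [], 0, (10.0, 1.0), rng)
             for _ in range(10_000)]
        assert abs(np.mean(a) - 10.0) < 3.0 * math.sqrt(10.0) / 100.0

    def test_gamma_chain_matches_grid_posterior(self, rng):
        K, m_total, prior = 3, 10, (1.0, 1.0)
        grid = np.linspace(1e-4, 30.0, 4000)
        logp = ((prior[0] - 1) * np.log(grid) - prior[1] * grid
                + K * np.log(grid) + gammaln(grid) - gammaln(grid + m_total))
        p = np.exp(logp - logp.max())
        p /= np.trapezoid(p, grid)
        target_mean = np.trapezoid(grid * p, grid)
        gamma, draws = 1.0, []
        for _ in range(20_000):
            gamma = hd.sample_gamma_concentration(gamma, K, m_total, prior,
                                                  rng)
            draws.append(gamma)
        draws = np.array(draws[1000:])
        n_eff = draws.size / 10.0  # generous autocorrelation allowance
        mc_err = 3.0 * draws.std() / math.sqrt(n_eff)
        assert abs(draws.mean() - target_mean) < mc_err

    def test_alpha_chain_matches_grid_cdf(self, rng):
        n, m, prior = 20, 4, (10.0, 1.0)
        grid = np.linspace(1e-4, 60.0, 8000)
        logp = ((prior[0] - 1) * np.log(grid) - prior[1] * grid
                + m * np.log(grid) + gammaln(grid) - gammaln(grid + n))
        p = np.exp(logp - logp.max())
        cdf = np.cumsum(p)
        cdf /= cdf[-1]
        alpha, draws = 1.0, []
        for _ in range(50_000):
            alpha = hd.sample_alpha_concentration(alpha, [n], m, prior, rng)
            draws.append(alpha)
        thinned = np.array(draws[1000::5])[:10_000]
        stat = kstest(thinned, lambda v: np.interp(v, grid, cdf))
        assert stat.pvalue > 0.01


class TestFitAndPredict:
    def test_single_observation_stays_single_cluster(self, scalar_prior, rng):
        model = hd.fit_hdpgm({"j0": np.array([[0.5]])}, prior=scalar_prior,
                             settings=hd.SamplerSettings(20, 10, 2), seed=0)
        assert all(len(ps.dish_stats) == 1 for ps in model.states)
        assert all(ps.m_counts.sum() == 1 for ps in model.states)

    def test_total_is_sum_of_per_segment(self, scalar_prior, rng):
        model = hd.fit_hdpgm({"j0": rng.standard_normal((12, 1))},
                             prior=scalar_prior,
                             settings=hd.SamplerSettings(20, 10, 2), seed=1)
        X = rng.standard_normal((7, 1))
        total, per = hd.log_predictive_recording(X, model)
        assert total == pytest.approx(per.sum(), rel=1e-12)

    def test_central_point_more_likely_than_outlier(self, rng):
        data = {"j0": rng.standard_normal((40, 1)),
                "j1": rng.standard_normal((40, 1))}
        model = hd.fit_hdpgm(data, settings=hd.SamplerSettings(40, 20, 4),
                             seed=2)
        t0, _ = hd.log_predictive_recording(np.array([[0.0]]), model)
        t10, _ = hd.log_predictive_recording(np.array([[10.0]]), model)
        assert t0 > t10

    def test_dominant_dish_predictive_close_to_component(self, scalar_prior,
                                                         rng):
        st = stats_from(0.1 * rng.standard_normal(200), q=1)
        ps = hd.PosteriorState(dish_stats=[st], m_counts=np.array([50.0]),
                               alpha=1.0, gamma=0.01)
        model = hd.TrainedModel(states=[ps], prior=scalar_prior,
                                settings=hd.SamplerSettings(1, 0, 1), seed=0)
        x = np.array([[0.0]])
        _, per = hd.log_predictive_recording(x, model)
        direct = hd.log_posterior_predictive(x[0], st, scalar_prior)
        assert abs(per[0] - direct) < 0.05

    def test_model_json_roundtrip(self, rng):
        data = {"j0": rng.standard_normal((10, 2)),
                "j1": rng.standard_normal((10, 2)) + 3.0}
        model = hd.fit_hdpgm(data, settings=hd.SamplerSettings(10, 5, 1),
                             seed=3)
        model2 = hd.model_from_json(hd.model_to_json(model))
        X = rng.standard_normal((4, 2))
        assert np.allclose(hd.log_predictive_recording(X, model)[1],
                           hd.log_predictive_recording(X, model2)[1])

    def test_rng_required_shape(self, scalar_prior):
        with pytest.raises(ValueError, match="no data"):
            hd.fit_hdpgm({}, prior=scalar_prior)
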