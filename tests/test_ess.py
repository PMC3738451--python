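import numpy as np
import pytest
from scipy import stats

from essbvs import DataBundle, log_posterior, make_size_prior
from essbvs.ess import (
    SamplerConfig,
    crossover_move,
    exchange_move,
    fsmh_sweep,
    init_sampler,
    run,
    tune_temperature_ladder,
    update_g,
)
from essbvs.priors import GPriorSpec, ModelIndicator


def tiny_cfg(**kw):
    base = dict(n_sweeps=300, burn_in=50, n_chains=3, seed=11)
    base.update(kw)
    return SamplerConfig(**base)


class TestInitSampler:
    def test_seed_determinism(self, toy_bundle):
        data, sp, gp = toy_bundle
        a = init_sampler(tiny_cfg(), data, sp, gp)
        b = init_sampler(tiny_cfg(), data, sp, gp)
        for ca, cb in zip(a.chains, b.chains):
            assert ca.order == cb.order and ca.g == cb.g

    def test_initial_sizes_within_truncation(self, toy_bundle):
        data, sp, gp = toy_bundle
        for seed in range(300):
            st_ = init_sampler(tiny_cfg(seed=seed), data, sp, gp)
            assert all(c.size <= sp.T for c in st_.chains)

    def test_initial_size_matches_prior_mean(self):
        # wider panel so the truncated mean is essentially E
        rng = np.random.default_rng(0)
        n, p = 60, 40
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, 1))
        data = DataBundle(Y - Y.mean(0), X, c_eff=1)
        sp = make_size_prior(3.0, 2.5, 7, p)
        sizes = []
        for seed in range(2000):
            st_ = init_sampler(tiny_cfg(seed=seed, n_chains=1), data, sp, GPriorSpec(n))
            sizes.append(st_.chains[0].size)
        se = np.std(sizes) / np.sqrt(len(sizes))
        assert np.mean(sizes) == pytest.approx(3.0, abs=3 * se + 0.05)

    def test_truncation_vs_degrees_of_freedom_guard(self, toy_bundle):
        data, sp, gp = toy_bundle
        bad = make_size_prior(3.0, 1.8, 20, data.p)  # T = 39 > n - c_eff - q = 37
        with pytest.raises(ValueError, match="degrees of freedom"):
            init_sampler(tiny_cfg(), data, bad, gp)


class TestFsmhSweep:
    def test_single_snp_acceptance_probability(self):
        """p=1 toy: empirical add-acceptance from the empty model matches
        the hand-computed MH probability min(1, exp(delta log posterior))."""
        rng = np.random.default_rng(3)
        n = 30
        X = rng.standard_normal((n, 1))
        Y = (0.4 * X[:, 0] + rng.standard_normal(n))[:, None]
        data = DataBundle(Y - Y.mean(0), X, c_eff=1)
        # p=1 admits no overdispersion: binomial-limit prior
        sp = make_size_prior(0.3, np.sqrt(0.3 * 0.7), 3, 1)
        gp = GPriorSpec(n)
        state = init_sampler(tiny_cfg(n_chains=1, seed=5), data, sp, gp)
        g = 10.0
        delta = (
            log_posterior(data, ModelIndicator((0,)), g, sp, gp).value
            - log_posterior(data, ModelIndicator(()), g, sp, gp).value
        )
        expected = min(1.0, np.exp(delta))
        accepted = 0
        trials = 3000
        for _ in range(trials):
            state.chains[0].set_model(())
            state.chains[0].set_g(g)
            fsmh_sweep(state, 0)
            accepted += state.chains[0].size == 1
        se = np.sqrt(expected * (1 - expected) / trials)
        assert accepted / trials == pytest.approx(expected, abs=4 * se + 0.01)

    def test_no_adds_at_truncation_bound(self):
        rng = np.random.default_rng(1)
        n, p = 40, 10
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, 1))
        data = DataBundle(Y - Y.mean(0), X, c_eff=1)
        sp = make_size_prior(2.0, 2.0, 1, p)  # T = 4 < p
        state = init_sampler(tiny_cfg(n_chains=1), data, sp, GPriorSpec(n))
        full = tuple(range(sp.T))
        for _ in range(50):
            state.chains[0].set_model(full)
            fsmh_sweep(state, 0)
            assert state.chains[0].size <= sp.T


class TestGlobalMoves:
    def test_crossover_conserves_index_multiset(self, toy_bundle):
        data, sp, gp = toy_bundle
        state = init_sampler(tiny_cfg(n_chains=3, seed=2), data, sp, gp)
        for _ in range(200):
            before = sorted(
                j for c in state.chains for j in c.order
            )
            crossover_move(state)
            after = sorted(j for c in state.chains for j in c.order)
            assert before == after

    def test_crossover_identical_parents_always_accepted(self, toy_bundle):
        data, sp, gp = toy_bundle
        state = init_sampler(tiny_cfg(n_chains=2, seed=4), data, sp, gp)
        for c in state.chains:
            c.set_model((1, 4))
            c.set_g(7.0)
        for _ in range(50):
            crossover_move(state)
        assert state.counters["crossover_accepted"] == state.counters["crossover_proposed"]
        assert all(c.order == [1, 4] for c in state.chains)

    def test_exchange_equal_logposts_always_accepted(self, toy_bundle):
        data, sp, gp = toy_bundle
        state = init_sampler(tiny_cfg(n_chains=2, seed=6), data, sp, gp)
        for c in state.chains:
            c.set_model((1,))
            c.set_g(5.0)
        for _ in range(50):
            exchange_move(state)
        assert state.counters["exchange_accepted"] == state.counters["exchange_proposed"]

    def test_single_chain_global_moves_are_noops(self, toy_bundle):
        data, sp, gp = toy_bundle
        state = init_sampler(tiny_cfg(n_chains=1), data, sp, gp)
        before = (list(state.chains[0].order), state.chains[0].g)
        crossover_move(state)
        exchange_move(state)
        tune_temperature_ladder(state)
        assert (list(state.chains[0].order), state.chains[0].g) == before


class TestUpdateG:
    def test_null_model_samples_the_prior(self, toy_bundle):
        """With gamma empty the marginal likelihood is flat in g, so the
        g-chain must recover the inverse-gamma(1/2, n/2) prior."""
        data, sp, gp = toy_bundle
        state = init_sampler(tiny_cfg(n_chains=1, seed=8), data, sp, gp)
        state.chains[0].set_model(())
        state.adapting = False
        samples = []
        for i in range(40000):
            update_g(state, 0)
            if i % 20 == 0:
                samples.append(state.chains[0].g)
        ref = stats.invgamma(a=gp.shape, scale=gp.rate)
        ks = stats.kstest(samples, ref.cdf)
        assert ks.pvalue > 1e-3

    def test_adaptation_freezes_after_burn_in(self, toy_bundle):
        data, sp, gp = toy_bundle
        state = init_sampler(tiny_cfg(n_chains=2), data, sp, gp)
        state.adapting = False
        step_before = [c.g_step for c in state.chains]
        base_before = state.ladder_base
        for _ in range(200):
            update_g(state, 0)
        tune_temperature_ladder(state)
        assert [c.g_step for c in state.chains] == step_before
        assert state.ladder_base == base_before


class TestLadderTuning:
    def test_low_acceptance_compresses_ladder(self, toy_bundle):
        data, sp, gp = toy_bundle
        state = init_sampler(tiny_cfg(n_chains=3), data, sp, gp)
        state._window = {"exchange_proposed": 100, "exchange_accepted": 2}
        b0 = state.ladder_base
        tune_temperature_ladder(state)
        assert state.ladder_base < b0
        assert min(c.temperature for c in state.chains) == 1.0

    def test_high_acceptance_stretches_ladder(self, toy_bundle):
        data, sp, gp = toy_bundle
        state = init_sampler(tiny_cfg(n_chains=3), data, sp, gp)
        state._window = {"exchange_proposed": 100, "exchange_accepted": 90}
        b0 = state.ladder_base
        tune_temperature_ladder(state)
        assert state.ladder_base > b0


class TestRun:
    def test_seed_reproducibility(self, toy_bundle):
        data, sp, gp = toy_bundle
        a = run(tiny_cfg(), data, sp, gp)
        b = run(tiny_cfg(), data, sp, gp)
        assert a.models == b.models
        assert np.array_equal(a.log_posteriors, b.log_posteriors)
        assert np.array_equal(a.g_values, b.g_values)

    def test_truncation_safety_of_history(self, toy_bundle):
        data, sp, gp = toy_bundle
        out = run(tiny_cfg(n_sweeps=500, burn_in=100), data, sp, gp)
        assert max(len(m) for m in out.models) <= sp.T

    def test_logposterior_trace_reproducible(self, toy_bundle):
        """Recorded cold-chain log-posteriors must match re-evaluation of
        (gamma, g) by the likelihood module — guards the incremental
        caches against state corruption."""
        data, sp, gp = toy_bundle
        out = run(tiny_cfg(n_sweeps=400, burn_in=100), data, sp, gp)
        sel = np.linspace(0, out.n_retained - 1, 40).astype(int)
        for i in sel:
            lp = log_posterior(
                data, ModelIndicator(out.models[i]), out.g_values[i], sp, gp
            )
            assert out.log_posteriors[i] == pytest.approx(lp.value, abs=1e-9)

    def test_exchange_acceptance_in_target_band_after_tuning(self, toy_bundle):
        data, sp, gp = toy_bundle
        cfg = tiny_cfg(n_sweeps=4000, burn_in=2000, p_crossover=0.0, adapt_interval=100)
        state = init_sampler(cfg, data, sp, gp)
        out = run(cfg, data, sp, gp)
        ex_rate = out.counters["exchange_accepted"] / out.counters["exchange_proposed"]
        assert 0.15 < ex_rate < 0.75  # band plus sampling slack

    def test_traces_cover_all_chains_and_sweeps(self, toy_bundle):
        data, sp, gp = toy_bundle
        cfg = tiny_cfg(n_sweeps=250, burn_in=50)
        out = run(cfg, data, sp, gp)
        assert out.traces["log_posterior"].shape == (250, 3)
        assert out.traces["model_size"].shape == (250, 3)
        assert out.n_retained == 200
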