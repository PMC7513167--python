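"""Sampler-level checks: individual block updates and full chain drivers."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from amhsurv.model import (
    BivariateSurvivalData,
    Hyperparams,
    ModelParams,
    _log_psi_sum,
)
from amhsurv.samplers import (
    ChainOutput,
    ChainState,
    MCMCConfig,
    auto_init,
    grid_imh_step,
    grid_imh_update_phi,
    imh_update_alpha,
    mh_update_beta,
    posterior_summary,
    run_chain,
    run_chains,
    rwm_update_alpha,
    slice_sample_1d,
    slice_update_alpha,
)
from amhsurv.diagnostics import gelman_rubin, iat
from amhsurv.simulate import TABLE_DESIGNS, SimulationDesign, simulate_dataset

D1 = TABLE_DESIGNS["D1"]
HYPER = Hyperparams()


class _StubRng:
    """Minimal deterministic generator for single-update unit checks."""

    def __init__(self, gamma=None, normal=None, uniform=0.5):
        self._gamma = gamma
        self._normal = normal
        self._uniform = uniform

    def gamma(self, shape, scale):
        return self._gamma

    def standard_normal(self):
        return self._normal

    def random(self):
        return self._uniform


class TestConfig:
    def test_kept_sample_arithmetic(self):
        cfg = MCMCConfig(L=110, B=10, J=10)
        assert cfg.S == 10

    def test_aliases(self):
        assert MCMCConfig(alpha_algorithm="A2").algorithm == "RWM"
        assert MCMCConfig(alpha_algorithm="SS").algorithm == "SS"

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"L": 10, "B": 10},
            {"J": 0},
            {"sigma2_rwm": 0.0},
            {"slice_lambda": -1.0},
            {"alpha_algorithm": "A9"},
            {"phi_grid_step": 0.3},
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            MCMCConfig(**kwargs)


class TestAlphaUpdates:
    def test_imh_self_proposal_always_accepted(self, d1_small):
        state = ChainState(D1, d1_small)
        rng = _StubRng(gamma=D1.alpha1, uniform=0.999999)
        imh_update_alpha(state, 1, d1_small, HYPER, rng)
        assert state.alpha1 == D1.alpha1
        assert state.accept_counts["alpha1"] == 1

    def test_rwm_zero_step_accepted(self, d1_small):
        state = ChainState(D1, d1_small)
        rng = _StubRng(normal=0.0, uniform=0.999999)
        rwm_update_alpha(state, 1, d1_small, HYPER, rng)
        assert state.accept_counts["alpha1"] == 1

    def test_rwm_negative_proposal_rejected(self, d1_small):
        state = ChainState(D1, d1_small)
        rng = _StubRng(normal=-100.0, uniform=0.0)
        rwm_update_alpha(state, 1, d1_small, HYPER, rng)
        assert state.alpha1 == D1.alpha1
        assert state.accept_counts["alpha1"] == 0


class TestSliceSampler:
    def test_recovers_truncated_normal(self):
        """Shrinkage-mode slice draws match a positive-truncated normal
        (Kolmogorov-Smirnov below the 1% critical value at 1e5 draws)."""

        def logk(x):
            return np.where(x > 0, -((x - 2.0) ** 2) / 2.0, -np.inf)

        rng = np.random.default_rng(123)
        n = 100_000
        out = np.empty(n)
        x = 2.0
        for i in range(n):
            x = slice_sample_1d(logk, x, 0.25, rng)
            out[i] = x
        target = stats.truncnorm(a=-2.0, b=np.inf, loc=2.0, scale=1.0)
        ks = stats.kstest(out, target.cdf).statistic
        assert ks < 1.6276 / math.sqrt(n)

    def test_narrow_slice_returns_current_point(self):
        # level above both neighbours at +-lambda: degenerate bracket
        def logk(x):
            return np.where(np.abs(x - 2.0) < 1e-9, 0.0, -1e9)

        rng = np.random.default_rng(0)
        for _ in range(5):
            # verbatim mode: the bracket degenerates to the current point
            assert slice_sample_1d(logk, 2.0, 0.05, rng, mode="paper") == 2.0
            # shrinkage mode: the draw stays within one step width
            x = slice_sample_1d(logk, 2.0, 0.05, rng)
            assert abs(x - 2.0) <= 0.05

    def test_paper_mode_stays_in_stepped_bracket(self):
        def logk(x):
            return np.where(x > 0, -((x - 2.0) ** 2) / 2.0, -np.inf)

        rng = np.random.default_rng(7)
        for _ in range(200):
            x = slice_sample_1d(logk, 2.0, 0.1, rng, mode="paper")
            assert 0.0 < x < 8.0

    def test_zero_density_start_rejected(self):
        def logk(x):
            return np.where(x > 0, 0.0, -np.inf)

        with pytest.raises(ValueError):
            slice_sample_1d(logk, -1.0, 0.1, np.random.default_rng(0))

    def test_unbounded_slice_detected(self):
        def logk(x):
            return np.zeros_like(x)  # improper flat kernel

        with pytest.raises(RuntimeError):
            slice_sample_1d(logk, 0.0, 10.0, np.random.default_rng(0),
                            max_steps=1000)


class TestBetaUpdate:
    def test_exact_gibbs_at_phi_zero(self):
        """With independent margins the correction ratio is 1: every
        proposal accepted and the draws are the conjugate Gamma."""
        truth = ModelParams(2.0, 1.0, 3.0, 1.0, 0.0)
        data = simulate_dataset(SimulationDesign(params=truth, n=50, seed=7))
        state = ChainState(truth, data)
        rng = np.random.default_rng(42)
        n_updates = 10_000
        draws = np.empty(n_updates)
        for i in range(n_updates):
            mh_update_beta(state, 1, data, HYPER, rng)
            draws[i] = state.beta1
        assert state.accept_counts["beta1"] == n_updates
        shape = HYPER.b11 + data.r1
        rate = HYPER.b12 + float((data.t1 ** truth.alpha1).sum())
        se = math.sqrt(shape) / rate / math.sqrt(n_updates)
        assert draws.mean() == pytest.approx(shape / rate, abs=4 * se)

    def test_self_proposal_accepted(self, d1_small):
        state = ChainState(D1, d1_small)
        rng = _StubRng(gamma=D1.beta1, uniform=0.999999)
        mh_update_beta(state, 1, d1_small, HYPER, rng)
        assert state.accept_counts["beta1"] == 1


class TestGridPhiUpdate:
    def test_flat_likelihood_gives_uniform_marginal(self):
        """Under a flat target the stationary law of phi is U(-1,1);
        checked by chi-square on a thinned subsequence (the raw chain
        moves only between adjacent grid cells and is autocorrelated)."""
        rng = np.random.default_rng(5)
        n, stride = 200_000, 100
        phi = 0.0
        draws = np.empty(n)
        for i in range(n):
            phi, _ = grid_imh_step(phi, lambda p: 0.0, rng)
            draws[i] = phi
        thin = draws[::stride]
        counts, _ = np.histogram(thin, bins=20, range=(-1, 1))
        expected = len(thin) / 20
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=19)
        assert np.all(np.abs(draws) < 1.0)

    def test_posterior_mean_matches_quadrature(self):
        """phi-only chain on independent-margin data agrees with a dense
        deterministic grid integration of the phi posterior."""
        truth = ModelParams(2.0, 1.0, 3.0, 1.0, 0.0)
        data = simulate_dataset(SimulationDesign(params=truth, n=200, seed=21))
        state = ChainState(truth, data)
        rng = np.random.default_rng(9)
        n = 40_000
        draws = np.empty(n)
        for i in range(n):
            grid_imh_update_phi(state, data, rng)
            draws[i] = state.phi
        grid = np.linspace(-0.9999, 0.9999, 4001)
        ll = np.array(
            [float(_log_psi_sum(state.F1, state.F2, g, state.pidx)) for g in grid]
        )
        w = np.exp(ll - ll.max())
        quad_mean = float((grid * w).sum() / w.sum())
        mcse = draws.std() * math.sqrt(max(iat(draws), 1.0) / n)
        assert draws.mean() == pytest.approx(quad_mean, abs=3 * mcse)


class TestRunChain:
    def test_thinning_bookkeeping(self, d1_small):
        cfg = MCMCConfig(L=110, B=10, J=10, seed=0)
        out = run_chain(d1_small, config=cfg)
        assert out.S == 10
        assert list(out.iterations) == list(range(20, 111, 10))

    def test_determinism(self, d1_small):
        cfg = MCMCConfig(L=300, B=100, J=5, alpha_algorithm="A3", seed=99)
        a = run_chain(d1_small, config=cfg)
        b = run_chain(d1_small, config=cfg)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_estimates_are_column_means(self, d1_small):
        cfg = MCMCConfig(L=300, B=100, J=5, seed=3)
        out = run_chain(d1_small, config=cfg)
        for i, p in enumerate(out.param_names):
            assert out.estimates[p] == pytest.approx(out.draws[:, i].mean())
        assert np.all(np.abs(out.draws[:, 4]) < 1.0)

    def test_all_censored_refused(self):
        data = BivariateSurvivalData([1.0, 2.0], [1.0, 2.0], [0, 0], [0, 0])
        with pytest.raises(ValueError, match="censored"):
            run_chain(data, config=MCMCConfig(L=20, B=0, J=1))

    def test_cross_sampler_posterior_agreement(self, cross_sampler_outputs):
        """A1/A2/A3 on one dataset agree within 3 combined MC standard
        errors for all five parameters."""
        _, outs = cross_sampler_outputs

        def mcse(out, i):
            x = out.draws[:, i]
            return x.std() * math.sqrt(max(iat(x), 1.0) / len(x))

        names = outs["A1"].param_names
        for a, b in (("A1", "A2"), ("A1", "A3"), ("A2", "A3")):
            for i, p in enumerate(names):
                diff = abs(outs[a].estimates[p] - outs[b].estimates[p])
                se = math.hypot(mcse(outs[a], i), mcse(outs[b], i))
                assert diff <= 3 * se, (a, b, p, diff, 3 * se)

    def test_efficiency_ordering(self, cross_sampler_outputs):
        """Slice sampling yields the largest effective sample size for the
        shapes, the prior-proposal IMH the smallest."""
        _, outs = cross_sampler_outputs
        ess_a1 = len(outs["A1"].draws) / max(iat(outs["A1"].draws[:, 0]), 1e-8)
        ess_a2 = len(outs["A2"].draws) / max(iat(outs["A2"].draws[:, 0]), 1e-8)
        ess_a3 = len(outs["A3"].draws) / max(iat(outs["A3"].draws[:, 0]), 1e-8)
        assert ess_a3 > ess_a2 > ess_a1

    def test_stationarity_from_truth(self):
        """Initialized at the truth of a large dataset, running means stay
        within 3 posterior SDs of their initial values."""
        data = simulate_dataset(
            SimulationDesign(params=D1, n=400, seed=55)
        )
        cfg = MCMCConfig(L=2000, B=0, J=1, alpha_algorithm="A2", seed=56)
        out = run_chain(data, config=cfg, init=D1)
        truth = D1.to_array()
        for i in range(5):
            x = out.draws[:, i]
            run_mean = np.cumsum(x) / np.arange(1, len(x) + 1)
            assert np.all(np.abs(run_mean[20:] - truth[i]) < 3 * x.std() + 1e-12)

    def test_multi_chain_psrf_converged(self):
        """Overdispersed RWM chains on D1 data pass the PSRF < 1.1 check."""
        data = simulate_dataset(SimulationDesign(params=D1, n=100, seed=61))
        cfg = MCMCConfig(L=11_000, B=1_000, J=10, alpha_algorithm="A2", seed=62)
        outs = run_chains(data, config=cfg, n_chains=2)
        for i in range(5):
            psrf = gelman_rubin([o.draws[:, i] for o in outs])
            assert psrf < 1.1

    def test_auto_init(self, d1_censored):
        p = auto_init(d1_censored)
        assert p.alpha1 == 1.0 and p.phi == 0.0
        assert p.beta1 == pytest.approx(
            d1_censored.r1 / float(d1_censored.t1.sum())
        )


class TestPosteriorSummary:
    def test_constant_chain(self):
        draws = np.full((50, 5), 2.5)
        out = ChainOutput(
            draws=draws, iterations=np.arange(50), acceptance_rates={},
            estimates={}, ci_lower={}, ci_upper={},
            config=MCMCConfig(L=50, B=0, J=1), seed=0,
        )
        s = posterior_summary(out)
        assert s["estimates"]["alpha1"] == 2.5
        assert s["ci_lower"]["alpha1"] == 2.5 == s["ci_upper"]["alpha1"]

    def test_uniform_grid_quantiles(self):
        col = np.arange(1, 1001) / 1000.0
        draws = np.tile(col[:, None], (1, 5))
        out = ChainOutput(
            draws=draws, iterations=np.arange(1000), acceptance_rates={},
            estimates={}, ci_lower={}, ci_upper={},
            config=MCMCConfig(L=1000, B=0, J=1), seed=0,
        )
        s = posterior_summary(out)
        assert s["ci_lower"]["phi"] == pytest.approx(0.025, abs=2e-3)
        assert s["ci_upper"]["phi"] == pytest.approx(0.975, abs=2e-3)
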