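"""Sampler correctness, diagnostics and reproducibility."""

import numpy as np
import pytest
from scipy import stats

import cocoondyn as cd
from cocoondyn.mcmc import (ChainConfig, CocoonSampler, gelman_rubin,
                            hpd_interval, mh_step, random_walk_mh)
from cocoondyn.model import ValidationError


class TestGenericMH:
    def test_zero_step_always_accepts(self, rng):
        x = np.array([1.3])
        for _ in range(20):
            x2, accepted, _ = mh_step(lambda v: -0.5 * v @ v, x, 0.0, rng)
            assert accepted
            assert np.array_equal(x2, x)

    def test_nonfinite_current_state_raises(self, rng):
        with pytest.raises(ValidationError):
            mh_step(lambda v: np.inf, np.array([0.0]), 0.1, rng)

    def test_standard_normal_moments(self, rng):
        draws, rate = random_walk_mh(
            lambda v: -0.5 * float(v @ v), np.zeros(1), 2.4, 100_000, rng,
            burn_in=2_000)
        x = draws[:, 0]
        # 3 Monte-Carlo standard errors with a conservative ESS estimate
        ess = len(x) / 10
        assert abs(x.mean()) < 3 * 1.0 / np.sqrt(ess)
        assert x.var() == pytest.approx(1.0, abs=0.1)
        assert 0.1 < rate < 0.7

    def test_acceptance_decreases_with_step_size(self, rng):
        rates = []
        for step in (0.1, 1.0, 5.0, 25.0):
            _, rate = random_walk_mh(
                lambda v: -0.5 * float(v @ v), np.zeros(1), step, 4_000,
                np.random.default_rng(4))
            rates.append(rate)
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_two_state_occupancy_matches_target(self, rng):
        # discrete two-state target embedded in a continuous random walk:
        # p(x) ~ 0.3 on x<0, 0.7 on x>=0 within [-1, 1)
        def logp(v):
            x = v[0]
            if not -1 <= x < 1:
                return -np.inf
            return np.log(0.3 if x < 0 else 0.7)
        draws, _ = random_walk_mh(logp, np.array([0.5]), 0.8, 60_000, rng)
        frac_high = float(np.mean(draws[:, 0] >= 0))
        assert frac_high == pytest.approx(0.7, abs=0.03)

    def test_poisson_gamma_conjugate_posterior(self, rng):
        # y_i ~ Poisson(rate), rate ~ Gamma(2, 1): posterior is
        # Gamma(2 + sum y, 1 + n), sampled here on the log scale
        y = rng.poisson(4.0, size=25)
        a_post, b_post = 2.0 + y.sum(), 1.0 + len(y)

        def logp(v):
            lam = np.exp(v[0])
            return float((2.0 + y.sum()) * v[0] - (1.0 + len(y)) * lam)

        draws, _ = random_walk_mh(logp, np.array([1.0]), 0.25, 60_000, rng,
                                  burn_in=5_000)
        lam = np.exp(draws[:, 0])
        want_mean = a_post / b_post
        want_var = a_post / b_post ** 2
        ess = len(lam) / 12
        mcse = np.sqrt(want_var / ess)
        assert abs(lam.mean() - want_mean) < 3 * mcse
        assert lam.var() == pytest.approx(want_var, rel=0.2)


class TestGelmanRubin:
    def test_identical_chains_closed_form(self):
        # B = 0, W = 1 gives sqrt((n-1)/n) with n = 3
        val = gelman_rubin([[1, 2, 3], [1, 2, 3]])
        assert val == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_iid_chains_near_one(self, rng):
        chains = rng.normal(size=(4, 20_000))
        assert gelman_rubin(chains) == pytest.approx(1.0, abs=0.01)

    def test_disjoint_chains_diverge(self, rng):
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(100, 1, 500)])
        assert gelman_rubin(chains) > 10

    def test_affine_invariance(self, rng):
        chains = rng.normal(size=(3, 400))
        a = gelman_rubin(chains)
        b = gelman_rubin(5.0 * chains - 7.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_variance_returns_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isnan(gelman_rubin([[1.0, 1.0], [1.0, 1.0]]))

    def test_too_few_chains_rejected(self):
        with pytest.raises(ValidationError):
            gelman_rubin([[1, 2, 3]])


class TestHpdInterval:
    def test_point_mass(self):
        lo, hi = hpd_interval(np.full(100, 3.25))
        assert lo == hi == 3.25

    def test_uniform_width(self, rng):
        lo, hi = hpd_interval(rng.random(100_000), mass=0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_exponential_left_anchored(self, rng):
        x = rng.exponential(1.0, 50_000)
        lo, hi = hpd_interval(x)
        q_lo, q_hi = np.quantile(x, [0.025, 0.975])
        assert lo < 0.01                      # starts at the mode, near zero
        assert (hi - lo) < (q_hi - q_lo)      # shorter than equal-tailed

    def test_never_wider_than_equal_tailed(self, rng):
        for _ in range(20):
            x = rng.gamma(rng.uniform(0.5, 5), size=500)
            lo, hi = hpd_interval(x, mass=0.9)
            q_lo, q_hi = np.quantile(x, [0.05, 0.95])
            assert hi - lo <= q_hi - q_lo + 1e-12

    def test_matches_arviz(self, rng):
        import arviz as az
        x = rng.gamma(2.0, size=5_000)
        lo, hi = hpd_interval(x, mass=0.94)
        ref = az.hdi(x, hdi_prob=0.94)
        assert lo == pytest.approx(ref[0], abs=0.02)
        assert hi == pytest.approx(ref[1], abs=0.02)

    def test_invalid_mass(self):
        with pytest.raises(ValidationError):
            hpd_interval([1, 2, 3], mass=1.5)


class TestChainConfig:
    def test_retention_arithmetic(self):
        cfg = ChainConfig(n_iterations=110, burn_in=100, thin=10, seed=1)
        assert cfg.n_retained == 1

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            ChainConfig(n_iterations=100, burn_in=100)
        with pytest.raises(ValidationError):
            ChainConfig(n_iterations=100, burn_in=50, thin=60)


class TestCocoonSampler:
    def test_single_retained_sample(self, small_counts):
        cfg = ChainConfig(n_chains=2, n_iterations=30, burn_in=20, thin=10,
                          seed=5)
        post = cd.run_chains(small_counts, config=cfg)
        assert post.values.shape[:2] == (2, 1)

    def test_bit_identical_reruns(self, small_counts):
        cfg = ChainConfig(n_chains=2, n_iterations=200, burn_in=100, thin=10,
                          seed=17)
        a = cd.run_chains(small_counts, config=cfg)
        b = cd.run_chains(small_counts, config=cfg)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.log_post, b.log_post)

    def test_block_deltas_match_joint_logposterior(self, small_counts):
        """Per-cell MH acceptance deltas must sum to the full change of the
        transformed-space log posterior when every proposal is applied; this
        fails if blocked cells are not conditionally independent."""
        cfg = ChainConfig.desk(seed=3, n_chains=2, n_iterations=100,
                               burn_in=50, thin=10)
        smp = CocoonSampler(small_counts, config=cfg, use_numba=False)
        for k in smp.lstep:
            smp.lstep[k] -= 2.0            # small steps stay inside support
        updates = [
            (lambda: smp._update_cells(0, force_all=True), (1, 2, 3)),
            (lambda: smp._update_cells(1, force_all=True), (1, 2, 3)),
            (lambda: smp._update_pools(force_all=True), (1, 2, 3)),
            (lambda: smp._update_site_year_rate("p_theta", force_all=True), (1, 2)),
            (lambda: smp._update_site_year_rate("p_kappa", force_all=True), (1, 2)),
            (lambda: smp._update_N_mean(force_all=True), (1, 2)),
            (lambda: smp._update_phi(force_all=True), ()),
            (lambda: smp._update_s(force_all=True), ()),
            (lambda: smp._update_k("theta", force_all=True), ()),
            (lambda: smp._update_k("kappa", force_all=True), ()),
        ]
        for fn, axes in updates:
            z0 = smp._logpost_z(smp.P)
            delta = fn()
            z1 = smp._logpost_z(smp.P)
            total = delta.sum(axis=axes) if axes else delta
            assert np.allclose(total, z1 - z0, rtol=1e-8, atol=1e-6)

    def test_compiled_sweep_matches_reference(self, small_counts):
        """The numba kernels and the numpy reference consume the same random
        stream and must produce the same chain trajectory."""
        pytest.importorskip("numba")
        cfg = ChainConfig.desk(seed=11, n_chains=2, n_iterations=100,
                               burn_in=50, thin=10)
        fast = CocoonSampler(small_counts, config=cfg, use_numba=True)
        if not fast._use_numba:
            pytest.skip("numba unavailable")
        ref = CocoonSampler(small_counts, config=cfg, use_numba=False)
        for it in range(1, 61):
            gain = min(0.3, 2.0 * it ** -0.6)
            fast.sweep(gain)
            ref.sweep(gain)
        for name in fast.P:
            np.testing.assert_allclose(fast.P[name], ref.P[name],
                                       rtol=1e-9, atol=1e-9, err_msg=name)

    def test_ragged_design_with_missing_samples(self, small_counts):
        """Sites with fewer samples (masked cells) fit without error and
        masked cells contribute nothing to the likelihood."""
        df = small_counts.to_frame()
        # drop the last sample of site 1 everywhere, and one single cell
        df = df[~((df["site"] == 1) & (df["sample"] == df["sample"].max()))]
        df = df.drop(df[(df["site"] == 2) & (df["sample"] == 1)
                        & (df["year"] == 2010)].index)
        ragged = cd.CocoonCounts.from_frame(df)
        assert ragged.mask.sum() == len(df)
        cfg = ChainConfig.desk(seed=21, n_chains=2, n_iterations=600,
                               burn_in=300, thin=10)
        post = cd.run_chains(ragged, config=cfg)
        st = post.state_at(0, 2)
        priors = cd.PriorSpec.from_counts(ragged)
        lp = cd.log_prior(st, priors) + cd.log_likelihood(ragged, st)
        assert lp == pytest.approx(post.log_post[0, 2], rel=1e-10)

    @pytest.mark.parametrize("opts_kwargs", [
        {"zero_history": True},
        {"phi_on_fresh_empties": False},
    ])
    def test_process_variants_fit_and_match_public_density(self, small_counts,
                                                           opts_kwargs):
        from cocoondyn.model import ProcessOptions, PriorSpec
        opts = ProcessOptions(**opts_kwargs)
        priors = PriorSpec.from_counts(small_counts, options=opts)
        cfg = ChainConfig.desk(seed=3, n_chains=2, n_iterations=800,
                               burn_in=400, thin=10)
        post = cd.run_chains(small_counts, priors, cfg)
        st = post.state_at(0, 5)
        lp = cd.log_prior(st, priors) + cd.log_likelihood(small_counts, st,
                                                          opts)
        assert lp == pytest.approx(post.log_post[0, 5], rel=1e-10)
        if opts.zero_history:
            first = priors.first_year[:, None, :]
            assert np.all(np.where(first, post.get("poolI"), 0.0) == 0.0)

    def test_retained_logpost_equals_public_density(self, small_counts,
                                                    small_fit, small_priors):
        st = small_fit.state_at(1, 3)
        lp = (cd.log_prior(st, small_priors)
              + cd.log_likelihood(small_counts, st))
        assert lp == pytest.approx(small_fit.log_post[1, 3], rel=1e-10)

    def test_summary_and_traces(self, small_fit):
        summ = small_fit.summary(["phi", "s", "k_theta"])
        assert list(summ["quantity"]) == ["phi", "s", "k_theta"]
        assert (summ["hpd_lower"] <= summ["hpd_upper"]).all()
        tr = small_fit.trace("p_theta[1,2010]")
        assert tr.shape == (small_fit.n_chains, small_fit.n_draws)
        assert ((tr > 0) & (tr < 1)).all()

    def test_save_load_roundtrip(self, small_fit, tmp_path):
        from cocoondyn.mcmc import PosteriorSamples
        path = tmp_path / "samples.npz"
        small_fit.save(path)
        again = PosteriorSamples.load(path)
        assert np.array_equal(again.values, small_fit.values)
        assert np.array_equal(again.years, small_fit.years)
        assert again.options == small_fit.options
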