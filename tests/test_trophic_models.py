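"""Trophic-position point estimate, posterior summaries and Bayesian fits."""

import numpy as np
import pytest

from trophiso.baselines import BaselineDistribution
from trophiso.errors import ConvergenceError, InputError, ValidationError
from trophiso.trophic_models import (
    MCMCSettings,
    TDFSet,
    TPModelConfig,
    convergence_check,
    credible_interval,
    effective_sample_size,
    fit_individual_one_baseline,
    fit_one_baseline,
    fit_two_baselines_full,
    posterior_mode,
    tp_point,
)

QUICK = TPModelConfig(mcmc=MCMCSettings.reduced(n_chains=2, n_iter=1500,
                                                n_burnin=300, thin=3))


def _baseline(rng, mean=7.6, sd=0.8, n=20, c_mean=-26.0, c_sd=1.5):
    return BaselineDistribution(
        "bin", "single",
        tuple(rng.normal(mean, sd, n)), tuple(rng.normal(c_mean, c_sd, n)),
    )


class TestTpPoint:
    @pytest.mark.parametrize(
        "consumer, baseline, tdf, lam, expected",
        [(7.0, 7.0, 4.3, 1.0, 1.0),       # consumer at the baseline
         (11.3, 7.0, 4.3, 1.0, 2.0),      # exactly one trophic step
         (15.6, 7.0, 4.3, 1.0, 3.0),      # two steps
         (10.0, 7.0, 2.0, 2.0, 3.5)],
    )
    def test_arithmetic(self, consumer, baseline, tdf, lam, expected):
        assert tp_point(consumer, baseline, tdf, lam) == pytest.approx(expected)

    def test_zero_tdf_rejected(self):
        with pytest.raises(InputError):
            tp_point(10.0, 7.0, 0.0)


class TestPosteriorSummaries:
    def test_mode_of_constant_draws(self):
        assert posterior_mode(np.full(2000, 2.2)) == 2.2

    def test_mode_of_normal_draws(self, rng):
        draws = rng.normal(2.2, 0.1, 10_000)
        assert posterior_mode(draws) == pytest.approx(2.2, abs=0.02)

    def test_mode_picks_higher_peak_of_bimodal(self, rng):
        draws = np.concatenate(
            [rng.normal(2.0, 0.05, 7000), rng.normal(3.0, 0.05, 3000)]
        )
        assert posterior_mode(draws) == pytest.approx(2.0, abs=0.05)

    def test_mode_requires_enough_draws(self):
        with pytest.raises(InputError):
            posterior_mode(np.ones(999))

    def test_ci_uniform_draws(self, rng):
        lo, hi = credible_interval(rng.uniform(0, 1, 100_000))
        assert lo == pytest.approx(0.025, abs=0.01)
        assert hi == pytest.approx(0.975, abs=0.01)

    def test_ci_normal_draws(self, rng):
        lo, hi = credible_interval(rng.normal(0, 1, 200_000))
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_ci_constant_draws(self):
        assert credible_interval(np.full(2000, 1.5)) == (1.5, 1.5)

    def test_ci_bad_level(self, rng):
        with pytest.raises(InputError):
            credible_interval(rng.normal(size=2000), level=1.5)


class TestConvergence:
    def test_identical_stationary_chains(self, rng):
        chain = rng.normal(size=5000)
        assert convergence_check(np.vstack([chain, chain])) == pytest.approx(
            1.0, abs=0.01
        )

    def test_disjoint_chains_flagged(self, rng):
        chains = np.vstack([rng.normal(0, 1, 2000), rng.normal(10, 1, 2000)])
        assert convergence_check(chains) > 1.5

    def test_single_chain_rejected(self, rng):
        with pytest.raises(InputError):
            convergence_check(rng.normal(size=(1, 2000)))

    def test_matches_arviz_split_rhat(self, rng):
        az = pytest.importorskip("arviz")
        chains = np.vstack(
            [rng.normal(0, 1, 2000), rng.normal(0.05, 1.1, 2000),
             rng.normal(-0.02, 0.9, 2000)]
        )
        ours = convergence_check(chains)
        theirs = float(az.rhat(chains, method="split"))
        assert ours == pytest.approx(theirs, rel=1e-6)

    def test_ess_of_iid_draws(self, rng):
        chains = rng.normal(size=(4, 2000))
        ess = effective_sample_size(chains)
        assert 0.5 * 8000 < ess < 1.6 * 8000


class TestOneBaseline:
    def test_parameter_recovery(self, rng):
        base = _baseline(rng)
        cons = base.d15N_mean + 4.3 * 1.3 + 0.5 * rng.standard_normal(8)
        post = fit_one_baseline(cons, base, cfg=QUICK, seed=7)
        assert abs(post.mode - 2.3) < 0.25
        assert post.ci95[0] < 2.3 < post.ci95[1]

    def test_zero_variance_limit_matches_point_formula(self, rng):
        base = BaselineDistribution(
            "b", "single", tuple(7.6 + 1e-3 * rng.standard_normal(10)),
            tuple([-26.0] * 10),
        )
        cons = 7.6 + 4.3 * 1.3 + 1e-3 * rng.standard_normal(6)
        tdf = TDFSet(d15N_sd=1e-3)
        post = fit_one_baseline(cons, base, tdf=tdf, cfg=QUICK, seed=11,
                                allow_nonconverged=True)
        expected = tp_point(float(cons.mean()), base.d15N_mean, 4.3)
        assert abs(post.mode - expected) < 0.02

    def test_monotone_in_consumer_d15n(self, rng):
        base = _baseline(rng)
        cons = base.d15N_mean + 4.3 + 0.4 * rng.standard_normal(6)
        lo = fit_one_baseline(cons, base, cfg=QUICK, seed=3)
        hi = fit_one_baseline(cons + 0.5, base, cfg=QUICK, seed=3)
        assert hi.mean > lo.mean

    def test_seed_determinism(self, rng):
        base = _baseline(rng)
        cons = base.d15N_mean + 4.3 + 0.4 * rng.standard_normal(6)
        a = fit_one_baseline(cons, base, cfg=QUICK, seed=5)
        b = fit_one_baseline(cons, base, cfg=QUICK, seed=5)
        assert np.array_equal(a.draws["tp"], b.draws["tp"])

    def test_draws_respect_prior_bounds(self, rng):
        base = _baseline(rng)
        cons = base.d15N_mean + 4.3 + 0.4 * rng.standard_normal(6)
        cfg = TPModelConfig(tp_max=4.0, mcmc=QUICK.mcmc)
        post = fit_one_baseline(cons, base, cfg=cfg, seed=9)
        tp = post.pooled()
        assert tp.min() >= 0.5 and tp.max() <= 4.0
        assert np.exp(post.draws["log_sigma_b"]).min() >= 0

    def test_empty_consumers_rejected(self, rng):
        with pytest.raises(InputError):
            fit_one_baseline([], _baseline(rng))

    def test_rhat_metadata_present(self, rng):
        base = _baseline(rng)
        cons = base.d15N_mean + 4.3 + 0.4 * rng.standard_normal(6)
        post = fit_one_baseline(cons, base, cfg=QUICK, seed=13)
        assert set(post.rhat) == {"tp", "mu_b", "log_sigma_b", "log_sigma_c",
                                  "delta_n"}
        assert all(np.isfinite(v) for v in post.rhat.values())

    def test_herbivore_regime_mode_near_two(self, rng):
        """Consumers one TDF above a high-elevation plant baseline sit at
        TP ≈ 2 (strict herbivory)."""
        base = _baseline(rng, mean=2.0, sd=1.5)
        cons = 2.0 + 4.3 * 1.2 + 0.3 * rng.standard_normal(5)
        post = fit_one_baseline(cons, base, cfg=QUICK, seed=21)
        assert post.mode == pytest.approx(2.2, abs=0.35)


class TestTwoBaselines:
    def test_consumers_at_source1_push_alpha_to_one(self, rng):
        s1 = _baseline(rng, mean=5.0, sd=1.0, c_mean=-26.0, c_sd=1.0, n=15)
        s2 = _baseline(rng, mean=6.5, sd=1.0, c_mean=-13.0, c_sd=1.0, n=15)
        cons_n = s1.d15N_mean + 4.3 + 0.3 * rng.standard_normal(8)
        cons_c = s1.d13C_mean + 0.7 + 0.3 * rng.standard_normal(8)
        cfg = TPModelConfig(mcmc=MCMCSettings.reduced(n_chains=2, n_iter=3000))
        post = fit_two_baselines_full(cons_n, cons_c, s1, s2, cfg=cfg, seed=2)
        assert post.alpha_summary["mean"] > 0.8
        assert post.mode == pytest.approx(2.0, abs=0.4)

    def test_mixture_recovery(self, rng):
        s1 = _baseline(rng, mean=5.0, sd=1.0, c_mean=-26.0, c_sd=1.0, n=15)
        s2 = _baseline(rng, mean=6.5, sd=1.0, c_mean=-13.0, c_sd=1.0, n=15)
        a, tp_true = 0.5, 1.9
        mu_n = a * s1.d15N_mean + (1 - a) * s2.d15N_mean + 4.3 * (tp_true - 1)
        mu_c = a * s1.d13C_mean + (1 - a) * s2.d13C_mean + 0.7 * (tp_true - 1)
        cons_n = mu_n + 0.4 * rng.standard_normal(8)
        cons_c = mu_c + 0.4 * rng.standard_normal(8)
        cfg = TPModelConfig(mcmc=MCMCSettings.reduced(n_chains=2, n_iter=4000))
        post = fit_two_baselines_full(cons_n, cons_c, s1, s2, cfg=cfg, seed=4)
        assert abs(post.alpha_summary["mean"] - a) < 0.15
        assert abs(post.mode - tp_true) < 0.3

    def test_length_mismatch_rejected(self, rng):
        s1, s2 = _baseline(rng), _baseline(rng)
        with pytest.raises(InputError):
            fit_two_baselines_full([10.0, 11.0], [-20.0], s1, s2)


class TestIndividual:
    def test_one_step_limit(self, rng):
        base = BaselineDistribution(
            "b", "single", tuple(7.0 + 0.05 * rng.standard_normal(12)),
            tuple([-26.0] * 12),
        )
        cfg = TPModelConfig(
            mcmc=MCMCSettings(n_chains=4, n_adapt=500, n_iter=400,
                              n_burnin=0, thin=4, n_walkers=8)
        )
        post = fit_individual_one_baseline(
            base.d15N_mean + 4.3, base, cfg=cfg, seed=1,
            allow_nonconverged=True,
        )
        assert post.mode == pytest.approx(2.0, abs=0.05)

    def test_multiple_consumers_rejected(self, rng):
        with pytest.raises(InputError, match="population"):
            fit_individual_one_baseline([10.0, 11.0], _baseline(rng))

    def test_summary_serializable(self, rng):
        import json

        base = _baseline(rng)
        cfg = TPModelConfig(
            mcmc=MCMCSettings(n_chains=2, n_adapt=400, n_iter=400,
                              n_burnin=0, thin=2, n_walkers=8)
        )
        post = fit_individual_one_baseline(
            base.d15N_mean + 5.0, base, cfg=cfg, seed=6,
            allow_nonconverged=True,
        )
        text = json.dumps(post.summary())
        assert "ci95" in text and "rhat" in text


class TestConfigValidation:
    def test_lambda_below_one_rejected(self):
        with pytest.raises(ValidationError):
            TPModelConfig(lambda_=0.5)

    def test_single_chain_rejected(self):
        with pytest.raises(ValidationError):
            MCMCSettings(n_chains=1)

    def test_negative_tp_lower_rejected(self):
        with pytest.raises(ValidationError):
            TPModelConfig(tp_min=-1.0)

    def test_nonconvergence_raises_without_flag(self, rng):
        # near-degenerate posterior (width ≪ the walker initialisation
        # jitter) plus an absurdly short run: chains cannot possibly mix
        base = BaselineDistribution(
            "b", "single", tuple(7.6 + 1e-4 * rng.standard_normal(10)),
            tuple([-26.0] * 10),
        )
        cons = 7.6 + 4.3 + 1e-4 * rng.standard_normal(6)
        cfg = TPModelConfig(
            mcmc=MCMCSettings(n_chains=3, n_adapt=0, n_iter=12, n_burnin=2,
                              thin=1)
        )
        with pytest.raises(ConvergenceError):
            fit_one_baseline(cons, base, tdf=TDFSet(d15N_sd=1e-3), cfg=cfg,
                             seed=8)
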