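import numpy as np
import pytest
from scipy import stats

import caredyn as cd
from caredyn.inference import SERIES_IDS


@pytest.fixture(scope="module")
def fixture_data():
    spec, series = cd.case_study_fixture(seed=101)
    return spec, series


@pytest.fixture(scope="module")
def priors():
    return cd.PriorSpec.table2()


class TestBetaLoglikelihood:
    def test_symmetric_case(self):
        # alpha=2, m=0.5 is Beta(2,2); density at the mode is 1.5
        assert cd.beta_loglikelihood(0.5, 0.5, 2.0) == pytest.approx(np.log(1.5))

    def test_mean_parameterisation_identity(self):
        # second shape alpha(1-m)/m makes the mean exactly m
        for alpha in (0.5, 3.0, 50.0, 2000.0):
            for m in (0.01, 0.2, 0.5, 0.9):
                b = alpha * (1 - m) / m
                assert stats.beta(alpha, b).mean() == pytest.approx(m, rel=1e-12)

    @pytest.mark.parametrize(
        "y,m,alpha",
        [
            (0.04, 0.03, 50.0),
            (0.5, 0.5, 2.0),
            (0.2, 0.25, 3.0),
            (0.97, 0.9, 400.0),
            (1e-4, 5e-4, 12.0),
        ],
    )
    def test_against_independent_beta_density(self, y, m, alpha):
        expected = stats.beta.logpdf(y, alpha, alpha * (1 - m) / m)
        assert abs(cd.beta_loglikelihood(y, m, alpha) - expected) < 1e-10

    def test_boundary_values_rejected(self):
        for y, m in [(0.0, 0.5), (1.0, 0.5), (0.5, 0.0), (0.5, 1.0)]:
            with pytest.raises(cd.DomainError):
                cd.beta_loglikelihood(y, m, 2.0)
        with pytest.raises(cd.DomainError):
            cd.beta_loglikelihood(0.5, 0.5, 0.0)


class TestLogPosterior:
    def test_empty_data_equals_log_prior(self, priors):
        setup = cd.FittingSetup.table2()
        phi = np.array([0.05, 0.3, 0.04, 0.03, 1000.0, 1000.0])
        lp = cd.log_posterior(phi, [], priors, setup)
        assert lp == pytest.approx(priors.log_prior(phi), rel=1e-12)

    def test_truncation_gives_minus_infinity(self, priors, fixture_data):
        _, series = fixture_data
        setup = cd.FittingSetup.table2()
        phi = np.array([-0.01, 0.3, 0.04, 0.03, 1000.0, 1000.0])
        assert cd.log_posterior(phi, series, priors, setup) == -np.inf

    def test_hand_summed_two_observation_oracle(self, priors):
        setup = cd.FittingSetup.table2()
        times = np.array([2017.5, 2018.0])
        phi = np.array([0.06, 0.30, 0.04, 0.03, 500.0, 800.0])
        m = cd.model_prevalence(*phi[:4], setup, times)
        data = [
            cd.PrevalenceSeries("moderate", times, np.array([0.045, 0.05])),
            cd.PrevalenceSeries("severe", times, np.array([0.031, 0.033])),
        ]
        expected = priors.log_prior(phi)
        for j, s in enumerate(data):
            for t_obs, y in zip(s.times, s.values):
                mm = m[s.series_id][np.where(times == t_obs)[0][0]]
                expected += cd.beta_loglikelihood(y, mm, phi[4 + j])
        assert cd.log_posterior(phi, data, priors, setup) == pytest.approx(
            expected, abs=1e-10
        )

    def test_fixed_alpha_mode(self, fixture_data):
        _, series = fixture_data
        setup = cd.FittingSetup.table2()
        pri = cd.PriorSpec.table2(alpha_fixed={sid: 2000.0 for sid in SERIES_IDS})
        phi = np.array([0.06, 0.30, 0.04, 0.03])
        assert np.isfinite(cd.log_posterior(phi, series, pri, setup))


class TestSampling:
    def test_prior_recovery_without_likelihood(self, priors):
        # with no data the sampler must reproduce the truncated-normal prior
        setup = cd.FittingSetup.table2()
        draws = cd.sample_posterior(
            [], priors, setup, seed=5, n_walkers=16, n_steps=800, n_warmup=400
        )
        q = draws.quantile("i", [0.25, 0.5, 0.75])
        expected = priors.i.ppf([0.25, 0.5, 0.75])
        assert np.allclose(q, expected, atol=0.015)  # prior scale is 0.1

    def test_seed_reproducibility_and_mc_agreement(self, fixture_data, priors):
        _, series = fixture_data
        setup = cd.FittingSetup.table2()
        kw = dict(n_walkers=16, n_steps=150, n_warmup=250)
        a = cd.sample_posterior(series, priors, setup, seed=21, **kw)
        a2 = cd.sample_posterior(series, priors, setup, seed=21, **kw)
        assert np.array_equal(a.chain, a2.chain)  # bitwise determinism
        b = cd.sample_posterior(series, priors, setup, seed=22, **kw)
        for name in ("i", "v"):
            med_a, med_b = a.quantile(name, 0.5), b.quantile(name, 0.5)
            # agree within a few posterior SDs scaled by effective draws
            sd = np.std(a.to_frame()[name])
            assert abs(med_a - med_b) < 4 * sd

    def test_draws_respect_truncation(self, fixture_data, priors):
        _, series = fixture_data
        setup = cd.FittingSetup.table2()
        draws = cd.sample_posterior(
            series, priors, setup, seed=33, n_walkers=16, n_steps=100, n_warmup=200
        )
        flat = draws.to_frame()
        assert (flat["i"] >= 0).all() and (flat["v"] >= 0).all()
        assert flat["m0"].between(0, 1).all() and flat["s0"].between(0, 1).all()
        assert (flat["alpha_moderate"] > 0).all()
        assert set(draws.rhat) == set(draws.names)

    def test_missing_seed_rejected(self, fixture_data, priors):
        _, series = fixture_data
        with pytest.raises(cd.DomainError):
            cd.sample_posterior(series, priors, cd.FittingSetup.table2(), seed=None)


class TestPosteriorBifurcation:
    def _degenerate_draws(self):
        phi = np.array([0.06, 0.30, 0.04, 0.03, 1000.0, 1000.0])
        chain = np.tile(phi, (50, 4, 1))
        names = ("i", "v", "m0", "s0", "alpha_moderate", "alpha_severe")
        return cd.PosteriorDraws(
            chain=chain, names=names, rhat={n: 1.0 for n in names}, acceptance=1.0
        )

    def test_degenerate_draws_give_identical_folds(self, table2_preset):
        draws = self._degenerate_draws()
        push = cd.posterior_bifurcation(
            draws, n_subsample=5, seed=1,
            base_params=table2_preset.params, P=table2_preset.P0,
        )
        assert push.per_draw["fold_upper"].nunique() == 1
        assert push.median_folds[1] == pytest.approx(
            push.per_draw["fold_upper"].iloc[0], abs=2.0
        )

    def test_median_folds_inside_per_draw_range(self, table2_preset):
        rng = np.random.default_rng(9)
        phi = np.array([0.06, 0.30, 0.04, 0.03, 1000.0, 1000.0])
        chain = phi * (1 + 0.05 * rng.standard_normal((40, 4, 6)))
        names = ("i", "v", "m0", "s0", "alpha_moderate", "alpha_severe")
        draws = cd.PosteriorDraws(
            chain=chain, names=names, rhat={n: 1.0 for n in names}, acceptance=1.0
        )
        push = cd.posterior_bifurcation(
            draws, n_subsample=30, seed=2,
            base_params=table2_preset.params, P=table2_preset.P0,
        )
        lo, hi = push.median_folds
        assert push.per_draw["fold_upper"].min() <= hi <= push.per_draw["fold_upper"].max()
        assert push.per_draw["fold_lower"].min() <= lo <= push.per_draw["fold_lower"].max()


class TestSeriesIO:
    def test_round_trip(self, tmp_path, fixture_data):
        _, series = fixture_data
        path = tmp_path / "series.csv"
        cd.write_series(series, path)
        back = cd.read_series(path)
        for s in series:
            assert np.array_equal(back[s.series_id].times, s.times)
            assert np.allclose(back[s.series_id].values, s.values, rtol=0, atol=1e-12)

    def test_series_validation(self):
        with pytest.raises(cd.DomainError):
            cd.PrevalenceSeries("m", [2017.0, 2017.0], [0.1, 0.2])
        with pytest.raises(cd.DomainError):
            cd.PrevalenceSeries("m", [2017.0, 2018.0], [0.1, 1.0])
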