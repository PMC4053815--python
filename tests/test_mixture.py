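import numpy as np
import pytest
from scipy import integrate
from scipy.stats import invgauss

from promcage.features import PriorPair
from promcage.fixtures import make_em_sample
from promcage.model import (
    InverseGaussianBeliefMixture,
    MixtureParams,
    Observation,
    classify,
    em_fit,
    ig_mle,
    ig_pdf,
    posterior,
)


class TestIgPdf:
    def test_mode_value_at_unit_parameters(self):
        # x = mu = lambda = 1: the exponential term vanishes
        assert ig_pdf(1.0, 1.0, 1.0) == pytest.approx(np.sqrt(1 / (2 * np.pi)), rel=1e-12)

    def test_matches_scipy_parameterization(self, rng):
        # independent oracle: scipy's invgauss with mu/lambda shape and
        # lambda scale is the same density
        for _ in range(200):
            x = rng.uniform(0.05, 50)
            mu = rng.uniform(0.1, 30)
            lam = rng.uniform(0.1, 30)
            assert ig_pdf(x, mu, lam) == pytest.approx(
                invgauss.pdf(x, mu / lam, scale=lam), rel=1e-10
            )

    def test_integrates_to_one(self, rng):
        for _ in range(5):
            mu = rng.uniform(0.5, 10)
            lam = rng.uniform(0.5, 10)
            total, _err = integrate.quad(
                lambda x: ig_pdf(x, mu, lam), 0, np.inf, limit=200
            )
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_invalid_arguments_are_errors(self):
        with pytest.raises(ValueError):
            ig_pdf(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            ig_pdf(1.0, 0.0, 1.0)


class TestIgMle:
    def test_matches_closed_form_on_sample(self, rng):
        x = invgauss.rvs(2.0 / 1.5, scale=1.5, size=2_000, random_state=rng)
        mu, lam = ig_mle(x)
        assert mu == pytest.approx(x.mean(), rel=1e-12)
        assert 1 / lam == pytest.approx(np.mean(1 / x - 1 / x.mean()), rel=1e-12)


class TestEmFit:
    def test_parameter_recovery_with_known_priors(self, rng):
        x, prior, fixed, _ = make_em_sample(
            5_000, 50.0, 30.0, 2.0, 1.0,
            prior_gen=lambda r: r.uniform(0.05, 0.95),
            n_labeled_bg=500, rng=rng,
        )
        est = InverseGaussianBeliefMixture().fit(x, prior=prior, fixed_background=fixed)
        p = est.params_
        assert p.mu1 == pytest.approx(50.0, rel=0.10)
        assert p.lambda1 == pytest.approx(30.0, rel=0.10)
        assert p.mu0 == pytest.approx(2.0, rel=0.10)
        assert p.lambda0 == pytest.approx(1.0, rel=0.10)

    def test_log_likelihood_non_decreasing(self, rng):
        x, prior, fixed, _ = make_em_sample(
            1_000, 40.0, 20.0, 1.5, 2.0, prior_gen=0.5, n_labeled_bg=100, rng=rng
        )
        est = InverseGaussianBeliefMixture().fit(x, prior=prior, fixed_background=fixed)
        diffs = np.diff(est.trajectory_)
        assert np.all(diffs >= -1e-7 * np.abs(est.trajectory_[:-1]))

    def test_all_background_labelled_matches_closed_form_mle(self, rng):
        x_bg = invgauss.rvs(2.0 / 1.0, scale=1.0, size=500, random_state=rng)
        x_free = np.array([30.0, 60.0, 45.0])
        obs = [Observation(v, PriorPair(0.5)) for v in x_free] + [
            Observation(v, PriorPair(0.0), fixed_label="background") for v in x_bg
        ]
        params, _ = em_fit(obs)
        mu_ref, lam_ref = ig_mle(np.concatenate([x_bg, x_free]), None)
        # free observations all sit far in the promoter mode; background MLE
        # is driven by the labelled sample
        mu_bg, lam_bg = ig_mle(x_bg)
        assert params.mu0 == pytest.approx(mu_bg, rel=0.02)
        assert params.lambda0 == pytest.approx(lam_bg, rel=0.05)

    def test_em_fixed_point_at_truth(self, rng):
        truth = MixtureParams(50.0, 30.0, 2.0, 1.0)
        x, prior, fixed, _ = make_em_sample(
            4_000, 50.0, 30.0, 2.0, 1.0, prior_gen=0.5, n_labeled_bg=400, rng=rng
        )
        one = InverseGaussianBeliefMixture(max_iter=1).fit(
            x, prior=prior, fixed_background=fixed, init=truth
        )
        full = InverseGaussianBeliefMixture(max_iter=200).fit(
            x, prior=prior, fixed_background=fixed, init=truth
        )
        # one EM step from the truth leaves the log-likelihood essentially
        # at its converged value
        assert one.trajectory_[0] == pytest.approx(full.log_likelihood_, rel=1e-3)

    def test_distinct_observations_required(self):
        with pytest.raises(ValueError):
            InverseGaussianBeliefMixture().fit([2.0, 2.0, 2.0])


class TestPosterior:
    def test_identical_components_give_prior(self):
        params = MixtureParams(3.0, 2.0, 3.0, 2.0)
        assert posterior(1.7, PriorPair(0.5), params).p_prom == pytest.approx(0.5)
        assert posterior(1.7, PriorPair(0.8), params).p_prom == pytest.approx(0.8)

    def test_degenerate_prior_dominates(self):
        params = MixtureParams(50.0, 30.0, 2.0, 1.0)
        assert posterior(0.5, PriorPair(1.0), params).p_prom == 1.0
        assert posterior(500.0, PriorPair(0.0), params).p_prom == 0.0

    def test_matches_brute_force_bayes(self, rng):
        # independent oracle computed in linear space with scipy densities
        n = 10_000
        x = rng.uniform(0.1, 80, n)
        p1 = rng.uniform(0.01, 0.99, n)
        mu1, lam1 = rng.uniform(5, 60), rng.uniform(1, 40)
        mu0, lam0 = rng.uniform(0.5, 4), rng.uniform(0.5, 4)
        params = MixtureParams(mu1, lam1, mu0, lam0)
        est = InverseGaussianBeliefMixture()
        est.params_ = params
        got = est.predict_proba(x, prior=p1)
        f1 = invgauss.pdf(x, mu1 / lam1, scale=lam1)
        f0 = invgauss.pdf(x, mu0 / lam0, scale=lam0)
        expected = p1 * f1 / (p1 * f1 + (1 - p1) * f0)
        assert np.allclose(got, expected, atol=1e-12)

    def test_extreme_observation_never_nan(self):
        params = MixtureParams(50.0, 30.0, 2.0, 1.0)
        for x in (1e-6, 1e6):
            p = posterior(x, PriorPair(0.5), params).p_prom
            assert np.isfinite(p) and 0.0 <= p <= 1.0

    def test_posterior_monotone_in_x_when_promoter_mean_larger(self):
        params = MixtureParams(50.0, 30.0, 2.0, 1.0)
        xs = np.linspace(1.0, 100.0, 400)
        est = InverseGaussianBeliefMixture()
        est.params_ = params
        post = est.predict_proba(xs, prior=np.full_like(xs, 0.5))
        assert np.all(np.diff(post) > -1e-12)


class TestClassify:
    def _results(self, ps):
        params = MixtureParams(3.0, 2.0, 3.0, 2.0)
        return [posterior(1.0, PriorPair(p), params) for p in ps]

    def test_strict_cutoff(self):
        res = classify(self._results([0.51, 0.5, 0.49]), c=0.5)
        assert [r.label for r in res] == ["promoter", "background", "background"]

    def test_lowering_cutoff_never_loses_calls(self, rng):
        res = self._results(rng.uniform(0, 1, 200))
        n_high = sum(r.label == "promoter" for r in classify(res, 0.7))
        n_low = sum(r.label == "promoter" for r in classify(res, 0.3))
        assert n_low >= n_high

    def test_invalid_cutoff_is_error(self):
        with pytest.raises(ValueError):
            classify([], c=1.0)


class TestInformativeVsFlatPriors:
    def test_informative_priors_raise_recall_on_low_count_promoters(self, rng):
        """Low-count promoters are recovered only when the belief prior
        carries the sequence evidence (the combined model beats the
        counts-only model)."""
        params = MixtureParams(50.0, 30.0, 2.0, 1.0)
        # promoters whose tag counts sit in the background range
        x_low = invgauss.rvs(4.0 / 10.0, scale=10.0, size=300, random_state=rng)
        x_low = np.clip(x_low, 0.2, None)
        est = InverseGaussianBeliefMixture()
        est.params_ = params
        informative = est.predict_proba(x_low, prior=np.full_like(x_low, 0.9))
        flat = est.predict_proba(x_low, prior=np.full_like(x_low, 0.5))
        recall_inf = (informative > 0.5).mean()
        recall_flat = (flat > 0.5).mean()
        assert recall_inf > recall_flat


class TestSerialization:
    def test_json_roundtrip_preserves_posteriors(self, tmp_path, rng):
        x, prior, fixed, _ = make_em_sample(
            800, 40.0, 20.0, 1.5, 2.0, prior_gen=0.7, n_labeled_bg=100, rng=rng
        )
        est = InverseGaussianBeliefMixture().fit(x, prior=prior, fixed_background=fixed)
        path = tmp_path / "model.json"
        est.to_json(path)
        loaded = InverseGaussianBeliefMixture.from_json(path)
        xs = np.linspace(0.5, 80, 50)
        pr = np.full_like(xs, 0.6)
        assert np.allclose(est.predict_proba(xs, pr), loaded.predict_proba(xs, pr))
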